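"""Cross-validation and confidence-weighted correlation.

Leave-one-out (LOO) validation fits the variogram once on all data, then
removes each observation in turn and predicts it from the remainder with the
fixed model — the fitted spatial structure is treated as a property of the
whole dataset, not of each training fold.  k-fold validation partitions the
observations into k near-equal folds (sizes differ by at most one), holds
each fold out once, and for k < n repeats the random partition (default five
times), reporting the mean correlation across repeats.

Agreement between observed and predicted values is summarised by a Pearson
correlation weighted by prediction confidence, w_i = 1 / sigma_i^2: precise
predictions count more.  Significance is the F-test of the weighted
least-squares slope (predicted on observed) against zero, with n - 2
denominator degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .data import VariantDataset
from .errors import ConfigError, InsufficientDataError
from .kriging import NeighborhoodPolicy, predict_point
from .variogram import (VariogramModel, empirical_variogram, fit_variogram,
                        pairwise_semivariances, FAMILIES)

logger = logging.getLogger(__name__)


class WeightedCorrelation(NamedTuple):
    r: float
    p: float
    undefined: bool = False


@dataclass
class CrossValidationResult:
    """Held-out predictions plus the weighted correlation summary."""

    per_point: pd.DataFrame  # columns: label, observed, predicted, sigma2, repeat
    weighted_r: float
    p_value: float
    undefined: bool
    k: int
    repeats: int
    seed: int | None = None
    model: VariogramModel | None = None


def weighted_pearson(observed, predicted, sigma2) -> WeightedCorrelation:
    """Pearson correlation with inverse-variance weights w_i = 1/sigma_i^2.

    Weights are normalised to sum to one (the correlation is invariant to
    their overall scale; the slope test is not, hence the fixed convention).
    A zero variance is replaced by the smallest positive variance present.
    Constant observed or predicted values make the correlation undefined and
    are flagged rather than propagated as NaN.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    s2 = np.asarray(sigma2, dtype=float)
    if not (len(obs) == len(pred) == len(s2)):
        raise ValueError("observed, predicted and sigma2 must have equal length")
    n = len(obs)
    if n < 3:
        raise InsufficientDataError("need at least 3 points for a correlation")
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    if np.any(s2 == 0):
        positive = s2[s2 > 0]
        if positive.size == 0:
            logger.warning("all variances are zero; falling back to equal weights")
            s2 = np.ones_like(s2)
        else:
            logger.warning("substituting %d zero variance(s) with min positive %.3e",
                           int((s2 == 0).sum()), positive.min())
            s2 = np.where(s2 == 0, positive.min(), s2)

    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return WeightedCorrelation(float("nan"), float("nan"), undefined=True)
    w = 1.0 / s2
    w = w / w.sum()
    mo = float(w @ obs)
    mp = float(w @ pred)
    cov = float(w @ ((obs - mo) * (pred - mp)))
    vo = float(w @ (obs - mo) ** 2)
    vp = float(w @ (pred - mp) ** 2)
    if vo <= 0 or vp <= 0:
        return WeightedCorrelation(float("nan"), float("nan"), undefined=True)
    r = cov / np.sqrt(vo * vp)

    # F-test of the WLS slope of predicted on observed
    slope = cov / vo
    intercept = mp - slope * mo
    fitted = intercept + slope * obs
    sse = float(w @ (pred - fitted) ** 2)
    ssr = float(w @ (fitted - mp) ** 2)
    if sse <= 0:
        p = 0.0
    else:
        f = ssr / (sse / (n - 2))
        p = float(stats.f.sf(f, 1, n - 2))
    return WeightedCorrelation(float(np.clip(r, -1.0, 1.0)), p, False)


def fit_dataset_variogram(dataset: VariantDataset, family: str = "spherical",
                          n_bins: int = 12,
                          active_lag: float | None = None) -> VariogramModel:
    """Convenience: pairwise semivariances -> binning -> model fit."""
    pairs = pairwise_semivariances(dataset)
    emp = empirical_variogram(pairs, n_bins=n_bins, active_lag=active_lag)
    return fit_variogram(emp, family)


def loo_cv(dataset: VariantDataset, family: str = "spherical",
           policy: NeighborhoodPolicy | None = None, n_bins: int = 12,
           active_lag: float | None = None,
           model: VariogramModel | None = None) -> CrossValidationResult:
    """Leave-one-out cross-validation with the all-data variogram held fixed."""
    policy = policy or NeighborhoodPolicy()
    if dataset.n < policy.min_n + 1:
        raise InsufficientDataError("dataset too small for leave-one-out validation")
    if model is None:
        model = fit_dataset_variogram(dataset, family, n_bins, active_lag)
    rows = []
    for i, obs in enumerate(dataset.observations):
        rest = dataset.drop(i)
        zhat, s2 = predict_point((obs.x, obs.y), rest, model, policy)
        rows.append((obs.label, obs.z, zhat, s2, 0))
    frame = pd.DataFrame(rows, columns=["label", "observed", "predicted", "sigma2", "repeat"])
    wc = weighted_pearson(frame["observed"], frame["predicted"], frame["sigma2"])
    return CrossValidationResult(frame, wc.r, wc.p, wc.undefined,
                                 k=dataset.n, repeats=1, model=model)


def _fold_assignments(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold label per observation; fold sizes differ by at most one."""
    labels = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    return labels[rng.permutation(n)]


def kfold_cv(dataset: VariantDataset, k: int, repeats: int = 5, seed: int = 0,
             family: str = "spherical", policy: NeighborhoodPolicy | None = None,
             n_bins: int = 12, active_lag: float | None = None,
             refit_per_fold: bool = False) -> CrossValidationResult:
    """k-fold cross-validation; k = n degenerates to leave-one-out exactly.

    For k < n the random partition is repeated (default 5 times) and the
    reported r and p are means across repeats.  ``refit_per_fold`` refits the
    variogram on each training fold instead of reusing the all-data model.
    """
    policy = policy or NeighborhoodPolicy()
    n = dataset.n
    if k < 2 or k > n:
        raise ConfigError(f"k must lie in [2, {n}], got {k}")
    if k == n:
        result = loo_cv(dataset, family, policy, n_bins, active_lag)
        return CrossValidationResult(result.per_point, result.weighted_r, result.p_value,
                                     result.undefined, k=k, repeats=1, seed=seed,
                                     model=result.model)

    full_model = None
    if not refit_per_fold:
        full_model = fit_dataset_variogram(dataset, family, n_bins, active_lag)
    rng = np.random.default_rng(seed)
    frames, rs, ps = [], [], []
    undefined = False
    for rep in range(repeats):
        folds = _fold_assignments(n, k, rng)
        rows = []
        for fold in range(k):
            test_idx = np.flatnonzero(folds == fold)
            train_idx = np.flatnonzero(folds != fold)
            train = dataset.subset(train_idx)
            model = full_model or fit_dataset_variogram(train, family, n_bins, active_lag)
            for i in test_idx:
                obs = dataset.observations[i]
                zhat, s2 = predict_point((obs.x, obs.y), train, model, policy)
                rows.append((obs.label, obs.z, zhat, s2, rep))
        frame = pd.DataFrame(rows, columns=["label", "observed", "predicted",
                                            "sigma2", "repeat"])
        frames.append(frame)
        wc = weighted_pearson(frame["observed"], frame["predicted"], frame["sigma2"])
        undefined = undefined or wc.undefined
        rs.append(wc.r)
        ps.append(wc.p)
    per_point = pd.concat(frames, ignore_index=True)
    return CrossValidationResult(per_point, float(np.mean(rs)), float(np.mean(ps)),
                                 undefined, k=k, repeats=repeats, seed=seed,
                                 model=full_model)


def family_comparison(dataset: VariantDataset,
                      policy: NeighborhoodPolicy | None = None,
                      n_bins: int = 12,
                      active_lag: float | None = None) -> pd.DataFrame:
    """LOO performance of each variogram family on one dataset.

    Returns a frame indexed by family with columns weighted_r, p_value and
    rmse — the basis for the model-family choice.
    """
    rows = {}
    for fam in FAMILIES:
        res = loo_cv(dataset, fam, policy, n_bins, active_lag)
        rmse = float(np.sqrt(np.mean((res.per_point["observed"]
                                      - res.per_point["predicted"]) ** 2)))
        rows[fam] = {"weighted_r": res.weighted_r, "p_value": res.p_value, "rmse": rmse}
    return pd.DataFrame(rows).T
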