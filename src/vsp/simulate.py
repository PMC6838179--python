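"""Gaussian-random-field simulation and variant-table fixtures.

``simulate_field`` draws a stationary Gaussian random field over (x, y)
coordinates whose covariance follows a given variogram model:
z = mean + L eps, where L is the Cholesky factor of the covariance matrix
C_ij = sill - gamma(h_ij) (with a 1e-10 diagonal jitter) and eps is standard
normal.  This is the exact generative model the variogram/kriging machinery
assumes, so the simulator closes the loop: fields simulated from known
parameters are the independent ground truth for recovery tests.

``make_variant_fixture`` produces paired control/treated variant datasets
shaped like a sparse disease-variant screen: by default 48 variants placed
along a 1278-residue protein, a trafficking-index response in [0, 1] drawn
from a spherical field (range 0.19, sill 0.05, mean 0.35) over the
(sequence, cholesterol-score) plane, and a cholesterol coordinate with a
configurable negative correlation (default -0.36) to the response.  The
treated condition re-draws the field with range and sill shrunk by
``condition_effect``, re-using the control innovations so that an effect of
1 reproduces the control exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data import VariantDataset, from_arrays
from .errors import ConfigError
from .variogram import VariogramModel

CHOLESKY_JITTER = 1e-10


@dataclass(frozen=True)
class FieldSpec:
    """Everything needed to draw one field realisation."""

    model: VariogramModel
    n_points: int
    coordinate_sampler: str = "uniform"
    mean: float = 0.0
    seed: int = 0
    protein_length: int = 10_000

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ConfigError("n_points must be >= 2")
        if self.coordinate_sampler not in ("uniform", "clustered"):
            raise ConfigError(f"unknown sampler {self.coordinate_sampler!r}")


def _sample_coords(spec: FieldSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if spec.coordinate_sampler == "uniform":
        x = rng.uniform(0.0, 1.0, spec.n_points)
        y = rng.uniform(0.0, 1.0, spec.n_points)
    else:  # clustered: points around a few seeded centres
        n_centers = max(2, spec.n_points // 15)
        centers = rng.uniform(0.1, 0.9, size=(n_centers, 2))
        which = rng.integers(0, n_centers, spec.n_points)
        xy = centers[which] + rng.normal(0.0, 0.05, size=(spec.n_points, 2))
        x, y = np.clip(xy[:, 0], 0.0, 1.0), np.clip(xy[:, 1], 0.0, 1.0)
    x = np.maximum(x, 1.0 / spec.protein_length)  # x = 0 has no residue
    return x, y


def _field_values(coords: np.ndarray, model: VariogramModel, mean: float,
                  eps: np.ndarray) -> np.ndarray:
    h = squareform(pdist(coords))
    cov = model.covariance(h)
    np.fill_diagonal(cov, model.sill)
    # jitter scaled to the sill so a (near-)zero-variance field stays flat
    jitter = CHOLESKY_JITTER * max(model.sill, np.finfo(float).tiny)
    cov = cov + jitter * np.eye(len(coords))
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("covariance matrix not positive definite; "
                          "inconsistent variogram model") from exc
    return mean + L @ eps


def simulate_field(spec: FieldSpec) -> VariantDataset:
    """One seeded realisation of the Gaussian random field as a dataset."""
    rng = np.random.default_rng(spec.seed)
    x, y = _sample_coords(spec, rng)
    eps = rng.standard_normal(spec.n_points)
    coords = np.column_stack([x, y])
    z = _field_values(coords, spec.model, spec.mean, eps)
    ds = from_arrays(x, y, z, protein_length=spec.protein_length)
    ds.axis_meta = {"simulated_from": spec.model.to_dict(), "seed": spec.seed,
                    "mean": spec.mean, "sampler": spec.coordinate_sampler}
    return ds


def make_variant_fixture(n_variants: int = 48, protein_length: int = 1278,
                         condition_effect: float = 0.6, seed: int = 0,
                         range_: float = 0.19, sill: float = 0.05,
                         mean: float = 0.35, chol_mean: float = 1.0,
                         chol_sd: float = 0.3,
                         chol_corr: float = -0.36) -> tuple[VariantDataset, VariantDataset]:
    """Paired control/treated datasets shaped like a sparse variant screen.

    The response (a trafficking index) is a spherical Gaussian field over
    (x, chol) plus a linear trend in the cholesterol coordinate whose slope
    realises the target response-coordinate correlation ``chol_corr``; the
    result is clipped to [0, 1].  Returns ``(control, treated)``.
    """
    if n_variants < 10:
        raise ConfigError("n_variants must be >= 10")
    if not (0.0 < condition_effect <= 1.0):
        raise ConfigError("condition_effect must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, protein_length + 1),
                                   size=n_variants, replace=False))
    x = positions / protein_length
    chol = chol_mean + chol_sd * rng.standard_normal(n_variants)
    eps = rng.standard_normal(n_variants)
    coords = np.column_stack([x, chol])

    # slope realising corr(z, chol) = chol_corr given field variance = sill
    rho = float(np.clip(chol_corr, -0.99, 0.99))
    beta = rho * np.sqrt(sill) / (chol_sd * np.sqrt(1.0 - rho**2))
    trend = beta * (chol - chol_mean)

    def draw(effect: float) -> np.ndarray:
        model = VariogramModel("spherical", 0.0, sill * effect, range_ * effect)
        z = _field_values(coords, model, mean, eps) + trend
        return np.clip(z, 0.0, 1.0)

    labels = [f"V{p}" for p in positions]
    ctl = from_arrays(x, chol, draw(1.0), protein_length=protein_length,
                      condition="CTL", labels=labels)
    trt = from_arrays(x, chol, draw(condition_effect), protein_length=protein_length,
                      condition="TRT", labels=labels)
    for ds, cond in ((ctl, "CTL"), (trt, "TRT")):
        ds.axis_meta = {
            "y_column": "chol", "z_column": "tridx", "condition": cond,
            "generator": {
                "range": range_, "sill": sill, "mean": mean,
                "condition_effect": condition_effect if cond == "TRT" else 1.0,
                "chol_corr_target": chol_corr, "seed": seed,
            },
        }
    return ctl, trt
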