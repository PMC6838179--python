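"""Ordinary kriging with local neighbourhoods.

Given a fitted variogram model, the prediction at a target location u is the
weighted average z*_u = sum_i w_i z_i over nearby observations, with weights
chosen to minimise the expected squared prediction error subject to the
unbiasedness constraint sum_i w_i = 1.  The weights solve the augmented
symmetric system

    [ C  1 ] [ w ]   [ c_u ]
    [ 1' 0 ] [ mu] = [  1  ]

where C_ij is the spatial covariance between observations, c_u the covariance
between each observation and the target, and mu the Lagrange multiplier for
the constraint.  The minimised kriging variance

    sigma^2_u = C(0) - (sum_i w_i C_iu + mu)

quantifies prediction confidence: it is 0 at an observation (the predictor
interpolates exactly) and approaches the sill far from all data.

Neighbourhoods follow a nearest-within-radius policy: up to ``max_n``
observations inside the search radius, falling back to the ``min_n`` nearest
overall when the radius is too empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data import VariantDataset
from .errors import InsufficientDataError, SingularSystemError
from .variogram import VariogramModel

logger = logging.getLogger(__name__)

# Coincident observations make C singular; the second point's x is nudged by
# this amount inside matrix assembly only (reports keep the true coordinate).
DUPLICATE_JITTER = 1e-9


@dataclass(frozen=True)
class NeighborhoodPolicy:
    """Local-neighbourhood selection rule for kriging.

    ``search_radius`` of None means "use the variogram range at solve time" —
    beyond the range observations carry no spatial information anyway.
    """

    min_n: int = 5
    max_n: int = 20
    search_radius: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.min_n <= self.max_n):
            raise ValueError("need 1 <= min_n <= max_n")

    def radius(self, model: VariogramModel) -> float:
        return self.search_radius if self.search_radius is not None else model.range_


@dataclass
class KrigingSolution:
    """Solved weights and prediction for one target location."""

    neighbor_indices: np.ndarray
    weights: np.ndarray
    lagrange: float
    prediction: float
    variance: float
    clamped: bool = False


def select_neighbors(u, dataset: VariantDataset, policy: NeighborhoodPolicy,
                     model: VariogramModel | None = None) -> np.ndarray:
    """Indices of the observations used to predict at ``u``.

    The ``max_n`` nearest observations within the search radius; if fewer than
    ``min_n`` fall inside, the ``min_n`` nearest overall regardless of radius.
    Ties break by (distance, observation index), so coincident observations
    keep their dataset order.
    """
    if dataset.n < policy.min_n:
        raise InsufficientDataError(
            f"dataset has {dataset.n} observations but policy requires >= {policy.min_n}"
        )
    u = np.asarray(u, dtype=float)
    d = np.hypot(*(dataset.coords - u).T)
    order = np.lexsort((np.arange(dataset.n), d))  # distance, then index
    radius = policy.radius(model) if model is not None else (
        policy.search_radius if policy.search_radius is not None else np.inf)
    inside = order[d[order] <= radius]
    if len(inside) >= policy.min_n:
        return inside[: policy.max_n]
    return order[: policy.min_n]


def _dedup_coords(coords: np.ndarray) -> np.ndarray:
    """Nudge exact duplicate rows apart so the covariance matrix is regular."""
    out = coords.copy()
    seen: dict[tuple, int] = {}
    for k in range(len(out)):
        key = (out[k, 0], out[k, 1])
        while key in seen:
            out[k, 0] += DUPLICATE_JITTER
            key = (out[k, 0], out[k, 1])
        seen[key] = k
    return out


def solve_kriging(u, neighbors: np.ndarray, model: VariogramModel,
                  dataset: VariantDataset) -> KrigingSolution:
    """Solve the ordinary-kriging system for target ``u`` over ``neighbors``."""
    neighbors = np.asarray(neighbors, dtype=int)
    k = len(neighbors)
    if k == 0:
        raise InsufficientDataError("empty neighborhood")
    u = np.asarray(u, dtype=float)
    coords = _dedup_coords(dataset.coords[neighbors])
    z = dataset.z[neighbors]

    sill_ = model.sill
    if sill_ <= 0.0:
        # degenerate zero-variance model (e.g. pure nugget fitted to a
        # constant field): every unbiased predictor is optimal; use the mean
        w = np.full(k, 1.0 / k)
        return KrigingSolution(neighbors, w, 0.0, float(w @ z), 0.0)

    diff = coords[:, None, :] - coords[None, :, :]
    hmat = np.hypot(diff[..., 0], diff[..., 1])
    hu = np.hypot(*(coords - u).T)

    sill = model.sill
    A = np.empty((k + 1, k + 1))
    A[:k, :k] = sill - model.gamma(hmat)
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    A[k, k] = 0.0
    b = np.empty(k + 1)
    b[:k] = sill - model.gamma(hu)
    b[k] = 1.0

    try:
        sol = scipy.linalg.solve(A, b)
    except scipy.linalg.LinAlgError as exc:
        bad = [dataset.labels[i] for i in neighbors]
        raise SingularSystemError(
            f"singular kriging system; coincident observations among {bad}"
        ) from exc
    if not np.all(np.isfinite(sol)):
        bad = [dataset.labels[i] for i in neighbors]
        raise SingularSystemError(
            f"non-finite kriging solution; coincident observations among {bad}"
        )

    w, mu = sol[:k], float(sol[k])
    zstar = float(w @ z)
    var = float(sill - (w @ b[:k] + mu))
    clamped = False
    if var < 0.0:
        # pure round-off may go slightly negative; anything larger means the
        # system and the variogram are inconsistent
        tol = 1e-12 + 1e-9 * sill
        if var > -tol:
            logger.debug("clamping kriging variance %.3e to 0", var)
            var, clamped = 0.0, True
        else:
            raise SingularSystemError(
                f"kriging variance {var:.3e} is negative beyond round-off; "
                "inconsistent covariance model"
            )
    return KrigingSolution(neighbors, w, mu, zstar, var, clamped)


def predict_point(u, dataset: VariantDataset, model: VariogramModel,
                  policy: NeighborhoodPolicy | None = None) -> tuple[float, float]:
    """Kriging prediction and variance at ``u``: neighbour selection + solve."""
    policy = policy or NeighborhoodPolicy()
    nbrs = select_neighbors(u, dataset, policy, model)
    sol = solve_kriging(u, nbrs, model, dataset)
    return sol.prediction, sol.variance
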