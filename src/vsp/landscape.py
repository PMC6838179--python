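"""Dense phenotype landscapes over the (x, y) plane.

A landscape is the kriging prediction z* and its variance sigma^2 evaluated
on a regular grid: x spans [0, 1] (the normalised protein sequence), y spans
the observed functional range padded by 5%.  Confidence is read from the
kriging variance — the "top q" confidence region is the fraction q of grid
cells with the smallest sigma^2.  Delta landscapes subtract two runs of the
pipeline cell by cell (e.g. treated minus control) to localise where a
perturbation moved the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import VariantDataset
from .errors import GridMismatchError
from .kriging import NeighborhoodPolicy, predict_point
from .variogram import VariogramModel


@dataclass
class PhenotypeLandscape:
    """Gridded predictions: ``z_hat`` and ``sigma2`` are (ny, nx) arrays."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    z_hat: np.ndarray
    sigma2: np.ndarray
    model: VariogramModel | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (len(self.grid_y), len(self.grid_x))
        if self.z_hat.shape != expected or self.sigma2.shape != expected:
            raise GridMismatchError(
                f"z_hat/sigma2 shape must be {expected}, got {self.z_hat.shape} "
                f"and {self.sigma2.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_hat.shape


@dataclass
class ConfidenceMask:
    """Boolean grid marking the top-``q`` confidence cells (lowest sigma^2)."""

    q: float
    threshold: float
    mask: np.ndarray


def default_grid(dataset: VariantDataset, grid_res: int = 100,
                 y_pad: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """x over [0, 1]; y over the observed range padded by ``y_pad`` per side."""
    ys = dataset.coords[:, 1]
    lo, hi = float(ys.min()), float(ys.max())
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    return (np.linspace(0.0, 1.0, grid_res),
            np.linspace(lo - y_pad * span, hi + y_pad * span, grid_res))


def build_landscape(dataset: VariantDataset, model: VariogramModel,
                    policy: NeighborhoodPolicy | None = None,
                    grid_res: int = 100,
                    grid_x: np.ndarray | None = None,
                    grid_y: np.ndarray | None = None) -> PhenotypeLandscape:
    """Evaluate the kriging predictor at every cell of a regular grid."""
    if grid_res < 2:
        raise ValueError("grid_res must be >= 2")
    policy = policy or NeighborhoodPolicy()
    if grid_x is None or grid_y is None:
        gx, gy = default_grid(dataset, grid_res)
        grid_x = gx if grid_x is None else grid_x
        grid_y = gy if grid_y is None else grid_y
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    z_hat = np.empty((len(grid_y), len(grid_x)))
    sigma2 = np.empty_like(z_hat)
    for r, yv in enumerate(grid_y):
        for c, xv in enumerate(grid_x):
            z_hat[r, c], sigma2[r, c] = predict_point((xv, yv), dataset, model, policy)
    prov = {
        "n_observations": dataset.n,
        "protein_length": dataset.protein_length,
        "axis_meta": dict(dataset.axis_meta),
        "policy": {"min_n": policy.min_n, "max_n": policy.max_n,
                   "search_radius": policy.search_radius},
    }
    return PhenotypeLandscape(grid_x, grid_y, z_hat, sigma2, model, prov)


def confidence_mask(landscape: PhenotypeLandscape, q: float) -> ConfidenceMask:
    """Cells whose kriging variance is at or below the empirical q-quantile.

    Ties at the threshold are included, so a constant sigma^2 field yields an
    all-true mask for any q.  Masks nest: q1 <= q2 implies mask(q1) is a
    subset of mask(q2).
    """
    if not (0.0 < q <= 1.0):
        raise ValueError("q must lie in (0, 1]")
    threshold = float(np.quantile(landscape.sigma2, q))
    return ConfidenceMask(q, threshold, landscape.sigma2 <= threshold)


def delta_landscape(a: PhenotypeLandscape, b: PhenotypeLandscape) -> PhenotypeLandscape:
    """Cell-wise difference b - a, with variances added (independent errors)."""
    if (len(a.grid_x) != len(b.grid_x) or len(a.grid_y) != len(b.grid_y)
            or not np.allclose(a.grid_x, b.grid_x)
            or not np.allclose(a.grid_y, b.grid_y)):
        raise GridMismatchError("landscapes must share the same grid")
    prov = {"delta_of": [a.provenance, b.provenance]}
    return PhenotypeLandscape(a.grid_x.copy(), a.grid_y.copy(),
                              b.z_hat - a.z_hat, a.sigma2 + b.sigma2,
                              model=None, provenance=prov)
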