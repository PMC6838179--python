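"""Molecular variogram: pairwise semivariance, lag binning and model fitting.

The variogram describes how the dissimilarity of the response z grows with
separation in the (x, y) plane.  For observations i and j the separation is
the Euclidean distance

    h_ij = sqrt((x_i - x_j)^2 + (y_i - y_j)^2)

and the semivariance is

    gamma_ij = (z_i - z_j)^2 / 2.

Binned means of gamma against h form the empirical variogram; a parametric
model (spherical by default) is fitted to the binned points by least squares.
The fitted *range* a is the distance beyond which observations are spatially
uncorrelated, and the *sill* c0 + c (the plateau) is the process variance.
Spatial covariance follows as C(h) = sill - gamma(h).

By convention gamma(0) = 0 exactly (kriging then interpolates the data
exactly); the nugget c0 applies to any h > 0 and models micro-scale or
measurement variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar, nnls
from scipy.spatial.distance import pdist

from .data import VariantDataset
from .errors import EmptyVariogramError, InsufficientDataError

logger = logging.getLogger(__name__)

FAMILIES = ("spherical", "linear", "exponential", "gaussian")


@dataclass
class PairRecords:
    """All unordered observation pairs (i < j) with distance and semivariance."""

    i: np.ndarray
    j: np.ndarray
    h: np.ndarray
    gamma: np.ndarray

    def __len__(self) -> int:
        return len(self.h)


@dataclass
class EmpiricalVariogram:
    """Lag-binned mean semivariance.

    Bins with no member pairs carry ``nan`` gamma and zero count; they are
    ignored during fitting.
    """

    bin_edges: np.ndarray
    bin_gamma: np.ndarray
    bin_counts: np.ndarray
    active_lag: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def populated(self) -> np.ndarray:
        return self.bin_counts > 0


@dataclass(frozen=True)
class VariogramModel:
    """A fitted variogram: family plus nugget c0, partial sill c and range a."""

    family: str
    nugget: float
    partial_sill: float
    range_: float
    rss: float = float("nan")

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError(
                f"invalid parameters: nugget={self.nugget}, "
                f"partial_sill={self.partial_sill}, range={self.range_}"
            )

    @property
    def sill(self) -> float:
        """Plateau of the variogram, C(0)."""
        return self.nugget + self.partial_sill

    def gamma(self, h) -> np.ndarray:
        return model_gamma(self, h)

    def covariance(self, h) -> np.ndarray:
        """Spatial covariance C(h) = C(0) - gamma(h); exactly sill at h = 0."""
        return self.sill - model_gamma(self, h)

    def to_dict(self) -> dict:
        return {
            "family": self.family, "nugget": self.nugget,
            "partial_sill": self.partial_sill, "sill": self.sill,
            "range": self.range_, "rss": self.rss,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(d["family"], d["nugget"], d["partial_sill"], d["range"],
                   d.get("rss", float("nan")))


def pairwise_semivariances(dataset: VariantDataset) -> PairRecords:
    """Distance and semivariance for every unordered pair of observations."""
    n = dataset.n
    if n < 2:
        raise InsufficientDataError("need at least 2 observations for pairwise analysis")
    h = pdist(dataset.coords)
    gamma = 0.5 * pdist(dataset.z[:, None], metric="sqeuclidean")
    i, j = np.triu_indices(n, k=1)
    return PairRecords(i=i, j=j, h=h, gamma=gamma)


def empirical_variogram(pairs: PairRecords, n_bins: int = 12,
                        active_lag: float | None = None) -> EmpiricalVariogram:
    """Bin pair semivariances into ``n_bins`` uniform lag intervals.

    ``active_lag`` defaults to half the maximum pair distance — beyond that
    the pair counts are too thin to inform the fit.  Pairs with h beyond the
    active lag are excluded.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if active_lag is None:
        active_lag = 0.5 * float(pairs.h.max())
    if active_lag <= 0:
        raise ValueError("active_lag must be > 0")
    inside = pairs.h <= active_lag
    if not inside.any():
        raise EmptyVariogramError(f"no pair within active lag {active_lag:g}")
    h = pairs.h[inside]
    g = pairs.gamma[inside]
    edges = np.linspace(0.0, active_lag, n_bins + 1)
    idx = np.clip(np.digitize(h, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=g, minlength=n_bins)
    gamma = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=gamma, where=counts > 0)
    return EmpiricalVariogram(edges, gamma, counts, float(active_lag))


def model_gamma(model: VariogramModel, h) -> np.ndarray:
    """Evaluate the model semivariance; gamma(0) = 0 by convention.

    Spherical: c0 + c * (1.5 h/a - 0.5 (h/a)^3) up to the range, sill beyond.
    Linear (with sill): c0 + c * h/a up to the range, sill beyond.
    Exponential / gaussian use the practical-range convention: gamma reaches
    ~95% of the sill at h = a.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("separation distance must be non-negative")
    c0, c, a = model.nugget, model.partial_sill, model.range_
    r = h / a
    if model.family == "spherical":
        out = np.where(r >= 1.0, c0 + c, c0 + c * (1.5 * r - 0.5 * r**3))
    elif model.family == "linear":
        out = c0 + c * np.minimum(r, 1.0)
    elif model.family == "exponential":
        out = c0 + c * (1.0 - np.exp(-3.0 * r))
    else:  # gaussian
        out = c0 + c * (1.0 - np.exp(-3.0 * r**2))
    out = np.where(h == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def _shape(family: str, h: np.ndarray, a: float) -> np.ndarray:
    """Unit-sill variogram shape; gamma = c0 + c * shape(h / a)."""
    r = h / a
    if family == "spherical":
        return np.where(r >= 1.0, 1.0, 1.5 * r - 0.5 * r**3)
    if family == "linear":
        return np.minimum(r, 1.0)
    if family == "exponential":
        return 1.0 - np.exp(-3.0 * r)
    return 1.0 - np.exp(-3.0 * r**2)


def _profiled_fit(a: float, family: str, h: np.ndarray,
                  g: np.ndarray) -> tuple[float, float, float]:
    """For a fixed range, (c0, c) enter linearly: solve them by NNLS.

    Returns (rss, c0, c).
    """
    X = np.column_stack([np.ones_like(h), _shape(family, h, a)])
    coef, _ = nnls(X, g)
    resid = g - X @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def fit_variogram(emp: EmpiricalVariogram, family: str = "spherical") -> VariogramModel:
    """Fit (nugget, partial sill, range) to the binned variogram.

    Minimises the unweighted residual sum of squares over the populated
    bins.  The nugget and partial sill enter the model linearly for a fixed
    range, so they are profiled out with non-negative least squares and the
    search reduces to one dimension: a fixed 400-point grid over the range
    followed by bounded scalar minimisation around the best grid point.
    The procedure is deterministic — same bins, same fit, bit for bit.
    A degenerate variogram (all bin gammas equal) returns a pure-nugget
    model with a warning rather than failing.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    keep = emp.populated & np.isfinite(emp.bin_gamma)
    h = emp.bin_centers[keep]
    g = emp.bin_gamma[keep]
    if len(h) < 3:
        raise InsufficientDataError("need at least 3 populated bins to fit a variogram")

    gmax = float(g.max())
    hmax = float(h.max())
    if gmax <= 0 or np.ptp(g) < 1e-15 * max(gmax, 1.0):
        warnings.warn("degenerate variogram (constant semivariance); returning pure nugget")
        return VariogramModel(family, gmax, 0.0, emp.active_lag, rss=0.0)

    a_lo, a_hi = 0.01 * hmax, 3.0 * hmax
    a_grid = np.linspace(a_lo, a_hi, 400)
    grid_rss = np.array([_profiled_fit(a, family, h, g)[0] for a in a_grid])
    k = int(np.argmin(grid_rss))
    lo = a_grid[max(k - 1, 0)]
    hi = a_grid[min(k + 1, len(a_grid) - 1)]
    sol = minimize_scalar(lambda a: _profiled_fit(a, family, h, g)[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-11})
    candidates = [float(a_grid[k]), float(sol.x)]
    best = min(((_profiled_fit(a, family, h, g), a) for a in candidates),
               key=lambda t: t[0][0])
    (rss, c0, c), a = best
    return VariogramModel(family, c0, c, max(a, 1e-12), rss=rss)


def fit_all_families(emp: EmpiricalVariogram) -> dict[str, VariogramModel]:
    """Fit every supported family to the same empirical variogram."""
    return {fam: fit_variogram(emp, fam) for fam in FAMILIES}
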