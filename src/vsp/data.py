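"""Variant tables and domain types.

A *variant observation* places one protein variant in the plane used for
spatial analysis: ``x`` is the residue position normalised by the full
protein length (so ``0 < x <= 1``), ``y`` is a functional coordinate chosen
per run (for example a cholesterol-accumulation score normalised to a
reference variant), and ``z`` is the response value being interpolated (for
example the trafficking index TrIdx, the endo-H-resistant fraction of a
variant's glycoforms, in [0, 1]).

Variant tables are plain delimited text with a header.  Required columns are
``label``, ``position`` and ``length``; measurement columns are selected by
an :class:`AxisConfig`.  Missing or non-numeric measurements are rejected at
load time — nothing is imputed silently.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, TableParseError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("label", "position", "length")


class TraffickingClass(enum.Enum):
    """Four-way binning of variant trafficking behaviour.

    Class I is reserved for variants with no detectable polypeptide (nonsense
    or splicing truncations); it is assigned only from an explicit null flag,
    never inferred from a trafficking index.  The remaining classes bin the
    trafficking index TrIdx: II = ER retained, III = intermediate, IV =
    significant ER export.  The boundary convention is [0, 0.2) -> II,
    [0.2, 0.5] -> III, (0.5, 1] -> IV.
    """

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


def classify_trafficking(tridx: float, is_null: bool = False) -> TraffickingClass:
    """Bin a trafficking index into classes I-IV.

    Parameters
    ----------
    tridx
        Trafficking index in [0, 1].
    is_null
        True for variants with no polypeptide expression; dominates ``tridx``.
    """
    if not (0.0 <= tridx <= 1.0):
        raise ValueError(f"trafficking index must lie in [0, 1], got {tridx!r}")
    if is_null:
        return TraffickingClass.I
    if tridx < 0.2:
        return TraffickingClass.II
    if tridx <= 0.5:
        return TraffickingClass.III
    return TraffickingClass.IV


@dataclass(frozen=True)
class VariantObservation:
    """One variant with its spatial and functional coordinates."""

    label: str
    position: int
    x: float
    y: float
    z: float
    condition: str = "CTL"
    is_null: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.label}: residue position must be >= 1")
        if not (0.0 < self.x <= 1.0):
            raise ValueError(f"{self.label}: normalised coordinate x={self.x} outside (0, 1]")
        if not (math.isfinite(self.y) and math.isfinite(self.z)):
            raise ValueError(f"{self.label}: non-finite measurement (y={self.y}, z={self.z})")


@dataclass
class VariantDataset:
    """An ordered collection of observations sharing one protein length.

    ``axis_meta`` records which table columns populated y and z and how they
    were normalised, so output files can state their provenance.
    """

    observations: list[VariantObservation]
    protein_length: int
    axis_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        for obs in self.observations:
            if obs.position > self.protein_length:
                raise ValueError(
                    f"{obs.label}: position {obs.position} exceeds protein length "
                    f"{self.protein_length}"
                )
        dupes = self.duplicate_coordinates()
        if dupes:
            for a, b in dupes:
                logger.warning(
                    "duplicate (x, y) coordinates: %s and %s at (%.6g, %.6g)",
                    a.label, b.label, a.x, a.y,
                )

    @property
    def n(self) -> int:
        return len(self.observations)

    @property
    def labels(self) -> list[str]:
        return [o.label for o in self.observations]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates."""
        return np.array([[o.x, o.y] for o in self.observations], dtype=float)

    @property
    def z(self) -> np.ndarray:
        return np.array([o.z for o in self.observations], dtype=float)

    def duplicate_coordinates(self) -> list[tuple[VariantObservation, VariantObservation]]:
        """All pairs of observations with exactly coincident (x, y)."""
        seen: dict[tuple[float, float], VariantObservation] = {}
        pairs = []
        for obs in self.observations:
            key = (obs.x, obs.y)
            if key in seen:
                pairs.append((seen[key], obs))
            else:
                seen[key] = obs
        return pairs

    def subset(self, indices: Sequence[int]) -> "VariantDataset":
        obs = [self.observations[i] for i in indices]
        return VariantDataset(obs, self.protein_length, dict(self.axis_meta))

    def drop(self, index: int) -> "VariantDataset":
        keep = [i for i in range(self.n) if i != index]
        return self.subset(keep)

    def with_z(self, z: np.ndarray) -> "VariantDataset":
        """Copy of the dataset with the response values replaced."""
        if len(z) != self.n:
            raise ValueError("z length mismatch")
        obs = [replace(o, z=float(v)) for o, v in zip(self.observations, z)]
        return VariantDataset(obs, self.protein_length, dict(self.axis_meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "position": [o.position for o in self.observations],
                "length": self.protein_length,
                "y": [o.y for o in self.observations],
                "z": [o.z for o in self.observations],
                "condition": [o.condition for o in self.observations],
                "is_null": [int(o.is_null) for o in self.observations],
            }
        )


@dataclass(frozen=True)
class AxisConfig:
    """Which table columns feed the functional axes and how to normalise them.

    ``normalize_*`` is one of ``"none"``, ``"reference"`` (divide by the raw
    value of ``reference`` — the reference variant maps to exactly 1.0) or
    ``"minmax"`` (affine map of the column onto [0, 1]).
    """

    y: str = "y"
    z: str = "z"
    normalize_y: str = "none"
    normalize_z: str = "none"
    reference: str | None = None
    condition: str = "CTL"

    def __post_init__(self) -> None:
        for mode in (self.normalize_y, self.normalize_z):
            if mode not in ("none", "reference", "minmax"):
                raise ConfigError(f"unknown normalization mode {mode!r}")
        if "reference" in (self.normalize_y, self.normalize_z) and not self.reference:
            raise ConfigError("reference normalization requested but no reference variant given")


def _normalize(values: pd.Series, mode: str, labels: pd.Series,
               reference: str | None, column: str) -> tuple[pd.Series, str]:
    if mode == "none":
        return values, "none"
    if mode == "reference":
        ref_rows = values[labels == reference]
        if ref_rows.empty:
            raise ConfigError(
                f"reference variant {reference!r} not present in table "
                f"(needed to normalize column {column!r})"
            )
        ref = float(ref_rows.iloc[0])
        if ref == 0:
            raise ConfigError(f"reference variant {reference!r} has zero value in {column!r}")
        return values / ref, f"reference:{reference}"
    # minmax
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ConfigError(f"column {column!r} is constant; min-max normalization undefined")
    return (values - lo) / (hi - lo), f"minmax:[{lo:g},{hi:g}]"


def _numeric(frame: pd.DataFrame, column: str) -> pd.Series:
    raw = frame[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableParseError(
            f"column {column!r}, row {row + 2}: cannot parse {raw.iloc[row]!r} as a number"
        )
    return out.astype(float)


def load_variant_table(path, axis_config: AxisConfig) -> VariantDataset:
    """Read a delimited variant table into a :class:`VariantDataset`.

    The delimiter is sniffed (tab or comma).  Rows with a truthy ``is_null``
    column are kept and flagged; their measurements must still be numeric.
    """
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    frame.columns = [str(c).strip() for c in frame.columns]
    for col in REQUIRED_COLUMNS + (axis_config.y, axis_config.z):
        if col not in frame.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")

    positions = _numeric(frame, "position")
    lengths = _numeric(frame, "length")
    if lengths.nunique() != 1:
        raise SchemaError("all rows must share one protein length")
    protein_length = int(lengths.iloc[0])

    labels = frame["label"].astype(str)
    y_raw = _numeric(frame, axis_config.y)
    z_raw = _numeric(frame, axis_config.z)
    y, y_prov = _normalize(y_raw, axis_config.normalize_y, labels, axis_config.reference,
                           axis_config.y)
    z, z_prov = _normalize(z_raw, axis_config.normalize_z, labels, axis_config.reference,
                           axis_config.z)

    if "is_null" in frame.columns:
        nulls = frame["is_null"].fillna(0).astype(int).astype(bool)
    else:
        nulls = pd.Series(False, index=frame.index)

    observations = [
        VariantObservation(
            label=str(lab),
            position=int(pos),
            x=float(pos) / protein_length,
            y=float(yv),
            z=float(zv),
            condition=axis_config.condition,
            is_null=bool(nv),
        )
        for lab, pos, yv, zv, nv in zip(labels, positions, y, z, nulls)
    ]
    meta = {
        "y_column": axis_config.y, "y_normalization": y_prov,
        "z_column": axis_config.z, "z_normalization": z_prov,
        "condition": axis_config.condition,
    }
    return VariantDataset(observations, protein_length, meta)


def write_variant_table(dataset: VariantDataset, path, sep: str = "\t") -> None:
    """Write a dataset back out; numeric fields round-trip at full precision."""
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def from_arrays(x: Iterable[float], y: Iterable[float], z: Iterable[float],
                protein_length: int = 10_000, condition: str = "CTL",
                labels: Iterable[str] | None = None) -> VariantDataset:
    """Build a dataset directly from coordinate arrays (simulation plumbing).

    ``x`` is quantised to the nearest residue so that x = position / length
    holds exactly; with the default length of 10000 the shift is <= 5e-5.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    z = np.asarray(list(z), dtype=float)
    positions = np.clip(np.rint(x * protein_length), 1, protein_length).astype(int)
    if labels is None:
        labels = [f"S{i + 1:04d}" for i in range(len(x))]
    obs = [
        VariantObservation(lab, int(p), float(p) / protein_length, float(yv), float(zv),
                           condition=condition)
        for lab, p, yv, zv in zip(labels, positions, y, z)
    ]
    return VariantDataset(obs, protein_length)
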