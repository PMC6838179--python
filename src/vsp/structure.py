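"""Project a phenotype landscape onto a protein structure.

Each residue r maps to the landscape column nearest x_r = r / protein_length.
Within that column the cell with the smallest kriging variance wins: its
prediction becomes the residue's value, the y coordinate of that cell its
companion value, and the variance its confidence.  Annotations are written
into the B-factor column of a PDB file (value scaled x100, clipped to
[0, 99.99]) so any molecular viewer can colour the structure by phenotype;
optionally the occupancy column carries a confidence rank in [0, 1]
(1 = most confident residue).

The PDB writer edits ATOM/HETATM records column-wise; every byte outside the
edited fields is preserved exactly, and a run with no annotations reproduces
the input byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import VspError
from .landscape import PhenotypeLandscape

RECOMMENDED_GRID_FRACTION = 0.1  # warn when grid_res < protein_length / 10


@dataclass(frozen=True)
class ResidueAnnotation:
    """Best-confidence landscape reading for one residue."""

    residue_number: int
    value: float
    companion: float
    confidence: float
    delta_value: float | None = None


@dataclass
class AnnotatedPdb:
    text: str
    matched_residues: list[int]
    unmatched_residues: list[int]


def annotate_residues(landscape: PhenotypeLandscape,
                      protein_length: int) -> list[ResidueAnnotation]:
    """One annotation per residue 1..protein_length.

    Ties in the column variance break toward the lower y value (grid_y is
    required ascending, and argmin returns the first minimum).
    """
    if landscape.z_hat.size == 0:
        raise VspError("empty landscape")
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    gy = np.asarray(landscape.grid_y, dtype=float)
    if np.any(np.diff(gy) < 0):
        raise VspError("landscape grid_y must be ascending")
    gx = np.asarray(landscape.grid_x, dtype=float)
    annotations = []
    for r in range(1, protein_length + 1):
        xr = r / protein_length
        col = int(np.argmin(np.abs(gx - xr)))
        row = int(np.argmin(landscape.sigma2[:, col]))
        annotations.append(ResidueAnnotation(
            residue_number=r,
            value=float(landscape.z_hat[row, col]),
            companion=float(gy[row]),
            confidence=float(landscape.sigma2[row, col]),
        ))
    return annotations


def annotations_to_frame(annotations: list[ResidueAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue": [a.residue_number for a in annotations],
            "value": [a.value for a in annotations],
            "companion": [a.companion for a in annotations],
            "sigma2": [a.confidence for a in annotations],
            "delta": [a.delta_value for a in annotations],
        }
    )


def _scale_b(value: float) -> str:
    return f"{min(max(value * 100.0, 0.0), 99.99):6.2f}"


def write_annotated_pdb(pdb_text: str, annotations: list[ResidueAnnotation],
                        value_field: str = "value",
                        occupancy: str | None = None,
                        residue_offset: int = 0) -> AnnotatedPdb:
    """Write annotation values into the B-factor column of a PDB.

    ``value_field`` selects the annotation attribute carried by the B-factor
    (``value``, ``confidence`` or ``delta_value``).  ``occupancy="rank"``
    additionally writes a confidence rank (1 = lowest variance) into the
    occupancy column.  ``residue_offset`` maps structure numbering onto
    annotation numbering: annotation residue = structure residue - offset.
    Atoms whose residue has no annotation keep their original B-factor and
    are reported in ``unmatched_residues``.
    """
    by_residue = {a.residue_number: a for a in annotations}
    ranks: dict[int, float] = {}
    if occupancy == "rank" and annotations:
        order = sorted(annotations, key=lambda a: (a.confidence, a.residue_number))
        m = len(order)
        for i, a in enumerate(order):
            ranks[a.residue_number] = 1.0 - i / (m - 1) if m > 1 else 1.0
    elif occupancy not in (None, "rank"):
        raise ValueError(f"unknown occupancy mode {occupancy!r}")

    lines = pdb_text.splitlines(keepends=True)
    matched: set[int] = set()
    unmatched: set[int] = set()
    out = []
    any_edit = False
    for ln, line in enumerate(lines, start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line.rstrip("\r\n")) < 66:
                raise VspError(f"malformed ATOM record at line {ln}: too short")
            try:
                resseq = int(line[22:26])
            except ValueError as exc:
                raise VspError(f"malformed ATOM record at line {ln}: bad residue number") from exc
            ann = by_residue.get(resseq - residue_offset)
            if ann is None:
                unmatched.add(resseq)
                out.append(line)
                continue
            value = getattr(ann, value_field)
            if value is None:
                unmatched.add(resseq)
                out.append(line)
                continue
            matched.add(resseq)
            new = line[:60] + _scale_b(float(value)) + line[66:]
            if occupancy == "rank":
                new = new[:54] + f"{ranks[resseq - residue_offset]:6.2f}" + new[60:]
            out.append(new)
            any_edit = True
        else:
            out.append(line)
    if annotations and not matched:
        raise VspError("no structure residue matched any annotation; check residue_offset")
    text = "".join(out)
    if any_edit:
        remark = (
            "REMARK 999 B-FACTOR CARRIES PHENOTYPE VALUE SCALED X100, CLIPPED [0,99.99]\n"
            f"REMARK 999 ANNOTATION FIELD: {value_field.upper()}\n"
        )
        text = remark + text
    return AnnotatedPdb(text, sorted(matched), sorted(unmatched))
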