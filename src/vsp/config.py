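"""Run configuration, provenance stamping and output helpers.

A :class:`RunConfig` gathers every knob the pipeline exposes — axis
selection (which measurement plays the functional coordinate y versus the
response z; swapping them re-orients the landscape without editing data),
variogram binning, model family, kriging neighbourhood, grid resolution and
seed.  Every output file is stamped with the package version and a short
fingerprint of the configuration so results are traceable to their settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from . import __version__
from .data import AxisConfig
from .kriging import NeighborhoodPolicy


@dataclass(frozen=True)
class RunConfig:
    y_column: str = "chol"
    z_column: str = "tridx"
    normalize_y: str = "none"
    normalize_z: str = "none"
    reference: str | None = None
    condition: str = "CTL"
    family: str = "spherical"
    n_bins: int = 12
    active_lag: float | None = None
    min_n: int = 5
    max_n: int = 20
    search_radius: float | None = None
    grid_res: int = 100
    confidence_q: float = 0.25
    seed: int = 0

    def axis_config(self) -> AxisConfig:
        return AxisConfig(y=self.y_column, z=self.z_column,
                          normalize_y=self.normalize_y, normalize_z=self.normalize_z,
                          reference=self.reference, condition=self.condition)

    def policy(self) -> NeighborhoodPolicy:
        return NeighborhoodPolicy(self.min_n, self.max_n, self.search_radius)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def fingerprint(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def stamp(self) -> str:
        """One-line provenance comment embedded at the top of text outputs."""
        return f"# vsp {__version__} config={self.fingerprint()} seed={self.seed}"


def write_stamped_tsv(frame, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(config.stamp() + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_stamped_json(obj: dict, path, config: RunConfig) -> None:
    payload = {"vsp_version": __version__, "config_fingerprint": config.fingerprint(),
               **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
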