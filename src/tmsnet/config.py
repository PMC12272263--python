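"""Run configuration: YAML-backed, flat keys per stage, strict validation.

Defaults carry the pipeline constants: 6x6 grid at the species spacing,
50% seed threshold, top-1% sparsity, 50% EFSI threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError
from .surface import SpeciesProfile, human_profile, macaque_profile
from . import fmri as _fmri

__all__ = ["RunConfig", "load_config"]

#: Fixed per-stage child-seed offsets so one global seed can be varied per
#: stage without perturbing the others.
SEED_OFFSETS = {"mesh": 101, "parcellation": 211, "fmri": 307}


@dataclass
class RunConfig:
    # species / surface
    species: str = "human"
    profile_overrides: dict[str, Any] = field(default_factory=dict)
    resolution: float | None = None  # vertices per mm; None -> species default
    layout: str | None = None  # None -> "<species>-default"

    # coil
    coil_radius_mm: float = 35.0
    coil_segments_per_loop: int = 64
    coil_di_dt: float = 1.0e8

    # fMRI model; amplitude 2 at sigma 1 plants within-network population
    # correlation a^2/(a^2+sigma^2) = 0.8
    n_timepoints: int | None = None  # None -> species default
    tr: float | None = None
    amplitudes: dict[int, float] = field(
        default_factory=lambda: {n: 2.0 for n in range(1, 8)}
    )
    sigma: float = 1.0
    rho: float = 0.3
    band_pass: bool = False
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1

    # thresholds & flags
    seed_fraction: float = 0.5
    sparsity: float = 0.01
    efsi_fraction: float = 0.5
    seed_normalization: str = "sum"
    rank_absolute: bool = False
    overlap_metric: str = "kept-fraction"

    # run control
    seed: int = 0
    write_field_maps: bool = True
    write_connectivity_maps: bool = True
    write_timeseries: bool = False

    def __post_init__(self) -> None:
        if self.species not in ("human", "macaque"):
            raise ParameterError(f"invalid config key 'species': {self.species!r}")
        for key in ("seed_fraction", "sparsity", "efsi_fraction"):
            v = getattr(self, key)
            if not 0 < v < 1:
                raise ParameterError(f"invalid config key '{key}': {v} not in (0, 1)")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ParameterError(f"invalid config key 'seed': {self.seed!r}")
        if self.seed_normalization not in ("sum", "max"):
            raise ParameterError(
                f"invalid config key 'seed_normalization': {self.seed_normalization!r}"
            )
        if self.overlap_metric not in ("kept-fraction", "dice"):
            raise ParameterError(
                f"invalid config key 'overlap_metric': {self.overlap_metric!r}"
            )
        self.amplitudes = {int(k): float(v) for k, v in self.amplitudes.items()}

    # ---- derived accessors -------------------------------------------------

    def profile(self) -> SpeciesProfile:
        base = human_profile if self.species == "human" else macaque_profile
        return base(**self.profile_overrides)

    def resolution_value(self) -> float:
        if self.resolution is not None:
            return self.resolution
        return 0.4 if self.species == "human" else 0.8

    def layout_name(self) -> str:
        return self.layout or f"{self.species}-default"

    def run_length(self) -> tuple[int, float]:
        if self.species == "human":
            t, tr = _fmri.HUMAN_DEFAULT_T, _fmri.HUMAN_DEFAULT_TR
        else:
            t, tr = _fmri.MACAQUE_DEFAULT_T, _fmri.MACAQUE_DEFAULT_TR
        return (self.n_timepoints or t, self.tr or tr)

    def signal_model(self) -> "_fmri.NetworkSignalModel":
        band = (self.band_low_hz, self.band_high_hz) if self.band_pass else None
        return _fmri.NetworkSignalModel(
            amplitudes=self.amplitudes, sigma=self.sigma, rho=self.rho, band=band
        )

    def stage_seed(self, stage: str) -> int:
        return self.seed + SEED_OFFSETS[stage]

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config (flat mapping of RunConfig keys); ``None`` gives the
    defaults.  Keyword overrides are applied on top and validated together."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ParameterError("config file must contain a YAML mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(raw)
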