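"""Pipeline configuration: tolerances, thresholds and acquisition defaults.

Defaults mirror the processing constants the curation protocol prescribes:
the mass-tiered wide assignment window (+/-15 ppm at m/z <= 120, +/-10 ppm
above), calibration-point intensity floor of 1e3 counts, strict < 5 ppm
reassignment, the >= 2-spectra multiplicity filter, and the recall-weighted
F_1.5 objective for the EIC-correlation cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .io import DEFAULT_NCE_LIST


@dataclass
class PipelineConfig:
    wide_tol_low_ppm: float = 15.0
    wide_tol_high_ppm: float = 10.0
    low_mass_boundary: float = 120.0
    tight_tol_ppm: float = 5.0
    precursor_match_ppm: float = 10.0
    eic_tol_ppm: float = 10.0
    min_calib_intensity: float = 1e3
    min_calib_points: int = 10
    lowess_span: float = 0.5
    multiplicity_min_count: int = 2
    match_tol_ppm: float = 5.0
    match_tol_da: float = 0.002
    f_beta: float = 1.5
    min_corr_points: int = 3
    fallback_threshold: float = 0.5
    nce_list: tuple[float, ...] = DEFAULT_NCE_LIST
    rt_window: float = 0.5
    first_mass_threshold: float = 41.0
    dbe_filter: bool = False
    correlation_method: str = "cosine"
    contributor: str = "SYNLAB"
    instrument: str = "Orbitrap Exploris 240 (Thermo Fisher Scientific)"
    instrument_type: str = "LC-ESI-QFT"
    resolution: int = 15000
    license: str = "CC BY"
    record_date: str = "2024.01.01"
    strict_reference_preset: bool = False
    strict_reference_threshold: float = 0.9
    seed: int = 1

    def effective_threshold_floor(self, level: str) -> float | None:
        """Stricter EIC cutoff floor for reference-material (Level 1) runs."""
        if self.strict_reference_preset and level == "1":
            return self.strict_reference_threshold
        return None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nce_list"] = list(self.nce_list)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "nce_list" in d:
            d["nce_list"] = tuple(d["nce_list"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
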