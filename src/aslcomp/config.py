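"""Validated pipeline configuration (YAML -> pydantic models).

All protocol constants are defaults here rather than literals buried in
code: the 225 ms finger delay, 8 cardiac-phase bins, the per-slice 95th
percentile ROI threshold, tau = 700 ms, T1,a = 1664 ms, alpha = 1.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator

from .cardiac_sync import DIASTOLE_BIN, FINGER_DELAY_MS, N_BINS, SYSTOLE_BIN
from .signal_model import T1_ARTERIAL_MS, TAU_MS

__all__ = [
    "SyncSettings",
    "FitSettings",
    "RoiSettings",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


class SyncSettings(BaseModel):
    finger_delay_ms: float = FINGER_DELAY_MS
    n_bins: int = N_BINS
    mode: str = "slice"
    count_floor: int = 3
    ref_slice: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.mode not in ("slice", "label"):
            raise ValueError("sync.mode must be 'slice' or 'label'")
        if self.n_bins < 2:
            raise ValueError("sync.n_bins must be >= 2")
        return self


class FitSettings(BaseModel):
    abv_bounds: Tuple[float, float] = (0.0, 100.0)
    dt_bounds: Tuple[float, float] = (0.0, 1500.0)
    sigma_bounds: Tuple[float, float] = (0.0, 500.0)
    sigma_init: float = 50.0
    tau_ms: float = TAU_MS
    alpha: float = 1.0
    t1a_ms: float = T1_ARTERIAL_MS
    min_points: int = 4
    decay: str = "observation"
    csf_factor: float = 1.0
    bins: Optional[List[int]] = None  # None fits every cardiac-phase bin


class RoiSettings(BaseModel):
    percentile: float = 95.0
    roi_ti_ms: float = 750.0
    dia_bin: int = DIASTOLE_BIN
    sys_bin: int = SYSTOLE_BIN
    summary_slice: Optional[int] = 4


class PipelineConfig(BaseModel):
    """Top-level run configuration, validated before any stage runs."""

    data_dir: Optional[Path] = None
    output_dir: Path = Path("aslcomp_out")
    physio_file: Optional[Path] = None
    broad_masks_file: Optional[Path] = None
    calibration_file: Optional[Path] = None
    csf_mask_file: Optional[Path] = None
    bp_readings: List[Tuple[float, float]] = Field(
        default_factory=lambda: [(115.6, 62.8)]
    )
    seed: int = 0
    sync: SyncSettings = Field(default_factory=SyncSettings)
    fit: FitSettings = Field(default_factory=FitSettings)
    roi: RoiSettings = Field(default_factory=RoiSettings)

    @model_validator(mode="after")
    def _check(self):
        for s, d in self.bp_readings:
            if not s > d > 0:
                raise ValueError(f"bad BP reading {s}/{d}")
        return self


def load_config(path: Path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable SHA-256 over the canonicalized configuration."""
    canon = yaml.safe_dump(
        yaml.safe_load(cfg.model_dump_json()), sort_keys=True
    )
    return hashlib.sha256(canon.encode()).hexdigest()
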