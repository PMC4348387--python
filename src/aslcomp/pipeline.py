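"""Pipeline orchestration: simulate / sync / fit / compliance stages.

Each stage is a plain function over in-memory objects; the CLI wraps these
and handles paths.  A motion-correction hook is provided as a pass-through
(the synthetic data are motion-free; plug in a registration callable for
real series).  Every run writes a manifest (config hash, seed, package
version) sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cardiac_sync import (
    MultiTIASLSeries,
    PhaseBinnedDelta,
    assign_phases,
    balance_report,
    detect_systolic_peaks,
    phase_binned_delta,
    shift_peaks,
    PhysioTrace,
)
from .config import PipelineConfig, config_hash
from .roi_compliance import (
    BloodPressures,
    ComplianceResult,
    compliance_map,
    percentile_mask,
    territory_rois,
    territory_summary,
)
from .voxel_fit import FitConfig, KineticParamMaps, calibrate_m0a, fit_maps

__all__ = [
    "SyncResult",
    "motion_correct",
    "run_sync",
    "run_fit",
    "run_compliance",
    "write_manifest",
]

logger = logging.getLogger(__name__)


@dataclass
class SyncResult:
    binned: PhaseBinnedDelta
    balance: pd.DataFrame
    peaks_shifted: np.ndarray


def motion_correct(series: MultiTIASLSeries,
                   method: Optional[Callable] = None) -> MultiTIASLSeries:
    """Motion-correction hook; identity by default.

    ``method`` may be any callable mapping a 4D (n_vol, nz, ny, nx) array to
    a realigned array of the same shape.
    """
    if method is None:
        return series
    data = {ti: method(arr) for ti, arr in series.data.items()}
    return MultiTIASLSeries(data=data, timing=series.timing,
                            series_start=series.series_start)


def run_sync(series: MultiTIASLSeries, physio: PhysioTrace,
             cfg: PipelineConfig) -> SyncResult:
    """Detect peaks, shift by the finger delay, assign phases, bin dM."""
    peaks = detect_systolic_peaks(physio)
    shifted = shift_peaks(peaks, cfg.sync.finger_delay_ms)
    assignments = {
        ti: assign_phases(series.timing, shifted,
                          series_start=series.series_start.get(ti, 0.0),
                          mode=cfg.sync.mode, n_bins=cfg.sync.n_bins)
        for ti in series.ti_list
    }
    binned = phase_binned_delta(series, assignments, n_bins=cfg.sync.n_bins)
    balance = balance_report(binned, ref_slice=cfg.sync.ref_slice,
                             floor=cfg.sync.count_floor)
    return SyncResult(binned=binned, balance=balance, peaks_shifted=shifted)


def fit_config_from(cfg: PipelineConfig, m0a: float = 1.0) -> FitConfig:
    f = cfg.fit
    return FitConfig(abv_bounds=f.abv_bounds, dt_bounds=f.dt_bounds,
                     sigma_bounds=f.sigma_bounds, sigma_init=f.sigma_init,
                     tau=f.tau_ms, alpha=f.alpha, t1a=f.t1a_ms, m0a=m0a,
                     min_points=f.min_points, decay=f.decay)


def run_fit(binned: PhaseBinnedDelta, cfg: PipelineConfig,
            mask: Optional[np.ndarray] = None,
            calibration: Optional[np.ndarray] = None,
            csf_mask: Optional[np.ndarray] = None,
            bins=None) -> KineticParamMaps:
    """Calibrate M0,a (if a calibration image is given) and fit all bins."""
    m0a = 1.0
    if calibration is not None and csf_mask is not None:
        m0a = calibrate_m0a(calibration, csf_mask, cfg.fit.csf_factor)
        logger.info("calibrated M0,a = %.4g", m0a)
    if bins is None:
        bins = cfg.fit.bins
    return fit_maps(binned, fit_config_from(cfg, m0a), mask=mask, bins=bins)


def roi_delta_m_image(binned_full: Dict[float, np.ndarray],
                      roi_ti: float) -> np.ndarray:
    """Mean dM volume of the full (unbinned) series at the ROI-defining TI."""
    return binned_full[roi_ti]


def mean_delta_m(series: MultiTIASLSeries, ti: float) -> np.ndarray:
    """Whole-series mean control-minus-tag volume for one TI."""
    arr = series.data[ti]
    labels = np.array(series.timing.label_order)
    return (arr[labels == "control"].mean(axis=0)
            - arr[labels == "tag"].mean(axis=0))


def run_compliance(maps: KineticParamMaps, series: MultiTIASLSeries,
                   broad_masks: np.ndarray, cfg: PipelineConfig,
                   names=None) -> ComplianceResult:
    """ROIs from the mean dM image, compliance map, territory medians."""
    bp = BloodPressures.from_readings(cfg.bp_readings)
    mean_dm = mean_delta_m(series, cfg.roi.roi_ti_ms)
    vessel_mask = percentile_mask(mean_dm, cfg.roi.percentile)
    rois = territory_rois(vessel_mask, broad_masks, names=names)
    abv_dia = maps.abv[cfg.roi.dia_bin]
    abv_sys = maps.abv[cfg.roi.sys_bin]
    ac = compliance_map(abv_dia, abv_sys, bp)
    summary = territory_summary(
        {"ac": ac, "abv_dia": abv_dia, "abv_sys": abv_sys,
         "dt_dia": maps.dt[cfg.roi.dia_bin], "dt_sys": maps.dt[cfg.roi.sys_bin],
         "sigma_dia": maps.sigma[cfg.roi.dia_bin],
         "sigma_sys": maps.sigma[cfg.roi.sys_bin]},
        rois, slice_index=cfg.roi.summary_slice,
    )
    return ComplianceResult(ac_map=ac, abv_dia_map=abv_dia,
                            abv_sys_map=abv_sys, bp=bp, summary=summary)


def write_manifest(outdir: Path, cfg: PipelineConfig,
                   stage_seconds: Optional[Dict[str, float]] = None) -> Path:
    """Reproducibility manifest; deterministic for a fixed config and seed.

    Per-stage wall times go to the run log, not the manifest, so re-runs of
    the same configuration produce byte-identical manifests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage_seconds:
        for stage, sec in stage_seconds.items():
            logger.info("stage %s: %.2f s", stage, sec)
    manifest = {
        "package": "aslcomp",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": config_hash(cfg),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
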