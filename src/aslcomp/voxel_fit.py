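"""Voxel-wise least-squares estimation of aBV, arrival time, and dispersion.

For each cardiac-phase bin the arterial kinetic model is fit to the seven
phase-binned dM values (one per inversion time, slice-delay corrected) by
bounded nonlinear least squares, yielding per-bin maps of arterial blood
volume (%v), bolus arrival time (ms), dispersion width (ms), and a fit
residual error.  The bolus duration tau is fixed by the QUIPSS II cut-off
and is not fitted; M0,a is calibrated once from the CSF signal of a fully
relaxed acquisition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import CalibrationError
from .cardiac_sync import PhaseBinnedDelta
from .signal_model import (
    ArterialParams,
    T1_ARTERIAL_MS,
    TAU_MS,
    arterial_delta_m,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "KineticParamMaps",
    "calibrate_m0a",
    "effective_ti",
    "fit_voxel",
    "fit_maps",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the voxel-wise arterial model fit.

    Bounds and initial values are package choices (the optimizer family is
    standard bounded least squares); all are exposed here.  ``sigma_init``
    seeds the dispersion width; aBV and dt are initialized from the data
    (plateau closed form and 10%-of-max arrival heuristic).
    """

    abv_bounds: tuple = (0.0, 100.0)  # %v
    dt_bounds: tuple = (0.0, 1500.0)  # ms
    sigma_bounds: tuple = (0.0, 500.0)  # ms
    sigma_init: float = 50.0
    tau: float = TAU_MS
    alpha: float = 1.0
    t1a: float = T1_ARTERIAL_MS
    m0a: float = 1.0
    min_points: int = 4
    decay: str = "observation"
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self) -> None:
        for lo, hi in (self.abv_bounds, self.dt_bounds, self.sigma_bounds):
            if not lo < hi:
                raise ValueError("each bounds pair must satisfy lo < hi")
        if not self.sigma_bounds[0] <= self.sigma_init <= self.sigma_bounds[1]:
            raise ValueError("sigma_init must lie within sigma_bounds")
        if self.min_points < 4:
            raise ValueError("min_points must be >= 4 (3 parameters + 1 dof)")


class FitResult(NamedTuple):
    """Per-voxel fit outcome; NaN fields mark an unfit/failed voxel."""

    abv: float  # %v
    dt: float  # ms
    sigma: float  # ms
    rmse: float
    success: bool


@dataclass
class KineticParamMaps:
    """Voxel-wise kinetic parameter maps per cardiac-phase bin.

    Arrays have shape (n_bins, nz, ny, nx); NaN marks voxels outside the
    mask, with too few dM values, or with a failed fit.
    """

    abv: np.ndarray
    dt: np.ndarray
    sigma: np.ndarray
    rmse: np.ndarray
    bins: tuple = ()
    n_failed: int = 0


def effective_ti(nominal_ti: float, slice_index: int, slice_delay: float) -> float:
    """Inversion time of a slice: nominal TI plus its acquisition delay."""
    if slice_index < 0:
        raise ValueError("slice_index must be >= 0")
    return nominal_ti + slice_index * slice_delay


def calibrate_m0a(m0_image: np.ndarray, csf_mask: np.ndarray,
                  factor: float = 1.0) -> float:
    """Arterial equilibrium magnetization from the CSF of a calibration scan.

    M0,a = median(M0 over the CSF mask) * ``factor``, where ``factor`` is the
    CSF-to-arterial-blood conversion (relative proton density and any
    relaxation correction); it is exposed, not hard-coded.
    """
    csf_mask = np.asarray(csf_mask, dtype=bool)
    if not csf_mask.any():
        raise CalibrationError("CSF mask is empty; cannot calibrate M0,a")
    return float(np.median(np.asarray(m0_image, dtype=float)[csf_mask]) * factor)


def _initial_guess(tis: np.ndarray, dm: np.ndarray, cfg: FitConfig) -> np.ndarray:
    peak = float(dm.max())
    i_peak = int(np.argmax(dm))
    if peak > 0:
        # plateau closed form at the peak TI
        abv0 = 100.0 * peak / (2.0 * cfg.alpha * cfg.m0a *
                               np.exp(-tis[i_peak] / cfg.t1a))
        above = np.nonzero(dm > 0.1 * peak)[0]
        dt0 = float(tis[above[0]]) if above.size else float(np.median(tis))
    else:
        abv0 = 0.0
        dt0 = float(np.median(tis))
    eps = 1e-9
    x0 = np.array([
        np.clip(abv0, cfg.abv_bounds[0] + eps, cfg.abv_bounds[1] - eps),
        np.clip(dt0, cfg.dt_bounds[0] + eps, cfg.dt_bounds[1] - eps),
        np.clip(cfg.sigma_init, cfg.sigma_bounds[0] + eps, cfg.sigma_bounds[1] - eps),
    ])
    return x0


def fit_voxel(tis, delta_m, cfg: FitConfig = FitConfig()) -> FitResult:
    """Fit (aBV, dt, sigma) to one voxel's dM values at effective TIs.

    Missing (NaN) dM values are dropped; fewer than ``cfg.min_points``
    remaining points leaves the voxel unfit.  The reported error is the
    degrees-of-freedom-adjusted residual standard error
    sqrt(SS/(n - 3)), an unbiased-variance estimate of the noise level.
    Deterministic: fixed data give a fixed result (no random restarts).
    """
    tis = np.asarray(tis, dtype=float)
    dm = np.asarray(delta_m, dtype=float)
    keep = np.isfinite(dm) & np.isfinite(tis)
    tis, dm = tis[keep], dm[keep]
    n = tis.size
    if n < cfg.min_points:
        return FitResult(np.nan, np.nan, np.nan, np.nan, False)

    def residuals(x):
        p = ArterialParams(abv=x[0], dt=x[1], sigma=x[2], tau=cfg.tau,
                           alpha=cfg.alpha, t1a=cfg.t1a, m0a=cfg.m0a)
        return arterial_delta_m(tis, p, decay=cfg.decay) - dm

    x0 = _initial_guess(tis, dm, cfg)
    lo = [cfg.abv_bounds[0], cfg.dt_bounds[0], cfg.sigma_bounds[0]]
    hi = [cfg.abv_bounds[1], cfg.dt_bounds[1], cfg.sigma_bounds[1]]
    try:
        res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            x_scale=[1.0, 100.0, 50.0],
                            xtol=cfg.xtol, ftol=cfg.ftol, gtol=cfg.gtol)
    except Exception:  # pragma: no cover - defensive
        logger.exception("voxel fit raised")
        return FitResult(np.nan, np.nan, np.nan, np.nan, False)
    if not res.success:
        return FitResult(np.nan, np.nan, np.nan, np.nan, False)
    dof = max(n - 3, 1)
    rmse = float(np.sqrt(np.sum(res.fun**2) / dof))
    return FitResult(float(res.x[0]), float(res.x[1]), float(res.x[2]),
                     rmse, True)


def fit_maps(binned: PhaseBinnedDelta, cfg: FitConfig = FitConfig(),
             mask: Optional[np.ndarray] = None,
             bins: Optional[Sequence[int]] = None) -> KineticParamMaps:
    """Fit the arterial model voxel-by-voxel for the requested phase bins.

    ``mask`` (nz, ny, nx) restricts fitting to a processing mask; without
    one every voxel is attempted.  Per-voxel failures are recorded, never
    raised, so a bad voxel cannot abort a map.
    """
    n_ti, n_bins, nz, ny, nx = binned.delta_m.shape
    if bins is None:
        bins = range(n_bins)
    bins = tuple(int(b) for b in bins)
    if mask is None:
        mask = np.ones((nz, ny, nx), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("fit_maps: empty processing mask; maps are all NaN",
                      stacklevel=2)

    shape = (n_bins, nz, ny, nx)
    out = {k: np.full(shape, np.nan) for k in ("abv", "dt", "sigma", "rmse")}
    tis = np.asarray(binned.ti_list, dtype=float)
    n_failed = 0
    for b in bins:
        for z in range(nz):
            tis_eff = tis + z * binned.slice_delay
            for y, x in zip(*np.nonzero(mask[z])):
                r = fit_voxel(tis_eff, binned.delta_m[:, b, z, y, x], cfg)
                if not r.success:
                    n_failed += 1
                    continue
                out["abv"][b, z, y, x] = r.abv
                out["dt"][b, z, y, x] = r.dt
                out["sigma"][b, z, y, x] = r.sigma
                out["rmse"][b, z, y, x] = r.rmse
    if n_failed:
        logger.info("fit_maps: %d voxel fits failed or were skipped", n_failed)
    return KineticParamMaps(abv=out["abv"], dt=out["dt"], sigma=out["sigma"],
                            rmse=out["rmse"], bins=bins, n_failed=n_failed)
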