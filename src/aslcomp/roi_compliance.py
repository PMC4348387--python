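"""Flow-territory ROIs and arterial compliance maps.

Large-vessel voxels are selected per slice as the top 5% of the mean
TI = 750 ms dM image (the TI with maximal arterial contrast), intersected
with broad hand-drawn (or phantom) territory masks for the right/left middle,
right/left posterior, and anterior cerebral arteries.  Arterial compliance is
the diastole-normalized change in arterial blood volume per unit pulse
pressure:

    AC = 100 * (aBV_sys - aBV_dia) / (aBV_dia * PP)   [% / mm Hg]

Multiplying AC by the pulse pressure gives the percent aBV change over the
cardiac cycle.  Territory values are summarized as medians on a chosen slice
(just above the circle of Willis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidPressureError

__all__ = [
    "BloodPressures",
    "ROISet",
    "ComplianceResult",
    "percentile_mask",
    "territory_rois",
    "compliance_map",
    "territory_summary",
    "cycle_change",
]

#: canonical territory names (single ACA: left/right not separable at this
#: voxel size)
TERRITORIES = ("RMCA", "LMCA", "ACA", "RPCA", "LPCA")


@dataclass(frozen=True)
class BloodPressures:
    """Brachial cuff pressures in mm Hg; PP = systolic - diastolic."""

    bp_sys: float
    bp_dia: float

    def __post_init__(self) -> None:
        if not self.bp_sys > self.bp_dia > 0:
            raise InvalidPressureError(
                f"need bp_sys > bp_dia > 0, got {self.bp_sys}/{self.bp_dia}"
            )

    @property
    def pp(self) -> float:
        return self.bp_sys - self.bp_dia

    @classmethod
    def from_readings(cls, readings: Sequence[Sequence[float]]) -> "BloodPressures":
        """Average repeated (systolic, diastolic) cuff readings (one per scan)."""
        arr = np.asarray(readings, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("readings must be a sequence of (sys, dia) pairs")
        return cls(bp_sys=float(arr[:, 0].mean()), bp_dia=float(arr[:, 1].mean()))


@dataclass
class ROISet:
    """Labeled territory masks after percentile thresholding.

    ``labels`` is an integer volume (nz, ny, nx); ``names`` maps label
    values (> 0) to territory names.
    """

    labels: np.ndarray
    names: Dict[int, str]
    thresholds: Dict[int, float] = field(default_factory=dict)

    def mask(self, territory: str) -> np.ndarray:
        for value, name in self.names.items():
            if name == territory:
                return self.labels == value
        raise KeyError(territory)


@dataclass
class ComplianceResult:
    """Compliance map with its inputs and per-territory medians."""

    ac_map: np.ndarray
    abv_dia_map: np.ndarray
    abv_sys_map: np.ndarray
    bp: BloodPressures
    summary: pd.DataFrame


def percentile_mask(image: np.ndarray, pct: float = 95.0) -> np.ndarray:
    """Per-slice top-(100-pct)% intensity mask of a 3D image.

    The threshold is computed independently for each slice (axis 0) and
    voxels strictly above it are kept, so ties at the threshold are excluded
    and counts stay minimal.  A constant slice keeps no voxels (warning).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3:
        raise ValueError("expected a 3D image (nz, ny, nx)")
    mask = np.zeros(img.shape, dtype=bool)
    for z in range(img.shape[0]):
        sl = img[z]
        if sl.size < 20:
            warnings.warn(f"slice {z}: fewer than 20 voxels", stacklevel=2)
        if np.ptp(sl) == 0:
            warnings.warn(f"slice {z}: constant intensity, empty slice mask",
                          stacklevel=2)
            continue
        mask[z] = sl > np.percentile(sl, pct)
    return mask


def territory_rois(mask: np.ndarray, broad_masks: np.ndarray,
                   names: Optional[Mapping[int, str]] = None) -> ROISet:
    """Intersect the thresholded vessel mask with broad territory masks.

    ``broad_masks`` is an integer label volume with disjoint labels (one per
    territory); each ROI is the elementwise product with the binary mask.
    Empty ROIs are retained with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    broad = np.asarray(broad_masks)
    if broad.shape != mask.shape:
        raise ValueError("broad_masks and mask shapes differ")
    labels = np.where(mask, broad, 0)
    values = [int(v) for v in np.unique(broad) if v != 0]
    if names is None:
        names = {v: (TERRITORIES[i] if i < len(TERRITORIES) else f"ROI{v}")
                 for i, v in enumerate(values)}
    else:
        names = dict(names)
    for v in values:
        if not (labels == v).any():
            warnings.warn(f"territory {names.get(v, v)}: empty ROI after "
                          "thresholding", stacklevel=2)
    return ROISet(labels=labels, names=names)


def compliance_map(abv_dia: np.ndarray, abv_sys: np.ndarray,
                   bp: BloodPressures) -> np.ndarray:
    """Arterial compliance map: 100*(aBV_sys - aBV_dia)/(aBV_dia * PP).

    Defined only where the diastolic aBV is positive; elsewhere NaN (guarded
    division, never infinity).  Units %/mm Hg.
    """
    if bp.pp <= 0:
        raise InvalidPressureError(f"pulse pressure must be > 0, got {bp.pp}")
    dia = np.asarray(abv_dia, dtype=float)
    sys_ = np.asarray(abv_sys, dtype=float)
    ac = np.full(dia.shape, np.nan)
    ok = np.isfinite(dia) & np.isfinite(sys_) & (dia > 0)
    ac[ok] = 100.0 * (sys_[ok] - dia[ok]) / (dia[ok] * bp.pp)
    return ac


def territory_summary(maps: Mapping[str, np.ndarray], rois: ROISet,
                      slice_index: Optional[int] = None) -> pd.DataFrame:
    """Median of each map over each territory ROI (tidy long format).

    ``maps`` maps a parameter name to a 3D volume; with ``slice_index`` the
    median is restricted to that slice (just above the circle of Willis).
    The median — not the mean — is used for robustness to residual outlier
    voxels.  Empty ROIs yield a missing (NaN) entry.
    """
    rows = []
    for value, name in sorted(rois.names.items()):
        roi = rois.labels == value
        if slice_index is not None:
            sel = np.zeros_like(roi)
            sel[slice_index] = roi[slice_index]
            roi = sel
        for param, vol in maps.items():
            vals = np.asarray(vol, dtype=float)[roi]
            vals = vals[np.isfinite(vals)]
            rows.append({
                "territory": name,
                "parameter": param,
                "n_voxels": int(vals.size),
                "median": float(np.median(vals)) if vals.size else np.nan,
            })
    return pd.DataFrame(rows)


def cycle_change(ac, pp: float):
    """Percent aBV change over the cardiac cycle: AC * PP."""
    if pp <= 0:
        raise InvalidPressureError(f"pulse pressure must be > 0, got {pp}")
    return np.asarray(ac, dtype=float) * pp if np.ndim(ac) else float(ac) * pp
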