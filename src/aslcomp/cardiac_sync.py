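"""Retrospective synchronization of ASL acquisitions to the cardiac cycle.

A finger-plethysmograph trace is reduced to systolic peak times, shifted
backwards by the finger transit delay (~225 ms) so peaks mark cerebral
systole, and each acquired slice is assigned a normalized cardiac phase

    phi_c = (t_acq - t1) / (t2 - t1)

where t1/t2 are the shifted peaks bracketing the slice acquisition time.
Phases advance linearly from 0 to 1 within a beat and reset at the next.
The cycle is partitioned into eight half-open bins [k/8, (k+1)/8); by
convention bin 1 is "early diastole" and bin 6 is "early systole".  Per
inversion time and bin, tag and control volumes are averaged and subtracted
to give phase-resolved dM maps, with tag/control counts tracked to detect
synchronization bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import OutOfTraceError, UnusableTraceError

__all__ = [
    "PhysioTrace",
    "AcquisitionTiming",
    "PhaseAssignment",
    "PhaseBinnedDelta",
    "MultiTIASLSeries",
    "detect_systolic_peaks",
    "shift_peaks",
    "cardiac_phase",
    "assign_phases",
    "phase_binned_delta",
    "balance_report",
    "label_mode_phase_span",
]

logger = logging.getLogger(__name__)

#: default finger-pulse transit delay relative to cerebral systole, ms
FINGER_DELAY_MS = 225.0
#: default number of cardiac-phase bins
N_BINS = 8
#: bin index of early diastole ([1/8, 2/8)) and early systole ([6/8, 7/8))
DIASTOLE_BIN = 1
SYSTOLE_BIN = 6

# physiological bounds on the inter-beat interval, ms
_RR_MIN_MS = 250.0
_RR_MAX_MS = 2000.0


@dataclass(frozen=True)
class PhysioTrace:
    """Uniformly sampled pulse waveform on the acquisition clock."""

    samples: np.ndarray
    fs: float  # Hz
    t0: float = 0.0  # ms

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0 Hz, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("physio trace is empty")

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + np.arange(self.samples.size) * 1000.0 / self.fs


@dataclass(frozen=True)
class AcquisitionTiming:
    """Protocol timing of a multi-TI tag/control acquisition.

    ``label_order`` marks each volume of a series as ``"tag"`` or
    ``"control"``; the default alternates starting with tag.  Tag/control
    identity always comes from this metadata, never from image intensities.
    """

    tr: float = 1400.0
    ti_list: tuple = (250.0, 350.0, 450.0, 550.0, 650.0, 750.0, 850.0)
    n_pairs: int = 80
    n_slices: int = 14
    slice_delay: float = 29.0
    quipss_cutoff: float = 700.0
    label_order: tuple = ()

    def __post_init__(self) -> None:
        tis = tuple(float(ti) for ti in self.ti_list)
        object.__setattr__(self, "ti_list", tis)
        if any(b <= a for a, b in zip(tis, tis[1:])):
            raise ValueError("ti_list must be strictly increasing")
        if self.tr <= max(tis):
            raise ValueError("TR must exceed the longest TI")
        if self.slice_delay < 0:
            raise ValueError("slice_delay must be >= 0")
        if not self.label_order:
            order = ("tag", "control") * self.n_pairs
            object.__setattr__(self, "label_order", order)
        else:
            order = tuple(self.label_order)
            if len(order) != 2 * self.n_pairs:
                raise ValueError("label_order length must equal 2*n_pairs")
            if set(order) - {"tag", "control"}:
                raise ValueError("label_order entries must be 'tag' or 'control'")
            object.__setattr__(self, "label_order", order)

    @property
    def n_volumes(self) -> int:
        return 2 * self.n_pairs


@dataclass(frozen=True)
class PhaseAssignment:
    """Cardiac phase and bin per (volume, slice) of one TI series.

    ``valid`` is False for volumes whose timestamps fall outside the physio
    trace (dropped, not errored).
    """

    phi: np.ndarray  # (n_volumes, n_slices), NaN where invalid
    bin_index: np.ndarray  # (n_volumes, n_slices), -1 where invalid
    valid: np.ndarray  # (n_volumes,) bool
    mode: str
    n_bins: int = N_BINS


@dataclass
class MultiTIASLSeries:
    """Per-TI stacks of tag/control volumes with acquisition timing.

    ``data`` maps each TI (ms) to an array of shape
    (n_volumes, n_slices, ny, nx), slices in ascending acquisition order.
    ``series_start`` maps each TI to the acquisition time (ms, physio clock)
    of the first slice of that series' first volume.
    """

    data: Dict[float, np.ndarray]
    timing: AcquisitionTiming
    series_start: Dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ti, arr in self.data.items():
            if arr.shape[0] != self.timing.n_volumes:
                raise ValueError(
                    f"TI {ti}: expected {self.timing.n_volumes} volumes, "
                    f"got {arr.shape[0]}"
                )
            if arr.shape[1] != self.timing.n_slices:
                raise ValueError(
                    f"TI {ti}: expected {self.timing.n_slices} slices, "
                    f"got {arr.shape[1]}"
                )

    @property
    def ti_list(self) -> tuple:
        return tuple(sorted(self.data))


@dataclass(frozen=True)
class PhaseBinnedDelta:
    """Phase-resolved dM maps per (TI, bin) with tag/control accounting.

    ``delta_m`` has shape (n_ti, n_bins, nz, ny, nx) and is NaN wherever a
    bin lacks tag or control data at a slice.  Counts are per (TI, bin,
    slice) because slices of one volume may land in different bins.
    """

    delta_m: np.ndarray
    n_tag: np.ndarray  # (n_ti, n_bins, nz)
    n_control: np.ndarray
    ti_list: tuple
    slice_delay: float
    n_bins: int = N_BINS


def detect_systolic_peaks(trace: PhysioTrace, band=(0.5, 8.0),
                          refractory_ms: float = 250.0) -> np.ndarray:
    """Detect systolic peak times (ms) in a plethysmograph trace.

    The trace is band-pass filtered (default 0.5-8 Hz, zero phase) and local
    maxima are located with a refractory period and a prominence floor of a
    quarter of the filtered peak-to-peak amplitude.  Inter-peak intervals
    outside physiological bounds (250-2000 ms) are logged as warnings.
    """
    x = trace.samples
    if np.ptp(x) == 0:
        raise UnusableTraceError("flat physio trace: no pulse detected")
    nyq = trace.fs / 2.0
    hi = min(band[1], 0.9 * nyq)
    lo = min(band[0], 0.5 * hi)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=trace.fs, output="sos")
    xf = sps.sosfiltfilt(sos, x)
    distance = max(1, int(round(refractory_ms * trace.fs / 1000.0)))
    prominence = 0.25 * np.ptp(xf)
    idx, _ = sps.find_peaks(xf, distance=distance, prominence=prominence)
    if idx.size < 2:
        raise UnusableTraceError(
            f"only {idx.size} systolic peak(s) detected; need at least 2"
        )
    peaks = trace.t0 + idx * 1000.0 / trace.fs
    rr = np.diff(peaks)
    bad = (rr < _RR_MIN_MS) | (rr > _RR_MAX_MS)
    if bad.any():
        logger.warning(
            "%d of %d inter-peak intervals outside %g-%g ms",
            int(bad.sum()), rr.size, _RR_MIN_MS, _RR_MAX_MS,
        )
    return peaks


def shift_peaks(peaks, delay: float = FINGER_DELAY_MS) -> np.ndarray:
    """Shift peak times earlier by the finger transit delay (ms).

    The cerebral pulse precedes the finger pulse, so subtracting ``delay``
    aligns plethysmograph peaks with cerebral systole.
    """
    if delay < 0:
        raise ValueError(f"delay must be >= 0 ms, got {delay}")
    return np.asarray(peaks, dtype=float) - delay


def cardiac_phase(t_acq, peaks) -> np.ndarray:
    """Normalized cardiac phase in [0, 1) of acquisition time(s).

    phi = (t_acq - t1)/(t2 - t1) with t1 <= t_acq < t2 the bracketing
    (shifted) systolic peaks.  Raises :class:`OutOfTraceError` if any time
    lies outside [first peak, last peak).
    """
    peaks = np.asarray(peaks, dtype=float)
    t = np.asarray(t_acq, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < peaks[0]) or np.any(t >= peaks[-1]):
        raise OutOfTraceError(
            "acquisition time outside the peak-covered interval "
            f"[{peaks[0]:.0f}, {peaks[-1]:.0f}) ms"
        )
    i = np.searchsorted(peaks, t, side="right") - 1
    phi = (t - peaks[i]) / (peaks[i + 1] - peaks[i])
    return float(phi[0]) if scalar else phi


def assign_phases(timing: AcquisitionTiming, peaks, series_start: float = 0.0,
                  mode: str = "slice", n_bins: int = N_BINS) -> PhaseAssignment:
    """Assign a cardiac phase and bin to every (volume, slice) of one series.

    In ``"slice"`` mode (default) the slice's own acquisition time
    ``series_start + v*TR + s*slice_delay`` is used; in ``"label"`` mode
    every slice of a volume inherits the phase of the volume start, so the
    whole stack is sorted by the cardiac phase of the labeling event.
    Volumes with any timestamp outside the peak range are dropped with a
    logged warning.
    """
    if mode not in ("slice", "label"):
        raise ValueError(f"mode must be 'slice' or 'label', got {mode!r}")
    peaks = np.asarray(peaks, dtype=float)
    nv, ns = timing.n_volumes, timing.n_slices
    vol_start = series_start + np.arange(nv) * timing.tr
    if mode == "slice":
        t_acq = vol_start[:, None] + np.arange(ns) * timing.slice_delay
    else:
        t_acq = np.broadcast_to(vol_start[:, None], (nv, ns)).copy()

    phi = np.full((nv, ns), np.nan)
    bins = np.full((nv, ns), -1, dtype=int)
    inside = (t_acq >= peaks[0]) & (t_acq < peaks[-1])
    valid = inside.all(axis=1)
    if not valid.all():
        logger.warning(
            "dropping %d of %d volumes with timestamps outside the physio trace",
            int((~valid).sum()), nv,
        )
    if valid.any():
        phi[valid] = cardiac_phase(t_acq[valid], peaks)
        bins[valid] = np.floor(n_bins * phi[valid]).astype(int)
        # guard against phi numerically equal to 1.0
        bins[valid] = np.clip(bins[valid], 0, n_bins - 1)
    return PhaseAssignment(phi=phi, bin_index=bins, valid=valid,
                           mode=mode, n_bins=n_bins)


def phase_binned_delta(series: MultiTIASLSeries,
                       assignments: Mapping[float, PhaseAssignment],
                       n_bins: int = N_BINS) -> PhaseBinnedDelta:
    """Average tag and control images per (TI, bin, slice) and subtract.

    dM = mean(control) - mean(tag) per bin; slices where a bin lacks either
    tag or control volumes get NaN (missing is represented, not raised).
    """
    ti_list = series.ti_list
    timing = series.timing
    labels = np.array(timing.label_order)
    is_tag = labels == "tag"
    ns = timing.n_slices
    first = series.data[ti_list[0]]
    ny, nx = first.shape[2], first.shape[3]

    dm = np.full((len(ti_list), n_bins, ns, ny, nx), np.nan)
    n_tag = np.zeros((len(ti_list), n_bins, ns), dtype=int)
    n_con = np.zeros_like(n_tag)

    for i, ti in enumerate(ti_list):
        arr = series.data[ti]
        asg = assignments[ti]
        for s in range(ns):
            b_of_vol = asg.bin_index[:, s]
            for b in range(n_bins):
                in_bin = (b_of_vol == b) & asg.valid
                tag_sel = in_bin & is_tag
                con_sel = in_bin & ~is_tag
                n_tag[i, b, s] = int(tag_sel.sum())
                n_con[i, b, s] = int(con_sel.sum())
                if n_tag[i, b, s] and n_con[i, b, s]:
                    dm[i, b, s] = (
                        arr[con_sel, s].mean(axis=0) - arr[tag_sel, s].mean(axis=0)
                    )
    return PhaseBinnedDelta(delta_m=dm, n_tag=n_tag, n_control=n_con,
                            ti_list=ti_list, slice_delay=timing.slice_delay,
                            n_bins=n_bins)


def balance_report(binned: PhaseBinnedDelta, ref_slice: int = 0,
                   floor: int = 3) -> pd.DataFrame:
    """Tabulate tag/control counts per (TI, bin) at a reference slice.

    Bins with a tag or control count below ``floor`` are flagged: a bin
    starved of either image type yields a noisy or undefined dM there.
    """
    rows = []
    for i, ti in enumerate(binned.ti_list):
        for b in range(binned.n_bins):
            nt = int(binned.n_tag[i, b, ref_slice])
            nc = int(binned.n_control[i, b, ref_slice])
            rows.append({
                "ti": ti, "bin": b, "n_tag": nt, "n_control": nc,
                "flagged": (nt < floor) or (nc < floor),
            })
    return pd.DataFrame(rows)


def label_mode_phase_span(timing: AcquisitionTiming, rr_ms: float) -> float:
    """Cardiac-phase span of the slice stack when sorted by label phase.

    With all slices of a volume assigned the labeling phase, the most distal
    slice is acquired ``n_slices * slice_delay`` ms later than the label, a
    phase offset of that interval over the R-R interval (0.406 for 14 slices
    at 29 ms and a 1000 ms R-R).
    """
    if rr_ms <= 0:
        raise ValueError("rr_ms must be > 0")
    return timing.n_slices * timing.slice_delay / rr_ms
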