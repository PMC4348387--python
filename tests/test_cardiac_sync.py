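"""Cardiac synchronization: peak detection, phase arithmetic, binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aslcomp import (
    AcquisitionTiming,
    MultiTIASLSeries,
    PhysioTrace,
    assign_phases,
    balance_report,
    cardiac_phase,
    detect_systolic_peaks,
    generate_physio,
    phase_binned_delta,
    shift_peaks,
)
from aslcomp.cardiac_sync import label_mode_phase_span
from aslcomp.exceptions import OutOfTraceError, UnusableTraceError


def test_detect_peaks_on_constructed_beats():
    """Beats planted at 0, 1000, 2000, ... ms are found within one sample."""
    trace, beats = generate_physio(hr_mean=60.0, hr_sd=0.0, duration=10_000.0,
                                   fs=200.0, finger_delay=0.0, seed=0, t0=-2000.0)
    peaks = detect_systolic_peaks(trace)
    sample_ms = 1000.0 / trace.fs
    for p in peaks:
        assert np.min(np.abs(beats - p)) <= sample_ms + 1e-9


def test_detect_peaks_flat_trace_unusable():
    with pytest.raises(UnusableTraceError):
        detect_systolic_peaks(PhysioTrace(samples=np.ones(1000), fs=100.0))


def test_detect_peaks_mean_interval_matches_heart_rate():
    """Two minutes at 65 bpm: mean inter-peak interval within 2% of 60000/65."""
    trace, _ = generate_physio(hr_mean=65.0, hr_sd=2.0, duration=120_000.0, seed=3)
    rr = np.diff(detect_systolic_peaks(trace))
    assert np.mean(rr) == pytest.approx(60000.0 / 65.0, rel=0.02)


def test_shift_peaks_values_and_round_trip():
    np.testing.assert_allclose(shift_peaks([1000.0, 2000.0], 225.0), [775.0, 1775.0])
    peaks = np.array([500.0, 1400.0, 2300.0])
    np.testing.assert_array_equal(shift_peaks(peaks, 0.0), peaks)
    # round trip: shifting then un-shifting recovers the original times
    np.testing.assert_allclose(shift_peaks(peaks, 225.0) + 225.0, peaks)
    with pytest.raises(ValueError):
        shift_peaks(peaks, -10.0)


@pytest.mark.parametrize("t_acq, expected", [
    (250.0, 0.25),
    (0.0, 0.0),
    (999.9, 0.9999),
])
def test_cardiac_phase_linear_ramp(t_acq, expected):
    assert cardiac_phase(t_acq, [0.0, 1000.0, 2000.0]) == pytest.approx(expected)


def test_cardiac_phase_outside_trace_raises():
    with pytest.raises(OutOfTraceError):
        cardiac_phase(2500.0, [0.0, 1000.0, 2000.0])
    with pytest.raises(OutOfTraceError):
        cardiac_phase(-1.0, [0.0, 1000.0, 2000.0])


@given(st.floats(0.0, 1999.0))
@settings(max_examples=100, derandomize=True)
def test_cardiac_phase_always_in_unit_interval(t_acq):
    phi = cardiac_phase(t_acq, [0.0, 700.0, 2000.0])
    assert 0.0 <= phi < 1.0


def _timing(n_pairs=10, n_slices=14):
    return AcquisitionTiming(n_pairs=n_pairs, n_slices=n_slices)


def test_assign_phases_slice_delay_offsets():
    """Constant R-R 1000 ms: slice s leads slice 0 by s*29/1000 in phase."""
    peaks = np.arange(0.0, 300_000.0, 1000.0)
    timing = _timing()
    asg = assign_phases(timing, peaks, series_start=5000.0, mode="slice")
    for s in range(timing.n_slices):
        expected = np.mod(asg.phi[:, 0] + s * 29.0 / 1000.0, 1.0)
        np.testing.assert_allclose(asg.phi[:, s], expected, atol=1e-9)


def test_label_mode_constant_phase_per_volume_and_identity():
    """Label mode gives one phase per volume; slice mode differs by the
    slice-delay offset (exact arithmetic identity at constant R-R)."""
    peaks = np.arange(0.0, 300_000.0, 1000.0)
    timing = _timing()
    lab = assign_phases(timing, peaks, series_start=5000.0, mode="label")
    sli = assign_phases(timing, peaks, series_start=5000.0, mode="slice")
    assert np.ptp(lab.phi, axis=1).max() == 0.0
    for s in range(timing.n_slices):
        np.testing.assert_allclose(
            np.mod(sli.phi[:, s] - s * 29.0 / 1000.0, 1.0), lab.phi[:, s],
            atol=1e-9)


def test_label_mode_stack_phase_span_exceeds_0_4():
    """14 slices x 29 ms over a 1000 ms R-R span 0.406 cardiac-phase units."""
    span = label_mode_phase_span(_timing(), rr_ms=1000.0)
    assert span == pytest.approx(0.406)
    assert span > 0.4


def test_assign_phases_counts_conserved_and_bins_partition():
    trace, _ = generate_physio(hr_mean=65.0, hr_sd=3.25,
                               duration=_timing(80).n_volumes * 1400.0 + 10_000.0,
                               seed=2)
    peaks = shift_peaks(detect_systolic_peaks(trace), 225.0)
    timing = _timing(80)
    asg = assign_phases(timing, peaks, series_start=1000.0)
    assert asg.valid.all()
    assert np.all((asg.phi >= 0) & (asg.phi < 1))
    # 160 volumes per TI distribute over exactly 8 bins at every slice
    for s in range(timing.n_slices):
        counts = np.bincount(asg.bin_index[:, s], minlength=8)
        assert counts.sum() == 160
        assert counts.size == 8


def _tiny_series(timing, values):
    """Series with one TI whose volumes are constant images of `values`."""
    nv, ns = timing.n_volumes, timing.n_slices
    arr = np.tile(np.asarray(values, dtype=float)[:, None, None, None],
                  (1, ns, 3, 3))
    return MultiTIASLSeries(data={750.0: arr}, timing=timing,
                            series_start={750.0: 1000.0})


def test_phase_binned_delta_single_pair_difference_and_identical_inputs():
    timing = AcquisitionTiming(n_pairs=2, n_slices=2)
    # R-R = TR/2 locks every volume to one cardiac phase, so tag and control
    # volumes share a bin and the bin mean difference is defined
    peaks = np.arange(0.0, 40_000.0, 700.0)
    asg = assign_phases(timing, peaks, series_start=1000.0)
    # tag volumes carry 0.9, control 1.0 -> dM = 0.1 wherever defined
    vals = [0.9 if lab == "tag" else 1.0 for lab in timing.label_order]
    binned = phase_binned_delta(_tiny_series(timing, vals), {750.0: asg})
    assert binned.n_tag.sum() == timing.n_pairs * timing.n_slices
    assert binned.n_control.sum() == timing.n_pairs * timing.n_slices
    defined = np.isfinite(binned.delta_m)
    assert defined.any()
    np.testing.assert_allclose(binned.delta_m[defined], 0.1)
    # identical tag and control series give dM identically zero
    binned0 = phase_binned_delta(_tiny_series(timing, np.ones(timing.n_volumes)),
                                 {750.0: asg})
    defined0 = np.isfinite(binned0.delta_m)
    np.testing.assert_allclose(binned0.delta_m[defined0], 0.0)


def test_phase_binned_delta_linearity():
    timing = AcquisitionTiming(n_pairs=4, n_slices=2)
    peaks = np.arange(0.0, 40_000.0, 917.0)
    asg = assign_phases(timing, peaks, series_start=1000.0)
    rng = np.random.default_rng(0)
    vals = rng.normal(1.0, 0.05, size=timing.n_volumes)
    b1 = phase_binned_delta(_tiny_series(timing, vals), {750.0: asg})
    b3 = phase_binned_delta(_tiny_series(timing, 3.0 * vals), {750.0: asg})
    np.testing.assert_allclose(b3.delta_m, 3.0 * b1.delta_m, atol=1e-12)


def test_balance_report_totals_and_harmonic_lock():
    """HR locked to a TR harmonic puts every volume in one bin (flagged)."""
    timing = AcquisitionTiming(n_pairs=10, n_slices=2)
    # R-R = TR/2 -> every volume start hits the same cardiac phase
    peaks = np.arange(0.0, 60_000.0, 700.0)
    asg = assign_phases(timing, peaks, series_start=1000.0)
    binned = phase_binned_delta(
        _tiny_series(timing, np.ones(timing.n_volumes)), {750.0: asg})
    rep = balance_report(binned, ref_slice=0, floor=3)
    assert isinstance(rep, pd.DataFrame)
    assert rep.n_tag.sum() == timing.n_pairs
    assert rep.n_control.sum() == timing.n_pairs
    occupied = rep[(rep.n_tag > 0) | (rep.n_control > 0)]
    assert len(occupied) == 1
    assert rep[rep.n_tag == 0].flagged.all()


def test_balance_counts_uniform_for_incommensurate_rates():
    """With R-R incommensurate to TR, phases equidistribute over bins."""
    timing = AcquisitionTiming(n_pairs=200, n_slices=1)
    peaks = np.arange(0.0, 700_000.0, 941.0)
    asg = assign_phases(timing, peaks, series_start=1000.0)
    counts = np.bincount(asg.bin_index[:, 0], minlength=8)
    assert counts.sum() == 400
    np.testing.assert_array_less(np.abs(counts - 50.0), 16.0)


def test_acquisition_timing_validation():
    with pytest.raises(ValueError):
        AcquisitionTiming(ti_list=(850.0, 250.0))
    with pytest.raises(ValueError):
        AcquisitionTiming(tr=800.0)
    with pytest.raises(ValueError):
        AcquisitionTiming(n_pairs=2, label_order=("tag",) * 4 + ("control",))
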