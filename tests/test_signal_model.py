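"""Kinetic model unit and property tests.

Closed forms are checked against independent numerical oracles: adaptive
quadrature of the Gaussian kernel for the dispersed bolus and of the full
delivery integrand for the tissue compartment.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, simpson
from scipy.stats import norm

from aslcomp import (
    ArterialParams,
    TissueParams,
    arterial_delta_m,
    dispersed_bolus,
    square_bolus,
    tissue_delta_m,
    two_compartment_signal,
)
from aslcomp.exceptions import InvalidBolusError, InvalidDispersionError


@pytest.mark.parametrize("t, expected", [
    (500.0, 1.0),   # inside the bolus
    (200.0, 0.0),   # before arrival
    (1000.0, 0.0),  # trailing edge: half-open interval
    (300.0, 1.0),   # leading edge included
])
def test_square_bolus_window(t, expected):
    assert square_bolus(t, dt=300.0, tau=700.0) == expected


def test_square_bolus_rejects_bad_tau():
    with pytest.raises(InvalidBolusError):
        square_bolus(500.0, dt=300.0, tau=0.0)


def test_dispersed_bolus_leading_edge_half():
    """Gaussian symmetry puts the dispersed leading edge at exactly 1/2."""
    assert dispersed_bolus(300.0, dt=300.0, tau=700.0, sigma=50.0) == pytest.approx(0.5)


def test_dispersed_bolus_degenerate_kernel_is_square():
    t = np.linspace(0.0, 1500.0, 301)
    np.testing.assert_array_equal(
        dispersed_bolus(t, 300.0, 700.0, 0.0), square_bolus(t, 300.0, 700.0)
    )


def test_dispersed_bolus_rejects_negative_sigma():
    with pytest.raises(InvalidDispersionError):
        dispersed_bolus(500.0, 300.0, 700.0, -1.0)


@pytest.mark.parametrize("t", [350.0, 650.0, 990.0, 1010.0, 1200.0])
@pytest.mark.parametrize("sigma", [20.0, 50.0, 120.0])
def test_dispersed_bolus_matches_numerical_convolution(t, sigma):
    """Closed erf form vs adaptive quadrature of the Gaussian kernel."""
    dt, tau = 300.0, 700.0
    expected, err = quad(lambda s: norm.pdf(t - s, 0.0, sigma), dt, dt + tau,
                         epsabs=1e-13, limit=200)
    assert err < 1e-10
    assert dispersed_bolus(t, dt, tau, sigma) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("sigma", [0.0, 10.0, 50.0, 150.0])
def test_label_mass_conservation(sigma):
    """The dispersed bolus carries the same label mass tau for any sigma."""
    dt, tau = 300.0, 700.0
    t = np.arange(dt - 8 * max(sigma, 1.0), dt + tau + 8 * max(sigma, 1.0), 0.5)
    integral = simpson(dispersed_bolus(t, dt, tau, sigma), x=t)
    assert integral == pytest.approx(tau, abs=1e-6 * tau)


def test_sigma_to_zero_limit_away_from_edges():
    """Dispersion vanishes pointwise away from the bolus edges as sigma -> 0."""
    dt, tau = 300.0, 700.0
    t = np.linspace(0.0, 1500.0, 1501)
    gaps = []
    for sigma in (20.0, 5.0, 1.0):
        keep = (np.abs(t - dt) > 3 * sigma) & (np.abs(t - dt - tau) > 3 * sigma)
        gaps.append(np.max(np.abs(dispersed_bolus(t[keep], dt, tau, sigma)
                                  - square_bolus(t[keep], dt, tau))))
    assert all(a > b for a, b in zip(gaps, gaps[1:]))
    # a 3-sigma exclusion bounds the residual by erfc(3/sqrt 2)/2
    assert gaps[-1] < 2e-3
    # with a 6-sigma exclusion the residual is numerically negligible
    keep = (np.abs(t - dt) > 6.0) & (np.abs(t - dt - tau) > 6.0)
    assert np.max(np.abs(dispersed_bolus(t[keep], dt, tau, 1.0)
                         - square_bolus(t[keep], dt, tau))) < 1e-8


@given(
    t=st.floats(0.0, 2000.0),
    dt=st.floats(0.0, 800.0),
    sigma=st.floats(0.0, 200.0),
)
@settings(max_examples=100, derandomize=True)
def test_dispersed_bolus_stays_in_unit_interval(t, dt, sigma):
    w = dispersed_bolus(t, dt, 700.0, sigma)
    assert 0.0 <= w <= 1.0


def test_arterial_plateau_closed_form():
    """On the undispersed plateau dM = 2*alpha*(aBV/100)*M0a*exp(-t/T1a)."""
    p = ArterialParams(abv=2.0, dt=300.0, sigma=0.0, m0a=1.0)
    t = np.array([300.0, 600.0, 900.0])
    np.testing.assert_allclose(
        arterial_delta_m(t, p), 2 * 0.02 * np.exp(-t / 1664.0), rtol=0, atol=1e-15
    )
    # frozen spot value of the plateau at t = 600 ms
    assert arterial_delta_m(600.0, p) == pytest.approx(0.0278912, abs=1e-6)


def test_arterial_zero_volume_and_pre_arrival():
    assert arterial_delta_m(500.0, ArterialParams(abv=0.0, dt=300.0, sigma=50.0)) == 0.0
    assert arterial_delta_m(200.0, ArterialParams(abv=2.0, dt=300.0, sigma=0.0)) == 0.0


def test_arterial_decay_monotonic_in_t1a():
    """Shorter blood T1 means more label decay, hence less signal."""
    t = 600.0
    vals = [
        arterial_delta_m(t, ArterialParams(abv=2.0, dt=300.0, sigma=0.0, t1a=t1a))
        for t1a in (2000.0, 1664.0, 1200.0, 800.0)
    ]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_arterial_label_decay_variant_matches_quadrature():
    """Decay-inside-convolution closed form vs brute-force quadrature."""
    p = ArterialParams(abv=2.0, dt=300.0, sigma=60.0)
    for t in (350.0, 700.0, 1050.0):
        expected, _ = quad(
            lambda s: np.exp(-s / p.t1a) * norm.pdf(t - s, 0.0, p.sigma),
            p.dt, p.dt + p.tau, epsabs=1e-14, limit=200,
        )
        expected *= 2 * p.alpha * (p.abv / 100.0) * p.m0a
        got = arterial_delta_m(t, p, decay="label")
        assert got == pytest.approx(expected, abs=1e-12)
    # both conventions coincide exactly for an undispersed bolus
    p0 = ArterialParams(abv=2.0, dt=300.0, sigma=0.0)
    t = np.linspace(0, 1500, 151)
    np.testing.assert_array_equal(
        arterial_delta_m(t, p0, decay="label"), arterial_delta_m(t, p0)
    )


def test_tissue_pre_arrival_and_zero_perfusion():
    tp = TissueParams(cbf=60.0, dt_tiss=800.0)
    assert tissue_delta_m(700.0, tp) == 0.0
    assert tissue_delta_m(900.0, TissueParams(cbf=0.0, dt_tiss=800.0)) == 0.0


@pytest.mark.parametrize("t", [900.0, 1200.0, 1600.0, 2500.0])
def test_tissue_closed_form_matches_quadrature(t):
    """Closed-form delivery integral vs adaptive quadrature of the integrand."""
    tp = TissueParams(cbf=60.0, dt_tiss=800.0)
    f = tp.f_per_ms
    r1app = 1.0 / tp.t1t + f / tp.lambda_bp
    b = min(t, tp.dt_tiss + 700.0)
    expected, _ = quad(
        lambda s: np.exp(-s / 1664.0) * np.exp(-(t - s) * r1app),
        tp.dt_tiss, b, epsabs=1e-14,
    )
    expected *= 2.0 * f
    assert tissue_delta_m(t, tp) == pytest.approx(expected, abs=1e-9)


def test_tissue_continuous_and_rising_after_arrival():
    tp = TissueParams(cbf=60.0, dt_tiss=700.0)
    t = np.linspace(600.0, 1100.0, 501)
    y = tissue_delta_m(t, tp)
    assert np.all(np.diff(y)[t[:-1] >= 700.0] > -1e-15)
    assert np.max(np.abs(np.diff(y))) < 3e-5  # no jumps at 1 ms resolution


def test_two_compartment_additivity():
    p = ArterialParams(abv=3.0, dt=350.0, sigma=50.0)
    tp0 = TissueParams(cbf=0.0, dt_tiss=700.0)
    tp = TissueParams(cbf=60.0, dt_tiss=700.0)
    t = np.linspace(0.0, 2500.0, 251)
    np.testing.assert_array_equal(two_compartment_signal(t, p, tp0),
                                  arterial_delta_m(t, p))
    np.testing.assert_allclose(
        two_compartment_signal(t, p, tp),
        arterial_delta_m(t, p) + tissue_delta_m(t, tp),
        rtol=0, atol=1e-18,
    )
    with pytest.raises(ValueError):
        two_compartment_signal(500.0, ArterialParams(abv=1.0, dt=800.0, sigma=0.0),
                               TissueParams(cbf=60.0, dt_tiss=700.0))


@pytest.mark.parametrize("kwargs", [
    {"abv": -1.0, "dt": 300.0, "sigma": 50.0},
    {"abv": 1.0, "dt": -5.0, "sigma": 50.0},
    {"abv": 1.0, "dt": 300.0, "sigma": -1.0},
    {"abv": 1.0, "dt": 300.0, "sigma": 50.0, "tau": 0.0},
    {"abv": 1.0, "dt": 300.0, "sigma": 50.0, "alpha": 1.5},
])
def test_arterial_params_invariants(kwargs):
    with pytest.raises((ValueError, InvalidBolusError, InvalidDispersionError)):
        ArterialParams(**kwargs)
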