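"""Kinetic models of the short inversion time pulsed-ASL difference signal.

The macrovascular (arterial) model treats the labeled blood in a large artery
as a plug-flow bolus of duration ``tau`` (enforced by the QUIPSS II saturation
cut-off) whose leading and trailing edges are smeared by Gaussian dispersion
of width ``sigma`` during transit.  The tag/control difference signal of a
voxel with arterial blood volume fraction aBV is

    dM(t) = 2 * alpha * (aBV/100) * M0a * exp(-t/T1a) * c(t)

where c(t) is the square bolus weighting convolved with a unit-area Gaussian
centered on the arrival time dt:

    c(t) = 1/2 * [ erf((t - dt) / (sigma*sqrt(2)))
                 - erf((t - dt - tau) / (sigma*sqrt(2))) ]

All times are in milliseconds; aBV is carried in percent of voxel volume (%v)
throughout the API and converted to a fraction only inside the signal
evaluation.

By default the longitudinal T1 decay of the label is applied at the
observation time ``t`` (outside the convolution), which keeps the sigma -> 0
limit exactly equal to the undispersed plug-flow model.  The alternative
convention — decay accrued at the time each labeled spin was created, i.e.
inside the convolution — is available via ``decay="label"`` and has the
closed form

    c_label(t) = exp(sigma^2 / (2*T1a^2)) * exp(-t/T1a) * 1/2 *
                 [ erf((t - dt - sigma^2/T1a) / (sigma*sqrt(2)))
                 - erf((t - dt - tau - sigma^2/T1a) / (sigma*sqrt(2))) ]

A single-compartment tissue (microvascular) model is provided solely for the
synthetic generator and the contamination study: at short TI (< 1 s) the
arterial signal of large-vessel voxels dominates, and the production fitting
path is arterial-only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erf

from .exceptions import InvalidBolusError, InvalidDispersionError

__all__ = [
    "ArterialParams",
    "TissueParams",
    "square_bolus",
    "dispersed_bolus",
    "arterial_delta_m",
    "tissue_delta_m",
    "two_compartment_signal",
]

_SQRT2 = float(np.sqrt(2.0))

#: default T1 of arterial blood at 3 T, ms
T1_ARTERIAL_MS = 1664.0
#: default bolus duration enforced by the QUIPSS II cut-off, ms
TAU_MS = 700.0
#: blood-tissue water partition coefficient, mL/g
LAMBDA_BP = 0.9
#: default gray-matter tissue T1 at 3 T, ms
T1_TISSUE_MS = 1330.0


@dataclass(frozen=True)
class ArterialParams:
    """Parameters of the dispersed plug-flow arterial compartment.

    Attributes
    ----------
    abv : float
        Arterial blood volume as percent of voxel volume (%v).
    dt : float
        Bolus arrival time, ms.
    sigma : float
        Gaussian dispersion width, ms.
    tau : float
        Bolus duration, ms (QUIPSS II cut-off).
    alpha : float
        Labeling efficiency, dimensionless.
    t1a : float
        Longitudinal relaxation time of arterial blood, ms.
    m0a : float
        Equilibrium magnetization of arterial blood, signal units.
    """

    abv: float
    dt: float
    sigma: float
    tau: float = TAU_MS
    alpha: float = 1.0
    t1a: float = T1_ARTERIAL_MS
    m0a: float = 1.0

    def __post_init__(self) -> None:
        if self.abv < 0:
            raise ValueError(f"aBV must be >= 0 %v, got {self.abv}")
        if self.dt < 0:
            raise ValueError(f"arrival time dt must be >= 0 ms, got {self.dt}")
        if self.sigma < 0:
            raise InvalidDispersionError(f"sigma must be >= 0 ms, got {self.sigma}")
        if self.tau <= 0:
            raise InvalidBolusError(f"tau must be > 0 ms, got {self.tau}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.t1a <= 0:
            raise ValueError(f"t1a must be > 0 ms, got {self.t1a}")
        if self.m0a <= 0:
            raise ValueError(f"m0a must be > 0, got {self.m0a}")

    def with_(self, **kwargs) -> "ArterialParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TissueParams:
    """Parameters of the single-compartment tissue (microvascular) model.

    ``cbf`` is tissue perfusion in mL/100 g/min; ``dt_tiss`` the arrival time
    of the label at the capillary bed, ms.  Used only by the synthetic
    generator and the two-compartment contamination study.
    """

    cbf: float
    dt_tiss: float
    lambda_bp: float = LAMBDA_BP
    t1t: float = T1_TISSUE_MS

    def __post_init__(self) -> None:
        if self.cbf < 0:
            raise ValueError(f"cbf must be >= 0, got {self.cbf}")
        if self.dt_tiss < 0:
            raise ValueError(f"dt_tiss must be >= 0 ms, got {self.dt_tiss}")
        if self.lambda_bp <= 0:
            raise ValueError(f"lambda_bp must be > 0, got {self.lambda_bp}")
        if self.t1t <= 0:
            raise ValueError(f"t1t must be > 0 ms, got {self.t1t}")

    @property
    def f_per_ms(self) -> float:
        """Perfusion in mL blood per mL tissue per ms (unit tissue density)."""
        return self.cbf / (100.0 * 60.0 * 1000.0)


def square_bolus(t, dt: float, tau: float):
    """Plug-flow square bolus weighting: 1 on [dt, dt+tau), else 0.

    The half-open right edge makes the bolus integral exactly ``tau`` and
    avoids double counting at the trailing edge.
    """
    if tau <= 0:
        raise InvalidBolusError(f"tau must be > 0 ms, got {tau}")
    t = np.asarray(t, dtype=float)
    w = ((t >= dt) & (t < dt + tau)).astype(float)
    return w if w.ndim else float(w)


def dispersed_bolus(t, dt: float, tau: float, sigma: float):
    """Square bolus convolved with a unit-area Gaussian kernel of s.d. sigma.

    Closed form ``1/2 [erf((t-dt)/(sigma*sqrt2)) - erf((t-dt-tau)/(sigma*sqrt2))]``;
    reduces exactly to :func:`square_bolus` at sigma = 0.
    """
    if sigma < 0:
        raise InvalidDispersionError(f"sigma must be >= 0 ms, got {sigma}")
    if tau <= 0:
        raise InvalidBolusError(f"tau must be > 0 ms, got {tau}")
    if sigma == 0:
        return square_bolus(t, dt, tau)
    t = np.asarray(t, dtype=float)
    s = sigma * _SQRT2
    w = 0.5 * (erf((t - dt) / s) - erf((t - dt - tau) / s))
    return w if w.ndim else float(w)


def arterial_delta_m(t, p: ArterialParams, decay: str = "observation"):
    """Difference signal dM(t) of the dispersed macrovascular compartment.

    Parameters
    ----------
    t : array_like
        Observation time(s) after labeling, ms.
    p : ArterialParams
        Compartment parameters; ``p.abv`` in %v.
    decay : {"observation", "label"}
        Where the T1 decay of the label is applied: at the observation time
        (outside the dispersion convolution; default) or accrued per labeled
        spin inside the convolution.
    """
    t = np.asarray(t, dtype=float)
    amp = 2.0 * p.alpha * (p.abv / 100.0) * p.m0a
    if decay == "observation":
        out = amp * np.exp(-t / p.t1a) * dispersed_bolus(t, p.dt, p.tau, p.sigma)
    elif decay == "label":
        if p.sigma == 0:
            out = amp * np.exp(-t / p.t1a) * square_bolus(t, p.dt, p.tau)
        else:
            s = p.sigma * _SQRT2
            shift = p.sigma**2 / p.t1a
            c = 0.5 * (
                erf((t - p.dt - shift) / s) - erf((t - p.dt - p.tau - shift) / s)
            )
            out = amp * np.exp(shift**2 / (2.0 * p.sigma**2) - t / p.t1a) * c
    else:
        raise ValueError(f"decay must be 'observation' or 'label', got {decay!r}")
    return out if out.ndim else float(out)


def tissue_delta_m(t, tp: TissueParams, alpha: float = 1.0, m0a: float = 1.0,
                   tau: float = TAU_MS, t1a: float = T1_ARTERIAL_MS):
    """Difference signal of the single-compartment tissue model.

    The labeled bolus (square, duration ``tau``) arrives at the capillary bed
    at ``tp.dt_tiss``; delivered label decays with the apparent tissue rate
    1/T1app = 1/T1t + f/lambda while in tissue and with 1/T1a while in blood:

        dM(t) = 2 alpha M0a f * integral_{dt_tiss}^{min(t, dt_tiss+tau)}
                exp(-s/T1a) exp(-(t-s)/T1app) ds

    evaluated in closed form.  Zero before arrival; continuous in t.
    """
    t = np.asarray(t, dtype=float)
    f = tp.f_per_ms
    if f == 0.0:
        out = np.zeros_like(t)
        return out if out.ndim else float(out)
    r1app = 1.0 / tp.t1t + f / tp.lambda_bp
    a = tp.dt_tiss
    b = np.minimum(t, a + tau)
    k = r1app - 1.0 / t1a
    with np.errstate(over="ignore", invalid="ignore"):
        if abs(k) < 1e-12:
            integral = np.exp(-t * r1app) * np.exp(k * a) * (b - a)
        else:
            integral = (
                np.exp(-t * r1app)
                * np.exp(k * a)
                * np.expm1(k * (b - a))
                / k
            )
    out = np.where(t > a, 2.0 * alpha * m0a * f * integral, 0.0)
    return out if out.ndim else float(out)


def two_compartment_signal(t, p: ArterialParams, tp: TissueParams,
                           decay: str = "observation"):
    """Sum of the macrovascular and tissue difference signals.

    Used by the synthetic generator and the contamination study; the
    production fitting path is arterial-only.
    """
    if tp.dt_tiss < p.dt:
        raise ValueError(
            f"tissue arrival ({tp.dt_tiss} ms) precedes arterial arrival ({p.dt} ms)"
        )
    return arterial_delta_m(t, p, decay=decay) + tissue_delta_m(
        t, tp, alpha=p.alpha, m0a=p.m0a, tau=p.tau, t1a=p.t1a
    )
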