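"""Shared fixtures: scaled-down phantom datasets generated at test time."""

import numpy as np
import pytest

from aslcomp import AcquisitionTiming, PhantomSpec, TerritorySpec, simulate_acquisition
from aslcomp.synthetic_data import _default_territories

PROTOCOL_TIS = (250.0, 350.0, 450.0, 550.0, 650.0, 750.0, 850.0)


def small_territories(z_range=(1, 5)):
    return {
        name: TerritorySpec(center=t.center, abv_dia=t.abv_dia, ac=t.ac,
                            dt_dia=t.dt_dia, z_range=z_range)
        for name, t in _default_territories().items()
    }


@pytest.fixture(scope="session")
def phantom_dataset():
    """Protocol-faithful acquisition on a 6-slice phantom (seed 0).

    Full 80 tag-control pairs per TI, protocol TR/TIs/slice delay, default
    noise and tissue background; only the slice count is scaled down.
    """
    spec = PhantomSpec(shape=(6, 24, 24), territories=small_territories(),
                       seed=0)
    timing = AcquisitionTiming(n_pairs=80, n_slices=6)
    return simulate_acquisition(spec, timing=timing, seed=0)


@pytest.fixture(scope="session")
def constant_dataset():
    """Noiseless, modulation-free, tissue-free phantom: exact-recovery oracle.

    Every territory keeps its diastolic parameters at all cardiac phases
    (zero planted compliance and zero systolic offsets), so any populated
    phase bin must recover the planted values to optimizer tolerance.
    """
    terrs = {
        name: TerritorySpec(center=t.center, abv_dia=t.abv_dia, ac=0.0,
                            dt_dia=t.dt_dia, z_range=(1, 3))
        for name, t in _default_territories().items()
    }
    spec = PhantomSpec(shape=(4, 24, 24), territories=terrs, seed=5,
                       noise_sd=0.0, cbf=0.0, dt_sys_offset=0.0,
                       sigma_dia_offset=0.0)
    timing = AcquisitionTiming(n_pairs=40, n_slices=4)
    return simulate_acquisition(spec, timing=timing, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
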