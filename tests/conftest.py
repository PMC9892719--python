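import numpy as np
import pandas as pd
import pytest

from catscreen.plate import default_screen_layout, make_scheme
from catscreen.preprocess import default_spillover
from catscreen.simulate import (
    SimDefaults,
    WellSimSpec,
    signature_intensity,
    simulate_plate,
    simulate_well,
)


@pytest.fixture(scope="session")
def spillover():
    return default_spillover()


@pytest.fixture(scope="session")
def neg_well(spillover):
    """One uninhibited (negative-control-like) well: p_mig=0.8, 20k events."""
    v, c = signature_intensity(1.0, 0.25)
    spec = WellSimSpec(
        p_mig=0.8, signature="V1-C1",
        violet_median_afu=v, cfse_median_afu=c, spillover=spillover,
    )
    return spec, simulate_well(spec, seed=7)


@pytest.fixture(scope="session")
def single_sig_scheme():
    return make_scheme(cfse_levels_um=[0.25], violet_levels_um=[1.0])


@pytest.fixture(scope="session")
def matrix_tube(spillover):
    """One pooled 12-plex matrix (with a no-sperm well) at 2,000 events/well."""
    layout = default_screen_layout(
        compound_ids=[f"C{i:03d}" for i in range(1, 10)],
        n_matrices=1,
        no_sperm_signature="V3-C3",
    )
    sim = SimDefaults(n_events_per_well=2000, spillover=spillover)
    tubes = simulate_plate(layout, sim, seed=11)
    return layout, tubes[1]
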