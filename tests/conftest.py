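"""Shared fixtures: grids and the expensive reference simulations.

The reference runs are session-scoped so that the behavioural tests and the
acceptance tests share one integration each of the standard configurations.
"""

import numpy as np
import pytest

from viscofilm.core import LongWaveParams, ThinFilmParams, make_grid
from viscofilm.experiments import run_long_wave, run_thin_film
from viscofilm.solver import EventSpec


@pytest.fixture(scope="session")
def grid200():
    return make_grid(2 * np.pi, 200)


@pytest.fixture(scope="session")
def fig3_run():
    """Thin-film reference run: B=0.04, M=0.2, A=0.2 to t~=1e4.

    Output times are geometric with extra resolution around the epoch when
    shock-like fronts develop in the surfactant-gradient field.
    """
    tt = np.unique(
        np.concatenate([np.geomspace(1.0, 1e4, 60), np.linspace(100, 200, 21)])
    )
    params = ThinFilmParams(B=0.04, M=0.2, A=0.2)
    return run_thin_film(params, EventSpec(t_end=1e4, output_times=tt))


@pytest.fixture(scope="session")
def clean_plug_run():
    """Surfactant-free long-wave plug run (eps=0.14, cB=0.001, A=0.2)."""
    params = LongWaveParams(cB=0.001, cM=0.0, eps=0.14, A=0.2)
    return run_long_wave(params, EventSpec(t_end=1e4, n_out=41))


@pytest.fixture(scope="session")
def surfactant_plug_run():
    """Surfactant-laden long-wave plug run (eps=0.14, cB=0.001, cM=0.02)."""
    params = LongWaveParams(cB=0.001, cM=0.02, eps=0.14, A=0.2)
    return run_long_wave(params, EventSpec(t_end=1e4, n_out=41))


@pytest.fixture(scope="session")
def strong_surfactant_plug_run():
    """Strong-surfactant long-wave plug run (eps=0.14, cM=10, A=0.25)."""
    params = LongWaveParams(cB=0.001, cM=10.0, eps=0.14, A=0.25)
    return run_long_wave(params, EventSpec(t_end=1e4, n_out=41))


@pytest.fixture(scope="session")
def bm_02():
    """Stability threshold of the strong-surfactant limit at A=0.2."""
    from viscofilm.statics import marginal_bingham

    return marginal_bingham(0.2)
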