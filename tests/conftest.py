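"""Shared fixtures: simulated runs and the synthetic fixture panel."""

import numpy as np
import pytest

from clperox.antioxidants import get_antioxidant
from clperox.simulator import (
    AntioxidantDose,
    RateConstants,
    SimulationConfig,
    generate_fixture_panel,
    simulate,
)

PANEL_SEED = 7


@pytest.fixture(scope="session")
def panel():
    """Default synthetic experiment panel (5 pure CL + 3 per class)."""
    return generate_fixture_panel(seed=PANEL_SEED)


@pytest.fixture(scope="session")
def panel_dir(tmp_path_factory):
    """The default panel written to disk once per session."""
    d = tmp_path_factory.mktemp("panel")
    generate_fixture_panel(seed=PANEL_SEED, outdir=d)
    return d


@pytest.fixture(scope="session")
def uninhibited_run():
    """Noiseless uninhibited simulation at default composition."""
    return simulate(SimulationConfig(duration_min=120.0, noise_sd=0.0))


@pytest.fixture(scope="session")
def chromanol_run():
    """Noiseless 1 uM chromanol (n=2) run spanning lag and post-lag rise."""
    spec = get_antioxidant("alpha-tocopherol")
    cfg = SimulationConfig(
        antioxidant=AntioxidantDose(spec, 1e-6), duration_min=300.0, noise_sd=0.0
    )
    return simulate(cfg, RateConstants.for_class("chromanol"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
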