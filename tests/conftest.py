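import numpy as np
import pytest

import trackchem as tc


@pytest.fixture(scope="session")
def registry():
    return tc.default_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


# Shared scaled-down validation ensembles (electron and proton reference
# setups). Session-scoped: the 1 us chemistry is the expensive part of the
# suite and several checks read the same runs.

N_EVENTS = 12
ELECTRON_EDEP_EV = 4000.0  # natural per-primary deposit of the 20 um cube
PROTON_EDEP_EV = 2700.0  # 20 MeV proton crossing the 1 um cube


@pytest.fixture(scope="session")
def electron_ensemble(registry):
    return tc.run_ensemble(
        "e750keV", N_EVENTS, ELECTRON_EDEP_EV, registry, seed=20260923
    )


@pytest.fixture(scope="session")
def proton_ensemble(registry):
    return tc.run_ensemble(
        "p20MeV", N_EVENTS, PROTON_EDEP_EV, registry, seed=20260924
    )
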