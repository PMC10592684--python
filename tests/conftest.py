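import numpy as np
import pytest

from cageforge.docking import DockingParams, dock, prepare_component
from cageforge.fixtures import ScenarioSpec, make_docking_scenario, make_helical_trimer
from cageforge.symmetry import get_entry


@pytest.fixture(scope="session")
def trimer():
    return make_helical_trimer(16, seed=11)


@pytest.fixture(scope="session")
def t_entry():
    return get_entry("T")


@pytest.fixture(scope="session")
def scenario():
    """Planted docking scenario shared across docking/pipeline tests."""
    olig_a, olig_b, truth, db = make_docking_scenario(seed=7)
    return {"a": olig_a, "b": olig_b, "truth": truth, "db": db}


@pytest.fixture(scope="session")
def docked(scenario, t_entry):
    params = DockingParams()
    ra, ta, rb, tb = scenario["truth"]["dof"]
    ranges = {
        "rot_a": (ra - 6.0, ra + 6.0),
        "rot_b": (rb - 6.0, rb + 6.0),
        "trans_a": (max(0.0, ta - 2.0), ta + 2.0),
        "trans_b": (max(0.0, tb - 2.0), tb + 2.0),
    }
    poses = dock(scenario["a"], scenario["b"], t_entry, params,
                 scenario["db"], ranges)
    prep_a = prepare_component(scenario["a"], scenario["db"], params,
                               with_ghosts=True)
    prep_b = prepare_component(scenario["b"], scenario["db"], params,
                               with_ghosts=False)
    return {"poses": poses, "params": params, "prep_a": prep_a,
            "prep_b": prep_b, "ranges": ranges}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
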