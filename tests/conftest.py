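import numpy as np
import pytest
from hypothesis import settings

import vesibud as vb

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ff_good():
    return vb.default_force_table("good")


@pytest.fixture(scope="session")
def ff_poor():
    return vb.default_force_table("poor")


@pytest.fixture(scope="session")
def bulk_water():
    return vb.make_fixture("bulk_water", seed=1)


@pytest.fixture(scope="session")
def poor_slab_coexistence(ff_poor):
    """One equilibrated poor-solvent slab run, shared by the coexistence
    tests: returns the CoexistenceResult of the final-half frames."""
    import warnings

    from vesibud.engine import IntegratorConfig, run
    from vesibud.phase_diagram import coexistence_from_slab

    state = vb.build_slab(0.30, (8.0, 8.0, 20.0), seed=41)
    state = vb.soft_relax(state, ff_poor, n_steps=300)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, traj, _ = run(state, IntegratorConfig(), ff_poor, 80_000, stride=4000)
        return coexistence_from_slab(traj.frames[len(traj) // 2:], ff_poor.zeta)


def two_bead_state(separation=0.5, box=6.0, types=(2, 2)):
    """Two beads along x at the given separation, at rest, centered in the box."""
    L = float(box)
    pos = np.array([[L / 2 - separation / 2, L / 2, L / 2],
                    [L / 2 + separation / 2, L / 2, L / 2]])
    return vb.SystemState(box=np.full(3, L), pos=pos, vel=np.zeros((2, 3)),
                          types=np.array(types, dtype=np.int8), mol=np.zeros(2, dtype=np.int32))
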