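import numpy as np
import pytest

from mlpforge.fixtures import FixtureSpec, make_fixture
from mlpforge.moltopo import Conformation, build_molecule
from mlpforge.oracle import ForceFieldEvaluator, ForceFieldParams
from mlpforge.sampler import relax


@pytest.fixture(scope="session")
def chain4():
    """Butane-like 4-heavy-atom chain with a declared 3 kcal/mol barrier."""
    return make_fixture(FixtureSpec("chain", size=4, barriers=(3.0,), seed=1, name="chain4"))


@pytest.fixture(scope="session")
def biaryl():
    return make_fixture(FixtureSpec("biaryl-like", barriers=(6.0,), seed=2, name="biaryl"))


@pytest.fixture(scope="session")
def chain4_evaluator(chain4):
    return ForceFieldEvaluator(chain4.molecule, chain4.params)


@pytest.fixture(scope="session")
def chain4_relaxed(chain4, chain4_evaluator):
    """Optimized chain4 start, shared across tests (deterministic)."""
    res = relax(chain4_evaluator, chain4.molecule, chain4.start, fmax_tol=1e-4, max_steps=400)
    assert res.converged
    return res.final


@pytest.fixture(scope="session")
def butane_like():
    """Small hand-built system with bonded + nonbonded terms for force checks."""
    mol = build_molecule(["C", "C", "C", "C"], [(0, 1), (1, 2), (2, 3)], name="butane")
    params = ForceFieldParams(
        bond={(0, 1): (300.0, 1.53), (1, 2): (300.0, 1.53), (2, 3): (300.0, 1.53)},
        angle={
            (0, 1, 2): (60.0, np.radians(111.0)),
            (1, 2, 3): (60.0, np.radians(111.0)),
        },
        dihedral={(0, 1, 2, 3): ((1.4, 1, 0.0), (0.2, 2, np.pi), (2.0, 3, 0.0))},
        epsilon=(0.1,) * 4,
        sigma=(3.4,) * 4,
        charges=(0.05, -0.05, -0.05, 0.05),
    )
    coords = np.array(
        [[0.0, 0.0, 0.0], [1.53, 0.0, 0.0], [2.07, 1.43, 0.0], [3.6, 1.45, 0.4]]
    )
    return mol, params, Conformation(mol, coords)
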