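"""Label conformations with the analytic reference force field.

The oracle plays the role an ab initio method plays in production
training-set pipelines: given a conformation it returns the energy
(kcal/mol) and exact analytic forces (kcal/mol/A).  A "degraded" copy with
jittered parameters stands in for a cheaper, less accurate method.
"""

import numpy as np

from mlpforge import FixtureSpec, make_fixture, perturb_params
from mlpforge.oracle import ForceFieldEvaluator

system = make_fixture(FixtureSpec("chain", size=4, barriers=(3.0,), seed=1, name="chain4"))
ev = ForceFieldEvaluator(system.molecule, system.params)

energy, forces = ev.energy_forces(system.start.coordinates)
print(f"start-geometry energy: {energy:.3f} kcal/mol")
print(f"max atomic force:      {np.linalg.norm(forces, axis=1).max():.2f} kcal/mol/A")
# a jittered start is strained, so forces are large until relaxation

degraded = ForceFieldEvaluator(system.molecule, perturb_params(system.params, 0.1, seed=7))
e2, f2 = degraded.energy_forces(system.start.coordinates)
print(f"degraded-oracle energy: {e2:.3f} kcal/mol "
      f"(disagrees with the reference by {abs(e2 - energy):.3f})")
# the disagreement between the two labelings is what the benchmark
# metrics quantify on scans and trajectories
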