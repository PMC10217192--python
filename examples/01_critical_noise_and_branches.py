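"""Fixed-noise analysis: critical noise values and equilibrium branches.

With the feedback off, the intrinsic noise xi is a control parameter and the
order parameter m settles into minima of the Landau potential.  This script
prints, for each preset model, the noise level where the pluripotent state
m=0 destabilizes (xi_c), the saddle-node point where differentiated branches
appear, and the phase-transition point where the ground state shifts.
"""

import numpy as np

from stemfate import ModelSpec, critical_noise, equilibrium_branches, ground_state

for name in ("model1", "model2", "model3"):
    spec = ModelSpec.from_preset(name)
    cn = critical_noise(spec)
    print(f"{name}: xi_c={cn.xi_c}  saddle={cn.xi_saddle}  "
          f"transition={cn.xi_transition:.6g} ({cn.transition_order} order)")

# Model 2 branch structure just below the saddle-node: five coexisting
# equilibria (m0 stable, outer m+- stable, inner mu+- unstable).
spec2 = ModelSpec.from_preset("model2")
rec = equilibrium_branches(spec2, [1.2]).records
print("\nmodel2 branches at xi=1.2:")
print(rec.to_string(index=False))

# Ground state on either side of the first-order transition at 19/16:
for xi in (1.1, 1.2):
    print(f"model2 ground state at xi={xi}: {np.round(ground_state(spec2, xi), 4)}")

# Interpretation: between xi=1.1875 and 1.25 the differentiated wells exist
# but the pluripotent state is still the global minimum — the coexistence
# window characteristic of a first-order transition.
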