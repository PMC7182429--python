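"""Compare the formation free energies of all candidate structures.

Reproduces the landscape comparison at small line tension (lam = 1e-4)
and moderate drive (dmu = 1e-3) in the bending-dominated limit: the belt
is the global minimum, the defect-free cap only a metastable intermediate.
"""

import numpy as np

from capshell import (ScaledParameters, dg_belt, dg_cap_bending,
                      dg_shell_n_defects, classify_point)

p = ScaledParameters(lam=1e-4, dmu=1e-3, gamma=0.0)
xs = np.linspace(1e-3, 2.0, 4001)
xb = np.linspace(1e-3, 2.5, 4001)

cap = dg_cap_bending(xs, p)
shell = np.min([dg_shell_n_defects(xs, n, p) for n in range(1, 13)], axis=0)
belt = dg_belt(xb, p)

print("minimized formation energies (units of 4 pi R0^2 Y):")
print(f"  defect-free cap : {cap.min():+.3e}  at x = {xs[cap.argmin()]:.3f}")
print(f"  shell w/ defects: {shell.min():+.3e}  at x = {xs[shell.argmin()]:.3f}")
print(f"  closed belt     : {belt.min():+.3e}  at x = {xb[belt.argmin()]:.3f}")

pt = classify_point(p)
print(f"\nglobal minimum: {pt.winner.structure.value} "
      f"(dg = {pt.winner.dg:.3e}); "
      f"metastable defectless cap: {pt.metastable_defectless_cap}")
print("\nA negative dg means the structure is more stable than free "
      "capsomers; the belt wins here, so growth stalls in an open, "
      "non-infectious ring rather than a closed capsid.")
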