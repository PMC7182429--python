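"""Scan the universal assembly phase diagram at a chosen FvK number.

Prints a coarse character map over (lam, dmu) plus the traced
belt/defect-shell frontier and, for gamma > 0, the cylinder threshold.
"""

import numpy as np

from capshell import Structure, compute_grid, trace_boundary

GAMMA = 0.0
lam_axis = np.geomspace(1e-5, 2e-3, 24)
dmu_axis = np.geomspace(1e-4, 1e-2, 30)

grid = compute_grid(lam_axis, dmu_axis, GAMMA)
abbr = {Structure.BELT: "B", Structure.SHELL_N_DEFECTS: "S",
        Structure.CAP_ONE_DEFECT: "1", Structure.CAP_DEFECTLESS: "C",
        Structure.CYLINDER: "Y", Structure.DISASSEMBLED: "."}

print(f"phase map at gamma = {GAMMA:g} "
      "(rows: lam bottom-up; cols: dmu left-right)")
for i in reversed(range(len(lam_axis))):
    print(f"lam={lam_axis[i]:8.1e}  "
          + "".join(abbr[grid.labels[i, j]] for j in range(len(dmu_axis))))
print("  B belt, S shell with defects, Y cylinder, . disassembled")

front = trace_boundary(Structure.BELT, Structure.SHELL_N_DEFECTS, GAMMA, 1e-4)
print(f"\nbelt/defect-shell frontier at lam=1e-4: dmu = {front:.4f}")
print("Above this drive a closed spherical shell (12 disclinations) beats "
      "the open belt; below it assembly stalls as a belt.")
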