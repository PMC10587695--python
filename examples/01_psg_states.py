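"""Sweep the polarization state generator and inspect the six canonical
illumination states.

The PSG is a fixed horizontal polarizer followed by a rotating quarter-wave
plate; each fast-axis angle emits one fully polarized state on a closed
Poincare-sphere trace.  At +/-15 deg the trace passes through the two
elliptical states E1/E2 used alongside the linear and circular ones.
"""

import numpy as np

from polstain import NAMED_STATES, degree_of_polarization, poincare_point, psg_state

for angle in (0, 15, -15, 45, -45):
    s = psg_state(np.deg2rad(angle))
    print(f"QWP at {angle:+4d} deg -> S = {np.round(s, 3)}  DoP = {degree_of_polarization(s):.4f}")

print("\nSix canonical illumination states and their Poincare coordinates:")
for name, st in NAMED_STATES.items():
    p = poincare_point(st.stokes)
    print(f"  {name:7s} {np.round(st.stokes, 3)}  sphere point {np.round(p, 3)}")

# Every state has DoP ~ 1 (fully polarized) and unit Poincare norm; linear
# states sit on the equator (third coordinate 0), circular at the poles.
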