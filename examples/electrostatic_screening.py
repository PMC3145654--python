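"""How ionic strength screens charge-charge interactions in the model.

Prints the Debye screening length across the experimental KCl range and
the screened-Coulomb energy of a salt bridge at contact distance.  The
screening length at physiological 0.1 M is ~10 A — about two bead
diameters — which is why ionic strength reshapes the apo ensemble.
"""

import numpy as np

from camdyn import energy
from camdyn.constants import bjerrum_length, debye_length

print(f"Bjerrum length (eps_r=80, 298 K): {bjerrum_length():.2f} A")
print(f"{'[KCl] (M)':>10s} {'Debye length (A)':>18s} {'salt bridge (eps)':>18s}")

pos = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])   # 5 A contact
pair = np.array([[0, 1]])
charge = np.array([1.0, -1.0])
for ionic in (0.05, 0.1, 0.2, 0.5):
    params = energy.ElectrostaticsParams(ionic_strength_M=ionic)
    e = energy.debye_huckel_energy(pos, pair, charge, params)
    print(f"{ionic:10.2f} {debye_length(ionic):18.2f} {e:18.3f}")
# The salt-bridge energy weakens monotonically with salt: at 0.5 M the
# interaction is roughly half its 0.05 M value, mirroring how high KCl
# screens the repulsions that destabilize the extended apo state.
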