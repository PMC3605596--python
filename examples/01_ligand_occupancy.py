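"""Equilibrium labeling fractions for fluorescent antagonists.

A 1:1 site with dissociation constant Kd is occupied to L/(L+Kd) at free
ligand concentration L.  The two labels differ 30-fold in affinity, yet
both cover most receptors at 10 nM -- the basis for counting receptors by
counting fluorescent spots.
"""

import numpy as np

from tirftrack.binding import (competition_curve, fractional_occupancy,
                               kd_from_log_affinity)

for name, log_aff in [("high-affinity label", 10.35),
                      ("30-fold weaker label", 8.83)]:
    kd = kd_from_log_affinity(log_aff)
    occ = fractional_occupancy(10e-9, kd)
    print(f"{name}: Kd = {kd * 1e12:.0f} pM, occupancy at 10 nM = {100 * occ:.2f}%")

# a competitive (Hill slope 1) inhibition curve and its Cheng-Prusoff IC50
L, kd, ki = 1e-9, kd_from_log_affinity(10.35), 2e-9
concs = np.logspace(-11, -6, 6)
bound = competition_curve(L, kd, concs, ki)
print("\ncompetition curve (tracer bound fraction vs competitor):")
for c, b in zip(concs, bound):
    print(f"  I = {c:9.2e} M  ->  bound = {b:.3f}")
print(f"Cheng-Prusoff IC50 = Ki*(1 + L/Kd) = {ki * (1 + L / kd):.3e} M")
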