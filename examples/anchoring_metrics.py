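"""Tyr-membrane anchoring metrics as a function of probe depth.

Generates toy membrane slabs with a Tyr-like sidechain at several depths and
reports the four anchoring observables: hydrogen bonds to headgroups,
pi-cation contacts with cholines, hydrophobic C-C contacts with lipid tails,
and the sidechain surface area buried by the tails. Anchoring is strongest
when the ring sits just below the headgroup plane.
"""

from bklinker.anchor import (InteractionCriteria, count_cc_contacts,
                             count_hbonds, count_pi_cation, lipid_burial_sasa)
from bklinker.synth import ToyMembraneSpec, gen_membrane_toy
from bklinker.traj import Selection

ring = Selection(chain_id="A", atom_names=["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])
oh = Selection(chain_id="A", atom_names=["OH"])
side = Selection(chain_id="A")
cholines = Selection(segment_class="lipid", atom_names=["N"])
acceptors = Selection(segment_class="lipid", atom_names=["N", "P"])
tails = Selection(segment_class="lipid", atom_names=[f"C2{i}" for i in range(2, 9)])
crit = InteractionCriteria()  # 4.5 A C-C, 5.0 A pi-cation, 3.0 A / 150 deg H-bond

print(f"{'depth z (A)':>12} {'H-bond':>7} {'pi-cation':>10} {'C-C':>5} {'burial (A^2)':>13}")
for z in (28.0, 22.0, 18.0, 15.5, 13.0):
    traj, _ = gen_membrane_toy(ToyMembraneSpec(probe_xy=(12.0, 12.0), probe_z=z))
    print(f"{z:>12.1f} "
          f"{count_hbonds(traj, oh, acceptors, crit)[0]:>7d} "
          f"{count_pi_cation(traj, ring, cholines, crit)[0]:>10d} "
          f"{count_cc_contacts(traj, ring, tails, crit)[0]:>5d} "
          f"{lipid_burial_sasa(traj, side, tails, crit)[0]:>13.1f}")
# Interface depths (z just below the 18 A phosphate plane) maximize the mix
# of polar (H-bond, pi-cation) and hydrophobic (C-C, burial) interactions --
# the signature of aromatic membrane anchoring.
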