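"""Write synthetic fixtures (PDB/DCD, CSV, JSON sidecars) to ./fixtures.

Every generator is seeded and documents its ground truth next to the data,
so any stage of the pipeline can be exercised without external downloads.
"""

import os

import numpy as np

from bklinker.hamodel import wt_ha_parameters
from bklinker.synth import (PlantedSpec, ToyMembraneSpec, gen_corr_traj,
                            gen_ha_gv, gen_membrane_toy, write_ground_truth)
from bklinker.traj import write_trajectory

out = "fixtures"
os.makedirs(out, exist_ok=True)

traj, C, adjacency = gen_corr_traj(PlantedSpec(n_chains=2, n_residues=10,
                                               n_frames=1000, seed=1))
write_trajectory(traj, f"{out}/planted.pdb", f"{out}/planted.dcd")
write_ground_truth({"n_planted_contacts": len(adjacency),
                    "same_block_C": float(C[C < 1].max())},
                   f"{out}/planted_truth.json")
print(f"planted trajectory: {traj.n_frames} frames, {traj.n_atoms} beads, "
      f"{len(adjacency)} planted contacts")

mem, truth = gen_membrane_toy(ToyMembraneSpec(probe_xy=(12.0, 12.0),
                                              probe_z=15.5, seed=2))
write_trajectory(mem, f"{out}/membrane.pdb")
write_ground_truth(truth, f"{out}/membrane_truth.json")
print(f"toy membrane: {mem.n_atoms} atoms; ground truth {truth}")

curve, gv_truth = gen_ha_gv(wt_ha_parameters(), 0.0,
                            np.arange(-100.0, 351.0, 10.0),
                            noise_sd=0.02, seed=3)
curve.to_frame().to_csv(f"{out}/ha_gv.csv", index=False)
write_ground_truth(gv_truth, f"{out}/ha_gv_truth.json")
print(f"HA-model G-V table: {len(curve.voltages)} voltages, "
      f"true V0.5 = {gv_truth['V05']:.1f} mV")
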