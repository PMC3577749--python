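"""Track hydrogen-bond persistence through a synthetic trajectory.

The disulfide-closed cyclic peptide template carries the six backbone
ladder bonds (60↔70, 62↔68, 64↔66, both directions).  One of them,
Gln70(NH)→Met60(O)-style, is scheduled to exist in exactly 70% of frames;
the existence profile recovers that fraction exactly.
"""

import numpy as np

from pepdimer import synthetic as syn
from pepdimer.hbonds import (
    HBondKey,
    existence_profile,
    mean_hbonds_per_frame,
    persistent_bonds,
)
from pepdimer.trajectory import Trajectory

topo, xyz = syn.build_template(syn.default_cyclic_template())
traj = Trajectory(topology=topo, coords=np.repeat(xyz[None], 100, axis=0))
key = HBondKey("B", 70, "NH", "B", 60, "O")
traj = syn.schedule_hbond_presence(traj, key, fraction=0.70, seed=11)

profile = existence_profile(traj, scope="B")
print(f"distinct bonds observed: {len(profile.keys)}")
print(f"mean H-bonds per frame:  {mean_hbonds_per_frame(profile):.2f}")
print("persistence table:")
for k in persistent_bonds(profile, threshold=0.0):
    p = profile.persistence[profile.keys.index(k)]
    print(f"  {k}: {p:.2f}")
# Five ladder bonds persist in every frame (1.00); the scheduled bond shows
# exactly 0.70 — the fraction of frames in which its geometry satisfies the
# 3.5 A / 30 deg criteria.
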