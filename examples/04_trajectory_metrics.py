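"""Trajectory metrics on a synthetic run with planted target values.

The generator builds frames around a toy protein/fatty-acid/water complex
in which every metric has a known value: Gaussian jitter fixes the
expected RMSF at sigma*sqrt(3), the donor-acceptor pair is placed inside
the H-bond criteria in an exact fraction of frames, and the ligand's last
carbon is displaced by a prescribed amount between the first and the last
frame (here 6.92 A, a palmitate-like tail penetration).
"""

from lipidsite import (
    contact_occupancy,
    hbond_occupancy,
    neutralizing_ions,
    penetration_depth,
    pocket_hydration,
    rmsf,
)
from lipidsite.synthetic import gen_trajectory, toy_complex

topo, base = toy_complex()
donor = int(topo.select(resname="LYS", atom_name="N")[0])
acceptor = int(topo.select(resname="PLM", atom_name="O1")[0])
tail = int(topo.select(resname="PLM", atom_name="C16")[0])
anchor = int(topo.select(resname="PLM", atom_name="C1")[0])

traj, truth = gen_trajectory(
    topo, base, n_frames=500, jitter_sigma=0.3,
    hbond_pair=(donor, acceptor), hbond_fraction=0.224,
    tail_atom=tail, tail_displacement=6.92,
    contact_plan={1: 0.6, 3: 0.3},
    water_plan=(1, 3), site_atom=anchor,
    seed=8,
)

occ, _ = hbond_occupancy(traj, [donor], [acceptor])
print(f"H-bond occupancy        : {occ:.1f}%  (planted {100 * truth.hbond_fraction:.1f}%)")

depth = penetration_depth(traj, tail)
print(f"tail penetration depth  : {depth:.2f} A  (planted {truth.tail_displacement} A)")

table = contact_occupancy(traj, topo.selections["ligand"], cutoff=4.0)
for row in table.itertuples():
    if row.occupancy_pct > 0:
        print(f"contact {row.resname}{row.resid:<3d}          : "
              f"{row.occupancy_pct:.1f}% of frames")

values = rmsf(traj)
print(f"median heavy-atom RMSF  : {sorted(values)[len(values) // 2]:.3f} A "
      f"(expected {truth.expected_rmsf:.3f} A for jittered atoms)")

counts, mean = pocket_hydration(traj, [anchor], radius=3.5)
print(f"pocket waters per frame : {mean:.1f}  (planted {truth.water_inside})")

n_na, n_cl = neutralizing_ions(25, -1)
print(f"neutralizing ions       : {n_na} Na+ / {n_cl} Cl-  "
      f"(25 salt pairs, -1 e solute)")
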