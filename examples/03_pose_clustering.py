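"""Cluster docked poses at a 2 A RMSD cutoff.

Docking engines report many poses; grouping them at a fixed in-place RMSD
cutoff with lowest-energy representatives summarizes the result as a few
clusters with occupancy fractions. Here two blobs of 90 and 10 poses stand
in for a dominant and a minor docking mode.
"""

import numpy as np

from lipidsite import cluster_poses
from lipidsite.poses import clustering_to_tsv
from lipidsite.synthetic import gen_pose_set

centers = [np.zeros((5, 3)), np.full((5, 3), 10.0 / np.sqrt(3))]
pose_set, labels = gen_pose_set(
    cluster_centers=centers,
    members_per_cluster=[90, 10],
    spread=0.1,
    energy_ranges=[(-6.0, -5.0), (-4.0, -3.0)],
    seed=13,
)

clustering = cluster_poses(pose_set, cutoff=2.0)
print(clustering_to_tsv(clustering, pose_set))
# Expected: two clusters at 90.0% and 10.0% occupancy, each represented by
# the lowest-energy member of its blob -- the computation behind statements
# like "90% of the docked poses fall in one cluster".
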