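"""Docked-pose RMSD clustering with lowest-energy representatives.

Reproduces the cluster analysis applied to docking output: poses are
grouped at a 2 Å in-place RMSD cutoff (no superposition, no symmetry
mapping), each cluster represented by its lowest-energy member, and
cluster occupancy fractions reported — the quantities behind statements
like "90% of the poses fall in one cluster".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class Pose:
    """One docked ligand conformation: ordered heavy-atom coordinates (Å)
    plus a predicted binding energy (kcal/mol)."""

    id: str
    coords: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError(f"pose {self.id!r}: coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InputError(f"pose {self.id!r}: non-finite coordinates")
        if not np.isfinite(self.energy):
            raise InputError(f"pose {self.id!r}: non-finite energy")


@dataclass
class PoseSet:
    poses: list[Pose] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.poses:
            n = self.poses[0].coords.shape[0]
            for p in self.poses:
                if p.coords.shape[0] != n:
                    raise InputError(
                        f"pose {p.id!r} has {p.coords.shape[0]} atoms, expected {n}"
                    )
        ids = [p.id for p in self.poses]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate pose ids")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


@dataclass
class PoseCluster:
    representative_id: str
    member_ids: list[str]
    occupancy: float


@dataclass
class PoseClustering:
    clusters: list[PoseCluster]
    cutoff: float


def pose_rmsd(a: Pose, b: Pose) -> float:
    """In-place RMSD between two poses (Å): no refitting, atoms matched
    by position in the coordinate list."""
    if a.coords.shape != b.coords.shape:
        raise InputError(
            f"atom-count mismatch: {a.coords.shape[0]} vs {b.coords.shape[0]}"
        )
    d = a.coords - b.coords
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def cluster_poses(pose_set: PoseSet, cutoff: float = 2.0) -> PoseClustering:
    """Greedy energy-ordered clustering at an RMSD cutoff.

    Poses are visited in ascending energy order (ties by id); each unassigned
    pose seeds a cluster and absorbs every unassigned pose with in-place
    RMSD strictly below ``cutoff``. The seed — the cluster's lowest-energy
    member — is its representative. Clusters are returned sorted by
    descending occupancy (ties: ascending representative energy, then id).
    """
    if len(pose_set) == 0:
        raise InputError("empty pose set")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    order = sorted(range(len(pose_set)), key=lambda i: (pose_set.poses[i].energy,
                                                        pose_set.poses[i].id))
    assigned = np.zeros(len(pose_set), dtype=bool)
    clusters: list[PoseCluster] = []
    total = len(pose_set)
    for seed_idx in order:
        if assigned[seed_idx]:
            continue
        seed = pose_set.poses[seed_idx]
        members = []
        for j in order:
            if not assigned[j] and pose_rmsd(seed, pose_set.poses[j]) < cutoff:
                assigned[j] = True
                members.append(pose_set.poses[j].id)
        clusters.append(
            PoseCluster(representative_id=seed.id, member_ids=members,
                        occupancy=len(members) / total)
        )
    energy = {p.id: p.energy for p in pose_set}
    clusters.sort(key=lambda c: (-c.occupancy, energy[c.representative_id],
                                 c.representative_id))
    return PoseClustering(clusters=clusters, cutoff=cutoff)


# --------------------------------------------------------------------------
# I/O: multi-model PDB pose files + 2-column energy TSV
# --------------------------------------------------------------------------

def read_pose_set(pdb_path, energies_path) -> PoseSet:
    """Read poses from a multi-model PDB (HETATM ligand records, one MODEL
    per pose) and energies from a 2-column TSV ``pose_id<TAB>energy``."""
    from .traj import read_frames_pdb  # shared multi-model PDB machinery

    atoms, frames, model_ids = read_frames_pdb(pdb_path, return_model_ids=True)
    energies: dict[str, float] = {}
    with open(energies_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 2:
                raise InputError(
                    f"{energies_path}:{lineno}: expected 2 columns, got {len(f)}"
                )
            energies[f[0]] = float(f[1])
    poses = []
    for mid, coords in zip(model_ids, frames):
        pid = str(mid)
        if pid not in energies:
            raise InputError(f"no energy for pose {pid!r} in {energies_path}")
        poses.append(Pose(id=pid, coords=coords, energy=energies[pid]))
    return PoseSet(poses=poses)


def write_pose_set(pose_set: PoseSet, pdb_path, energies_path,
                   resname: str = "LIG") -> None:
    """Write poses as a multi-model PDB of HETATM carbons plus an energy TSV.

    Atom metadata is generic (pose coordinates carry no topology); the
    format is sufficient for round-tripping coordinates and energies.
    """
    with open(pdb_path, "w") as fh:
        for k, pose in enumerate(pose_set, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            for i, (x, y, z) in enumerate(pose.coords, start=1):
                fh.write(
                    f"HETATM{i:5d}  C{i % 100:<2d}{resname:>4s} L{1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
    with open(energies_path, "w") as fh:
        for k, pose in enumerate(pose_set, start=1):
            fh.write(f"{k}\t{pose.energy:.6g}\n")


def clustering_to_tsv(clustering: PoseClustering, pose_set: PoseSet) -> str:
    """Report: rank, representative, size, occupancy %, representative energy."""
    energy = {p.id: p.energy for p in pose_set}
    lines = [
        f"# pose clustering, cutoff {clustering.cutoff:.2f} A (in-place RMSD)",
        "rank\trepresentative\tsize\toccupancy_pct\trep_energy_kcal_mol",
    ]
    for k, c in enumerate(clustering.clusters, start=1):
        lines.append(
            f"{k}\t{c.representative_id}\t{len(c.member_ids)}\t"
            f"{100.0 * c.occupancy:.1f}\t{energy[c.representative_id]:.3f}"
        )
    return "\n".join(lines) + "\n"
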