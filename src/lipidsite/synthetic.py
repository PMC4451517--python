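"""Seeded generators with known ground truth for every pipeline stage.

These stand in for data that cannot be redistributed or regenerated at
desk scale: the FABP-derived profile library (emulated by sequence
families with a planted binding motif), docking output (pose sets with
known cluster structure), and MD trajectories (frames with prescribed
fluctuation, hydrogen-bond occupancy, contacts, tail displacement and
pocket hydration). Every generator is a pure function of its arguments:
the same seed gives bitwise-identical output within this implementation.

The generated geometries are deliberately non-physical — atoms are placed
wherever the target statistic requires — so recovering a planted value
tests the estimator, not molecular realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .poses import Pose, PoseSet
from .pssm import ALPHABET, ProfileLibrary, build_pssm
from .traj import Atom, Topology, Trajectory

GAP = "-"


# --------------------------------------------------------------------------
# Sequence generators
# --------------------------------------------------------------------------

def gen_motif_family(
    motif: str, n_seqs: int, substitution_rate: float, seed: int
) -> tuple[list[str], tuple[int, int]]:
    """A gapless alignment of noisy motif copies, plus the true interval.

    Each position of each copy is independently replaced by a uniformly
    chosen *other* residue with probability ``substitution_rate``
    (must be < 0.5 so the motif stays the columnwise majority in
    expectation).
    """
    if not motif:
        raise InputError("empty motif")
    if not (0 <= substitution_rate < 0.5):
        raise InputError("substitution_rate must lie in [0, 0.5)")
    if n_seqs < 1:
        raise InputError("n_seqs must be >= 1")
    for ch in motif:
        if ch not in ALPHABET:
            raise InputError(f"motif symbol {ch!r} outside alphabet")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_seqs):
        chars = list(motif)
        for p in range(len(chars)):
            if rng.random() < substitution_rate:
                alternatives = [a for a in ALPHABET if a != chars[p]]
                chars[p] = alternatives[rng.integers(len(alternatives))]
        rows.append("".join(chars))
    return rows, (0, len(motif))


def gen_query(
    background_length: int, motif: str, insert_position: int, seed: int
) -> tuple[str, tuple[int, int]]:
    """A uniform-random background sequence with ``motif`` spliced in.

    Returns the sequence and the motif's 0-based half-open interval.
    """
    if background_length < 0:
        raise InputError("background_length must be non-negative")
    if not (0 <= insert_position <= background_length):
        raise InputError(
            f"insert_position {insert_position} outside [0, {background_length}]"
        )
    rng = np.random.default_rng(seed)
    bg = "".join(ALPHABET[i] for i in rng.integers(len(ALPHABET), size=background_length))
    seq = bg[:insert_position] + motif + bg[insert_position:]
    return seq, (insert_position, insert_position + len(motif))


def random_motif(length: int, seed: int) -> str:
    """Uniform random residue string (a synthetic binding motif)."""
    if length < 1:
        raise InputError("motif length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(ALPHABET[i] for i in rng.integers(len(ALPHABET), size=length))


def gen_scan_benchmark(
    motif_length: int = 20,
    n_seqs: int = 50,
    substitution_rate: float = 0.1,
    background_length: int = 150,
    n_profiles: int = 10,
    seed: int = 0,
) -> tuple[ProfileLibrary, str, tuple[int, int], str]:
    """End-to-end planted-motif benchmark for the scanning pipeline.

    A random motif seeds a noisy family of ``n_seqs`` copies; the family is
    partitioned into ``n_profiles`` disjoint sub-alignments, each built into
    one PSSM, giving a motif-bearing library. A query of
    ``background_length`` random residues carries one motif copy at a random
    position. Returns ``(library, query, true_interval, motif)``.
    """
    if n_seqs % n_profiles != 0:
        raise InputError("n_seqs must be divisible by n_profiles")
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731 - derived subseeds
    motif = random_motif(motif_length, sub())
    family, _ = gen_motif_family(motif, n_seqs, substitution_rate, sub())
    per = n_seqs // n_profiles
    entries = [
        build_pssm(family[k * per : (k + 1) * per], name=f"fam_{k:04d}")
        for k in range(n_profiles)
    ]
    insert = int(rng.integers(background_length + 1))
    query, interval = gen_query(background_length, motif, insert, sub())
    return ProfileLibrary(entries=entries), query, interval, motif


def motif_recovery_jaccard(seed: int, **benchmark_kwargs) -> float:
    """Run the full planted-motif pipeline once; return the Jaccard overlap.

    Generates a benchmark library and query with :func:`gen_scan_benchmark`,
    scans under the two default parameter sets, aggregates and normalizes
    the positional scores, calls enriched regions, and returns the Jaccard
    index between the top-ranked region and the true motif interval
    (0.0 when no region is called).
    """
    from .align import scan_library
    from .scoring import detect_enriched_regions, normalize_track, raw_residue_scores

    library, query, (lo, hi), _motif = gen_scan_benchmark(
        seed=seed, **benchmark_kwargs
    )
    hits = scan_library(query, library)
    track = normalize_track(raw_residue_scores(hits, len(query)))
    regions = detect_enriched_regions(track)
    if not regions:
        return 0.0
    top = regions[0]
    inter = max(0, min(top.end, hi) - max(top.start, lo))
    union = (top.end - top.start) + (hi - lo) - inter
    return inter / union


# --------------------------------------------------------------------------
# Pose-set generator
# --------------------------------------------------------------------------

def gen_pose_set(
    cluster_centers: list[np.ndarray],
    members_per_cluster: list[int],
    spread: float,
    energy_ranges: list[tuple[float, float]],
    seed: int,
) -> tuple[PoseSet, list[int]]:
    """Poses drawn around known cluster centers, plus true labels.

    Each pose is its cluster center plus isotropic Gaussian noise of the
    given spread (Å); energies are uniform within the cluster's range.
    Exact recovery by 2 Å clustering is guaranteed when centers are farther
    apart than ``2 * (cutoff + 3 * spread)``.
    """
    if not (len(cluster_centers) == len(members_per_cluster) == len(energy_ranges)):
        raise InputError("cluster parameter lists have inconsistent lengths")
    if spread < 0:
        raise InputError("spread must be non-negative")
    rng = np.random.default_rng(seed)
    poses: list[Pose] = []
    labels: list[int] = []
    k = 0
    for c, (center, n, (e_lo, e_hi)) in enumerate(
        zip(cluster_centers, members_per_cluster, energy_ranges)
    ):
        center = np.atleast_2d(np.asarray(center, dtype=float))
        for _ in range(n):
            k += 1
            coords = center + rng.normal(0.0, spread, size=center.shape)
            energy = float(rng.uniform(e_lo, e_hi))
            poses.append(Pose(id=f"pose_{k:04d}", coords=coords, energy=energy))
            labels.append(c)
    return PoseSet(poses=poses), labels


# --------------------------------------------------------------------------
# Trajectory generator
# --------------------------------------------------------------------------

@dataclass
class TrajectoryGroundTruth:
    """Planted target values for every trajectory metric."""

    n_frames: int
    jitter_sigma: float
    expected_rmsf: float                       # sigma * sqrt(3) for jittered atoms
    hbond_fraction: float = 0.0
    bound_frames: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    hbond_pair: tuple[int, int] | None = None
    tail_atom: int | None = None
    tail_displacement: float = 0.0
    contact_fractions: dict[int, float] = field(default_factory=dict)
    contact_frames: dict[int, np.ndarray] = field(default_factory=dict)
    water_inside: int = 0
    water_outside: int = 0
    site_atom: int | None = None
    water_radius: float = 3.5

    def to_tsv(self) -> str:
        """Sidecar key/value export of the planted targets."""
        rows = [
            ("n_frames", self.n_frames),
            ("jitter_sigma_A", self.jitter_sigma),
            ("expected_rmsf_A", self.expected_rmsf),
            ("hbond_fraction", self.hbond_fraction),
            ("n_bound_frames", len(self.bound_frames)),
            ("tail_displacement_A", self.tail_displacement),
            ("water_inside", self.water_inside),
            ("water_outside", self.water_outside),
        ]
        for resid, frac in sorted(self.contact_fractions.items()):
            rows.append((f"contact_fraction_res{resid}", frac))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def toy_complex(
    n_residues: int = 10,
    n_waters: int = 6,
    lys_position: int = 5,
    tail_carbons: int = 15,
    with_hydrogens: bool = False,
) -> tuple[Topology, np.ndarray]:
    """A minimal protein–fatty-acid–water system for trajectory generation.

    A linear chain of ``n_residues`` three-atom residues (N, CA, O; one
    lysine at ``lys_position`` whose backbone N serves as the H-bond
    donor), a fatty-acid-like ligand (carboxyl C1/O1/O2 head plus an alkyl
    tail ending in the "last carbon"), ``n_waters`` water oxygens placed
    far from the complex, and a token heme iron with a dioxygen. Groups are
    separated by >20 Å so that only atoms a generator plan moves can create
    contacts.
    """
    resnames = ["LEU", "PHE", "VAL", "ILE", "GLY", "ALA", "SER", "THR"]
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []

    for r in range(1, n_residues + 1):
        resname = "LYS" if r == lys_position else resnames[(r - 1) % len(resnames)]
        x = 4.0 * r
        for name, elem, dy in (("N", "N", 0.0), ("CA", "C", 1.2), ("O", "O", 2.4)):
            atoms.append(Atom(name=name, element=elem, resname=resname,
                              resid=r, chain="A", is_hydrogen=False))
            coords.append((x, dy, 0.0))
        if with_hydrogens:
            atoms.append(Atom(name="HN", element="H", resname=resname,
                              resid=r, chain="A", is_hydrogen=True))
            coords.append((x, -1.0, 0.0))

    # ligand: carboxyl head + alkyl tail along +z, well away from the chain
    head = [("C1", "C"), ("O1", "O"), ("O2", "O")]
    for k, (name, elem) in enumerate(head):
        atoms.append(Atom(name=name, element=elem, resname="PLM", resid=1,
                          chain="L", is_hydrogen=False, hetero=True))
        coords.append((0.8 * k, 25.0, 0.0))
    for c in range(2, tail_carbons + 2):
        atoms.append(Atom(name=f"C{c}", element="C", resname="PLM", resid=1,
                          chain="L", is_hydrogen=False, hetero=True))
        coords.append((0.0, 25.0, 1.3 * (c - 1)))

    for w in range(n_waters):
        atoms.append(Atom(name="O", element="O", resname="HOH", resid=100 + w,
                          chain="W", is_hydrogen=False, hetero=True))
        coords.append((-30.0, -30.0, 3.0 * w))

    atoms.append(Atom(name="FE", element="FE", resname="HEM", resid=200,
                      chain="H", is_hydrogen=False, hetero=True))
    coords.append((0.0, 60.0, 0.0))
    for k in range(2):
        atoms.append(Atom(name=f"O{k + 1}", element="O", resname="OXY",
                          resid=201, chain="H", is_hydrogen=False, hetero=True))
        coords.append((0.0, 60.0, 3.0 + 1.2 * k))

    from .traj import _default_selections

    topo = Topology(atoms=atoms, selections=_default_selections(atoms))
    return topo, np.array(coords, dtype=float)


def gen_trajectory(
    topology: Topology,
    base_coords: np.ndarray,
    n_frames: int,
    jitter_sigma: float = 0.0,
    hbond_pair: tuple[int, int] | None = None,
    hbond_fraction: float = 0.0,
    hbond_sampling: str = "exact",
    donor_hydrogen: int | None = None,
    hbond_in_distance: float = 2.8,
    hbond_out_distance: float = 8.0,
    tail_atom: int | None = None,
    tail_displacement: float = 0.0,
    contact_plan: dict[int, float] | None = None,
    ligand_anchor: int | None = None,
    contact_distance: float = 3.0,
    water_plan: tuple[int, int] | None = None,
    site_atom: int | None = None,
    water_radius: float = 3.5,
    seed: int = 0,
    frame_interval: float = 1.0,
) -> tuple[Trajectory, TrajectoryGroundTruth]:
    """Frames around a template with exactly planted metric values.

    * Per-atom isotropic Gaussian jitter of ``jitter_sigma`` Å per
      coordinate (expected heavy-atom RMSF ``sigma * sqrt(3)``).
    * ``hbond_pair = (donor, acceptor)``: the acceptor is placed
      ``hbond_in_distance`` Å from the (fixed) donor in bound frames and
      ``hbond_out_distance`` Å otherwise. With the default
      ``hbond_sampling="exact"`` exactly ``round(hbond_fraction *
      n_frames)`` randomly chosen frames are bound (a constructed, not
      sampled, occupancy — separates estimator correctness from sampling
      error); with ``"bernoulli"`` each frame is independently bound with
      probability ``hbond_fraction`` (the stochastic two-state variant,
      subject to binomial sampling error).
    * ``tail_atom`` translates linearly so the first→last displacement is
      exactly ``tail_displacement`` Å.
    * ``contact_plan`` maps protein residue numbers to contact fractions:
      the residue's first heavy atom is placed ``contact_distance`` Å from
      the ligand anchor in the planned fraction of frames, 15 Å away
      otherwise.
    * ``water_plan = (k_inside, m_outside)``: k water oxygens stay within
      ``water_radius`` of ``site_atom``, m stay outside; the rest remain
      far from the complex.

    Atoms a plan positions are excluded from jitter; two plans claiming the
    same atom raise an :class:`InputError`. Returns the trajectory and a
    :class:`TrajectoryGroundTruth` carrying every planted value.
    """
    base = np.asarray(base_coords, dtype=float)
    if base.shape != (len(topology), 3):
        raise InputError("base_coords shape does not match topology")
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    if not (0.0 <= hbond_fraction <= 1.0):
        raise InputError("hbond_fraction must lie in [0, 1]")
    if jitter_sigma < 0 or tail_displacement < 0:
        raise InputError("parameters must be non-negative")

    rng = np.random.default_rng(seed)
    controlled: dict[int, str] = {}

    def claim(idx: int, plan: str) -> None:
        if idx in controlled:
            raise InputError(
                f"conflicting plans: atom {idx} claimed by both "
                f"{controlled[idx]!r} and {plan!r}"
            )
        controlled[idx] = plan

    gt = TrajectoryGroundTruth(
        n_frames=n_frames,
        jitter_sigma=jitter_sigma,
        expected_rmsf=jitter_sigma * math.sqrt(3.0),
    )

    if hbond_pair is not None:
        donor, acceptor = hbond_pair
        claim(donor, "hbond")
        claim(acceptor, "hbond")
        if donor_hydrogen is not None:
            claim(donor_hydrogen, "hbond")
    if tail_atom is not None:
        claim(tail_atom, "tail")
    anchor = ligand_anchor
    if contact_plan:
        if anchor is None:
            lig = topology.selections.get("ligand", np.empty(0, int))
            lig = [i for i in lig if not topology.atoms[i].is_hydrogen]
            if not lig:
                raise InputError("contact_plan requires a ligand anchor atom")
            anchor = int(lig[0])
        claim(anchor, "contact-anchor")
    plan_waters: list[int] = []
    if water_plan is not None:
        k_in, m_out = water_plan
        waters = topology.selections.get("water-oxygen", np.empty(0, int))
        if k_in + m_out > waters.size:
            raise InputError(
                f"water plan needs {k_in + m_out} waters, topology has {waters.size}"
            )
        if site_atom is None:
            raise InputError("water_plan requires site_atom")
        plan_waters = [int(w) for w in waters[: k_in + m_out]]
        for w in plan_waters:
            claim(w, "water")
        if site_atom not in controlled:
            claim(site_atom, "water-site")

    frames = np.broadcast_to(base, (n_frames,) + base.shape).copy()
    if jitter_sigma > 0:
        jitter = rng.normal(0.0, jitter_sigma, size=frames.shape)
        if controlled:
            jitter[:, sorted(controlled), :] = 0.0
        frames += jitter

    if hbond_pair is not None:
        donor, acceptor = hbond_pair
        if hbond_sampling == "exact":
            n_bound = round(hbond_fraction * n_frames)
            bound = np.sort(rng.choice(n_frames, size=n_bound, replace=False))
        elif hbond_sampling == "bernoulli":
            bound = np.nonzero(rng.random(n_frames) < hbond_fraction)[0]
        else:
            raise InputError(f"unknown hbond_sampling {hbond_sampling!r}")
        u = base[acceptor] - base[donor]
        norm = np.linalg.norm(u)
        u = u / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        is_bound = np.zeros(n_frames, dtype=bool)
        is_bound[bound] = True
        # unbound frames keep the acceptor at its template position when that
        # is already distant (avoids parking it near unrelated atoms)
        unbound_pos = (
            base[acceptor]
            if norm >= hbond_out_distance
            else base[donor] + hbond_out_distance * u
        )
        frames[:, acceptor] = np.where(
            is_bound[:, None], base[donor] + hbond_in_distance * u, unbound_pos
        )
        if donor_hydrogen is not None:
            frames[:, donor_hydrogen] = base[donor] + 1.0 * u
        gt.hbond_fraction = hbond_fraction
        gt.bound_frames = bound
        gt.hbond_pair = hbond_pair

    if tail_atom is not None:
        direction = np.array([0.0, 0.0, 1.0])
        if n_frames > 1:
            t = np.linspace(0.0, 1.0, n_frames)
            frames[:, tail_atom] = base[tail_atom] + np.outer(
                t * tail_displacement, direction
            )
        gt.tail_atom = tail_atom
        gt.tail_displacement = tail_displacement if n_frames > 1 else 0.0

    if contact_plan:
        n_plan = len(contact_plan)
        for k, (resid, frac) in enumerate(sorted(contact_plan.items())):
            if not (0.0 <= frac <= 1.0):
                raise InputError(f"contact fraction for residue {resid} not in [0,1]")
            idx = topology.select(resid=resid, heavy_only=True)
            idx = [i for i in idx if not topology.atoms[i].hetero]
            if not idx:
                raise InputError(f"contact_plan: no heavy atoms in residue {resid}")
            atom = int(idx[0])
            claim(atom, f"contact-res{resid}")
            ang = 2.0 * math.pi * k / max(n_plan, 1)
            d = np.array([math.cos(ang), -1.0, math.sin(ang)])
            d /= np.linalg.norm(d)
            n_contact = round(frac * n_frames)
            chosen = np.sort(rng.choice(n_frames, size=n_contact, replace=False))
            in_contact = np.zeros(n_frames, dtype=bool)
            in_contact[chosen] = True
            frames[:, atom] = base[anchor] + np.where(
                in_contact[:, None], contact_distance, 15.0
            ) * d
            gt.contact_fractions[resid] = frac
            gt.contact_frames[resid] = chosen

    if water_plan is not None:
        k_in, m_out = water_plan
        for j, w in enumerate(plan_waters):
            ang = 2.0 * math.pi * j / max(len(plan_waters), 1)
            d = np.array([math.cos(ang), math.sin(ang), 0.3])
            d /= np.linalg.norm(d)
            r = (water_radius - 1.0) if j < k_in else (water_radius + 10.0)
            frames[:, w] = base[site_atom] + r * d
        gt.water_inside = k_in
        gt.water_outside = m_out
        gt.site_atom = site_atom
        gt.water_radius = water_radius

    traj = Trajectory(topology=topology, frames=frames,
                      frame_interval=frame_interval)
    return traj, gt
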