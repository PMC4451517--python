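"""MD-trajectory post-processing: RMSF, H-bond and contact occupancy,
tail penetration depth, pocket hydration, and the neutralizing-ion helper.

Trajectories are ordered coordinate frames over a fixed atom table
(:class:`Topology`), read from desk-scale text formats: multi-model PDB
(MODEL/ENDMDL) or XYZ. Frames are typically saved every picosecond.
Ligand-relative metrics assume the trajectory has first been superposed
onto a reference frame's protein heavy atoms, which removes global
rotation/diffusion; :func:`superpose_frames` provides the Kabsch fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, InputError, ParseError

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
    "TYR", "VAL",
}
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "SPC"}
HEME_RESNAMES = {"HEM", "HEME"}
DIOXYGEN_RESNAMES = {"OXY", "DOX"}

KNOWN_ELEMENTS = {
    "H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I", "NA", "K", "MG",
    "CA", "FE", "ZN", "MN", "CU", "SE",
}

SELECTION_NAMES = ("protein", "ligand", "heme", "dioxygen", "water-oxygen")


class Atom(NamedTuple):
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    is_hydrogen: bool
    hetero: bool = False


@dataclass
class Topology:
    """Fixed, ordered atom table with named index-set selections.

    The named selections (protein / ligand / heme / dioxygen /
    water-oxygen) are pairwise disjoint; any may be empty.
    """

    atoms: list[Atom]
    selections: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for name in SELECTION_NAMES:
            self.selections.setdefault(name, np.empty(0, dtype=int))
        seen: set[int] = set()
        for name, idx in self.selections.items():
            idx = np.asarray(idx, dtype=int)
            self.selections[name] = idx
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise InputError(f"selection {name!r} index out of bounds")
            if name in SELECTION_NAMES:
                overlap = seen.intersection(idx.tolist())
                if overlap:
                    raise InputError(
                        f"selection {name!r} overlaps another named selection "
                        f"at atoms {sorted(overlap)[:5]}"
                    )
                seen.update(idx.tolist())

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def heavy(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int
        )

    def select(
        self,
        chain: str | None = None,
        resid: int | None = None,
        resname: str | None = None,
        atom_name: str | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Indices of atoms matching every given field."""
        out = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain != chain:
                continue
            if resid is not None and a.resid != resid:
                continue
            if resname is not None and a.resname != resname:
                continue
            if atom_name is not None and a.name != atom_name:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            out.append(i)
        return np.array(out, dtype=int)


@dataclass
class Trajectory:
    topology: Topology
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_interval: float = 1.0  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InputError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise InputError("trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise InputError(
                f"{self.frames.shape[1]} coordinates per frame but "
                f"{len(self.topology)} topology atoms"
            )
        if not np.all(np.isfinite(self.frames)):
            raise InputError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    Defaults (donor–acceptor heavy-atom distance ≤ 3.5 Å, donor-H···acceptor
    deviation from linearity ≤ 30°) follow common MD practice; both are
    configurable and echoed in output headers. When the topology carries no
    hydrogens the angle term is skipped (distance-only mode).
    """

    max_distance: float = 3.5
    max_angle_deviation: float = 30.0

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise InputError("max_distance must be positive")
        if not (0 < self.max_angle_deviation <= 90):
            raise InputError("max_angle_deviation must lie in (0, 90] degrees")


# --------------------------------------------------------------------------
# Element handling
# --------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {name!r}")
    two = stripped[:2].upper()
    if two in KNOWN_ELEMENTS and two.isalpha():
        # two-letter candidates like FE, CL, NA; but avoid eating CA (calcium)
        # for protein alpha-carbons — resolved by caller context; default to
        # one-letter when the first letter alone is an element.
        if stripped[0].upper() in KNOWN_ELEMENTS and two not in {"FE", "CL", "NA", "BR", "MG", "ZN", "MN", "SE", "CU"}:
            return stripped[0].upper()
        return two
    one = stripped[0].upper()
    if one in KNOWN_ELEMENTS:
        return one
    raise ParseError(f"unknown element for atom name {name!r}")


# --------------------------------------------------------------------------
# Multi-model PDB and XYZ I/O
# --------------------------------------------------------------------------

def read_frames_pdb(path, return_model_ids: bool = False):
    """Low-level multi-model PDB reader.

    Returns ``(atoms, frames)`` — the atom table from the first MODEL and a
    ``(n_frames, n_atoms, 3)`` array — or additionally the MODEL serial
    numbers. Atom-count or identity drift between frames is a
    :class:`ParseError` naming the frame.
    """
    atoms: list[Atom] = []
    frames: list[list[tuple[float, float, float]]] = []
    model_ids: list[int] = []
    current: list[tuple[float, float, float]] | None = None
    in_model = False
    n_models_seen = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                n_models_seen += 1
                current = []
                try:
                    model_ids.append(int(line.split()[1]))
                except (IndexError, ValueError):
                    model_ids.append(n_models_seen)
            elif rec == "ENDMDL":
                if current is None:
                    raise ParseError(f"{path}:{lineno}: ENDMDL without MODEL")
                frames.append(current)
                frame_no = len(frames)
                if len(current) != len(atoms):
                    raise ParseError(
                        f"{path}: frame {frame_no} has {len(current)} atoms, "
                        f"expected {len(atoms)}"
                    )
                current = None
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    if frames:
                        raise ParseError(
                            f"{path}:{lineno}: coordinate record outside MODEL"
                        )
                    current = []  # single-frame file without MODEL cards
                    model_ids.append(1)
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: malformed coordinates"
                    ) from None
                current.append((x, y, z))
                if len(frames) == 0:
                    name = line[12:16].strip()
                    elem_field = line[76:78].strip() if len(line) >= 78 else ""
                    if elem_field:
                        element = elem_field.upper()
                        if element not in KNOWN_ELEMENTS:
                            raise ParseError(
                                f"{path}:{lineno}: unknown element {elem_field!r}"
                            )
                    else:
                        element = _element_from_name(name)
                    try:
                        resid = int(line[22:26])
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: malformed residue number"
                        ) from None
                    atoms.append(
                        Atom(
                            name=name,
                            element=element,
                            resname=line[17:20].strip(),
                            resid=resid,
                            chain=line[21].strip(),
                            is_hydrogen=(element == "H"),
                            hetero=(rec == "HETATM"),
                        )
                    )
    if current is not None:
        if in_model:
            raise ParseError(f"{path}: final MODEL not closed by ENDMDL")
        frames.append(current)
    if not frames:
        raise ParseError(f"{path}: no coordinate frames found")
    arr = np.array(frames, dtype=float)
    if return_model_ids:
        return atoms, arr, model_ids
    return atoms, arr


def _default_selections(atoms: list[Atom]) -> dict[str, np.ndarray]:
    sel: dict[str, list[int]] = {name: [] for name in SELECTION_NAMES}
    for i, a in enumerate(atoms):
        if a.resname in WATER_RESNAMES:
            if a.element == "O":
                sel["water-oxygen"].append(i)
        elif a.resname in HEME_RESNAMES:
            sel["heme"].append(i)
        elif a.resname in DIOXYGEN_RESNAMES:
            sel["dioxygen"].append(i)
        elif a.resname in PROTEIN_RESNAMES:
            sel["protein"].append(i)
        elif a.hetero:
            sel["ligand"].append(i)
    return {k: np.array(v, dtype=int) for k, v in sel.items()}


def read_trajectory(path, fmt: str | None = None,
                    frame_interval: float = 1.0) -> Trajectory:
    """Read a trajectory from multi-model PDB or XYZ.

    ``fmt`` is ``'pdb'`` or ``'xyz'``; inferred from the extension when
    omitted. Named selections are derived from residue names (PDB) and are
    empty for XYZ input, which carries no residue information.
    """
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    if fmt == "pdb":
        atoms, frames = read_frames_pdb(path)
        topo = Topology(atoms=atoms, selections=_default_selections(atoms))
        return Trajectory(topology=topo, frames=frames,
                          frame_interval=frame_interval)
    if fmt == "xyz":
        atoms, frames = _read_frames_xyz(path)
        return Trajectory(
            topology=Topology(atoms=atoms),
            frames=frames,
            frame_interval=frame_interval,
        )
    raise InputError(f"unsupported trajectory format {fmt!r}")


def _read_frames_xyz(path):
    atoms: list[Atom] = []
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path}:{i + 1}: expected atom count for frame {frame_no}"
            ) from None
        if i + 1 + n >= len(lines) + 1:
            raise ParseError(f"{path}: frame {frame_no} truncated")
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: frame {frame_no} truncated")
        coords = []
        for k, ln in enumerate(block):
            f = ln.split()
            if len(f) < 4:
                raise ParseError(
                    f"{path}:{i + 3 + k}: malformed XYZ atom line in frame {frame_no}"
                )
            elem = f[0].upper()
            if elem not in KNOWN_ELEMENTS:
                raise ParseError(f"{path}:{i + 3 + k}: unknown element {f[0]!r}")
            if frame_no == 1:
                atoms.append(
                    Atom(name=f[0], element=elem, resname="UNK", resid=1,
                         chain="", is_hydrogen=(elem == "H"))
                )
            else:
                if elem != atoms[k].element:
                    raise ParseError(
                        f"{path}: frame {frame_no} atom {k + 1}: element "
                        f"{f[0]!r} differs from frame 1"
                    )
            coords.append([float(f[1]), float(f[2]), float(f[3])])
        if frame_no > 1 and n != len(atoms):
            raise ParseError(
                f"{path}: frame {frame_no} has {n} atoms, expected {len(atoms)}"
            )
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return atoms, np.array(frames, dtype=float)


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or XYZ (coords at 3 decimals
    for PDB, 6 for XYZ)."""
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    if fmt == "pdb":
        with open(path, "w") as fh:
            for m in range(traj.n_frames):
                fh.write(f"MODEL     {m + 1:4d}\n")
                for i, a in enumerate(traj.topology.atoms):
                    x, y, z = traj.frames[m, i]
                    rec = "HETATM" if a.hetero else "ATOM  "
                    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                    fh.write(
                        f"{rec}{(i % 99999) + 1:5d} {name:<4.4s} {a.resname:<3.3s} "
                        f"{a.chain or 'A':1.1s}{a.resid:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {a.element:>2.2s}\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif fmt == "xyz":
        with open(path, "w") as fh:
            for m in range(traj.n_frames):
                fh.write(f"{len(traj.topology)}\n")
                fh.write(f"frame {m + 1}\n")
                for i, a in enumerate(traj.topology.atoms):
                    x, y, z = traj.frames[m, i]
                    fh.write(f"{a.element.capitalize()} {x:.6f} {y:.6f} {z:.6f}\n")
    else:
        raise InputError(f"unsupported trajectory format {fmt!r}")


# --------------------------------------------------------------------------
# Superposition and metrics
# --------------------------------------------------------------------------

def superpose_frames(
    traj: Trajectory,
    reference_frame_index: int = 0,
    fit_selection: np.ndarray | None = None,
) -> Trajectory:
    """Least-squares (Kabsch) superposition of every frame onto a reference.

    Each frame is rigid-body transformed so that the RMSD of
    ``fit_selection`` (default: protein heavy atoms, else all heavy atoms)
    onto the reference frame is minimal.
    """
    if not (0 <= reference_frame_index < traj.n_frames):
        raise InputError(f"reference frame {reference_frame_index} out of range")
    if fit_selection is None:
        prot = traj.topology.selections.get("protein", np.empty(0, int))
        heavy = traj.topology.heavy
        fit_selection = (
            np.intersect1d(prot, heavy) if prot.size else heavy
        )
    fit_selection = np.asarray(fit_selection, dtype=int)
    if fit_selection.size < 3:
        raise InputError("superposition needs at least 3 fit atoms")

    ref = traj.frames[reference_frame_index, fit_selection]
    ref_centroid = ref.mean(axis=0)
    ref_c = ref - ref_centroid
    out = np.empty_like(traj.frames)
    for m in range(traj.n_frames):
        mob = traj.frames[m, fit_selection]
        mob_centroid = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob - mob_centroid)
        out[m] = (traj.frames[m] - mob_centroid) @ rot.as_matrix().T + ref_centroid
    return Trajectory(topology=traj.topology, frames=out,
                      frame_interval=traj.frame_interval)


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    per_residue: bool = False,
):
    """Root-mean-square fluctuation about the time-mean position.

    ``RMSF_i = sqrt( <|r_i(t) - <r_i>|^2> )``. By default only heavy atoms
    are considered (hydrogens excluded). With ``per_residue`` the atomic
    values are averaged within each residue and returned as a
    :class:`pandas.Series` indexed by ``CHAIN:RESNAME:RESID``.
    """
    if traj.n_frames < 2:
        raise DegenerateInputError("RMSF needs at least 2 frames")
    if selection is None:
        selection = traj.topology.heavy
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise InputError("empty RMSF selection")
    coords = traj.frames[:, selection]            # (F, n, 3)
    rel = coords - coords[0]  # conditioning: exact zeros for static input
    mean = rel.mean(axis=0)
    dev2 = ((rel - mean) ** 2).sum(axis=2)        # (F, n)
    per_atom = np.sqrt(dev2.mean(axis=0))
    if not per_residue:
        return per_atom
    labels = [
        f"{traj.topology.atoms[i].chain}:{traj.topology.atoms[i].resname}:"
        f"{traj.topology.atoms[i].resid}"
        for i in selection
    ]
    s = pd.Series(per_atom, index=labels)
    return s.groupby(level=0, sort=False).mean()


def hbond_occupancy(
    traj: Trajectory,
    donor_atoms: np.ndarray,
    acceptor_atoms: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[float, np.ndarray]:
    """Percentage of frames with at least one satisfied donor–acceptor pair.

    A pair is satisfied when the heavy-atom distance is within
    ``criteria.max_distance`` and — if the topology contains hydrogens — a
    hydrogen covalently attached to the donor (within 1.25 Å) exists whose
    D–H···A angle deviates from linear by at most
    ``criteria.max_angle_deviation`` degrees. Without hydrogens the check
    is distance-only. Returns ``(occupancy_percent, per-frame flags)``.
    """
    donor_atoms = np.asarray(donor_atoms, dtype=int)
    acceptor_atoms = np.asarray(acceptor_atoms, dtype=int)
    if donor_atoms.size == 0 or acceptor_atoms.size == 0:
        raise InputError("empty donor or acceptor selection")
    h_idx = np.array(
        [i for i, a in enumerate(traj.topology.atoms) if a.is_hydrogen], dtype=int
    )
    use_angle = h_idx.size > 0

    d = traj.frames[:, donor_atoms, None, :] - traj.frames[:, None, acceptor_atoms, :]
    dist = np.sqrt((d ** 2).sum(axis=3))           # (F, nd, na)
    within = dist <= criteria.max_distance
    flags = within.any(axis=(1, 2))

    if use_angle:
        for f in np.nonzero(flags)[0]:
            ok = False
            for di, ai in zip(*np.nonzero(within[f])):
                dpos = traj.frames[f, donor_atoms[di]]
                apos = traj.frames[f, acceptor_atoms[ai]]
                hd = np.linalg.norm(traj.frames[f, h_idx] - dpos, axis=1)
                for h in h_idx[hd <= 1.25]:
                    hpos = traj.frames[f, h]
                    v1 = dpos - hpos
                    v2 = apos - hpos
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2)
                    )
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if 180.0 - ang <= criteria.max_angle_deviation:
                        ok = True
                        break
                if ok:
                    break
            flags[f] = ok

    occupancy = 100.0 * float(flags.sum()) / traj.n_frames
    return occupancy, flags


def contact_occupancy(
    traj: Trajectory,
    ligand_selection: np.ndarray,
    cutoff: float = 4.0,
) -> pd.DataFrame:
    """Per-residue heavy-atom contact occupancy with the ligand.

    For every protein residue, the percentage of frames in which any of
    its heavy atoms lies within ``cutoff`` Å of any ligand heavy atom.
    Returns a DataFrame (chain, resid, resname, occupancy_pct) sorted by
    descending occupancy, then residue number.
    """
    ligand_selection = np.asarray(ligand_selection, dtype=int)
    if ligand_selection.size == 0:
        raise InputError("empty ligand selection")
    heavy = set(traj.topology.heavy.tolist())
    lig = np.array([i for i in ligand_selection if i in heavy], dtype=int)
    if lig.size == 0:
        raise InputError("ligand selection contains no heavy atoms")

    prot = traj.topology.selections.get("protein", np.empty(0, int))
    if prot.size == 0:
        prot = np.array(
            [i for i in traj.topology.heavy if i not in set(lig.tolist())],
            dtype=int,
        )
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i in prot:
        a = traj.topology.atoms[i]
        if a.is_hydrogen:
            continue
        groups.setdefault((a.chain, a.resid, a.resname), []).append(i)

    rows = []
    for (chain, resid, resname), idx in groups.items():
        idx = np.array(idx, dtype=int)
        hit = 0
        for f in range(traj.n_frames):
            if cdist(traj.frames[f, idx], traj.frames[f, lig]).min() <= cutoff:
                hit += 1
        rows.append((chain, resid, resname, 100.0 * hit / traj.n_frames))
    df = pd.DataFrame(rows, columns=["chain", "resid", "resname", "occupancy_pct"])
    return df.sort_values(
        ["occupancy_pct", "resid"], ascending=[False, True]
    ).reset_index(drop=True)


def penetration_depth(traj: Trajectory, tail_atom_index: int) -> float:
    """Displacement (Å) of the ligand's terminal (last-carbon) atom between
    the first and the last frame.

    Meaningful in a protein-fixed frame, i.e. after superposition; unlike
    the other metrics this one is sensitive to frame order.
    """
    if not (0 <= tail_atom_index < len(traj.topology)):
        raise InputError(f"tail atom index {tail_atom_index} out of range")
    if traj.n_frames < 2:
        raise DegenerateInputError("penetration depth needs at least 2 frames")
    d = traj.frames[-1, tail_atom_index] - traj.frames[0, tail_atom_index]
    return float(np.linalg.norm(d))


def pocket_hydration(
    traj: Trajectory,
    site_atoms: np.ndarray,
    radius: float = 3.5,
) -> tuple[np.ndarray, float]:
    """Per-frame count of water oxygens within ``radius`` of any site atom.

    Returns ``(counts, mean)``. A stably low count indicates a dehydrated
    pocket.
    """
    site_atoms = np.asarray(site_atoms, dtype=int)
    if site_atoms.size == 0:
        raise InputError("empty site selection")
    waters = traj.topology.selections.get("water-oxygen", np.empty(0, int))
    counts = np.zeros(traj.n_frames, dtype=int)
    if waters.size:
        for f in range(traj.n_frames):
            dmin = cdist(traj.frames[f, waters], traj.frames[f, site_atoms]).min(axis=1)
            counts[f] = int((dmin <= radius).sum())
    return counts, float(counts.mean())


def neutralizing_ions(n_salt_pairs: int, net_solute_charge: int) -> tuple[int, int]:
    """Sodium/chloride counts that neutralize a solvated system.

    ``n_salt_pairs`` Na+/Cl- pairs set the bulk salt concentration; extra
    counter-ions offset the solute's net charge ``q`` so the total system
    charge is exactly zero: ``n_Na = pairs + max(0, -q)``,
    ``n_Cl = pairs + max(0, q)``. (A -1 e solute with 25 pairs gives the
    familiar 26 Na+ / 25 Cl- recipe.)
    """
    if n_salt_pairs < 0:
        raise InputError("n_salt_pairs must be non-negative")
    q = int(net_solute_charge)
    return n_salt_pairs + max(0, -q), n_salt_pairs + max(0, q)
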