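"""Orchestration of the full workflows behind the CLI.

Two entry points mirror the study's two computational arms:

* :func:`run_sitescan` — build/scan a profile library against a query
  sequence, aggregate per-residue positional scores, call enriched
  regions, and optionally paint the scores onto a structure
  (library → scan → score → regions → paint).
* :func:`run_trajmetrics` — read a trajectory, superpose on the protein,
  and emit the full metric bundle (RMSF, H-bond occupancy, contact table,
  penetration depth, hydration series) with one shared header of criteria.

Both are deterministic for a fixed :class:`RunConfig` and write a log
sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from . import align, scoring, traj as traj_mod
from .errors import InputError, LipidsiteError
from .pssm import read_pssm_file
from .traj import HBondCriteria, Topology


@dataclass
class RunConfig:
    """All tunables of one pipeline run; defaults match the module defaults."""

    # site-scan inputs
    query: str | None = None              # FASTA path
    library: str | None = None            # ASCII PSSM path
    structure: str | None = None          # PDB to paint (optional)
    chain: str = "A"
    residue_offset: int = 0
    scan_params: list[tuple[float, float, str]] = field(
        default_factory=lambda: [(10.0, 0.5, "BLOSUM62"), (11.0, 1.0, "BLOSUM45")]
    )
    score_threshold: float = 0.0
    min_region_length: int = 5
    merge_gap: int = 2
    # trajectory inputs
    trajectory: str | None = None
    traj_format: str | None = None
    superpose: bool = True
    hbond_max_distance: float = 3.5
    hbond_max_angle_deviation: float = 30.0
    hbond_donors: str | None = None       # selection expression
    hbond_acceptors: str | None = None
    contact_cutoff: float = 4.0
    tail_atom: str | None = None          # selection expression for last carbon
    hydration_site: str | None = None
    hydration_radius: float = 3.5
    # shared
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_toml(cls, path, overrides: dict | None = None) -> "RunConfig":
        """Load from a TOML file; ``overrides`` (e.g. CLI flags) win."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if overrides:
            data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def parse_selection(topology: Topology, expr: str) -> np.ndarray:
    """Resolve a simple selection expression to atom indices.

    Space-separated ``key:value`` terms (``chain``, ``resid``, ``resname``,
    ``name``) plus the bare flag ``heavy``; all terms must match.
    Example: ``"chain:A resname:LYS name:N heavy"``.
    """
    kwargs: dict = {}
    heavy = False
    for term in expr.split():
        if term == "heavy":
            heavy = True
            continue
        if ":" not in term:
            raise InputError(f"bad selection term {term!r} (expected key:value)")
        key, value = term.split(":", 1)
        if key == "chain":
            kwargs["chain"] = value
        elif key == "resid":
            kwargs["resid"] = int(value)
        elif key == "resname":
            kwargs["resname"] = value
        elif key == "name":
            kwargs["atom_name"] = value
        else:
            raise InputError(f"unknown selection key {key!r}")
    idx = topology.select(heavy_only=heavy, **kwargs)
    if idx.size == 0:
        raise InputError(f"selection {expr!r} matches no atoms")
    return idx


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise package errors with context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, LipidsiteError):
                exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


def run_sitescan(config: RunConfig) -> dict[str, Path]:
    """Library scan → positional score track → regions → optional painting.

    Writes ``track.tsv``, ``regions.bed``, ``alignments.tsv``,
    ``sitescan.log`` and (when a structure is given) ``painted.pdb`` into
    ``config.out_dir``; returns the paths.
    """
    if config.query is None or config.library is None:
        raise InputError("run_sitescan requires 'query' and 'library' paths")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"# sitescan configuration: {config}"]

    with _stage("read-query"):
        records = list(SeqIO.parse(config.query, "fasta"))
        if not records:
            raise InputError(f"no sequences in {config.query}")
        query_name = records[0].id
        query = str(records[0].seq).upper()
    with _stage("read-library"):
        library = read_pssm_file(config.library)
    log_lines.append(f"# query {query_name} length {len(query)}")
    log_lines.append(f"# library {config.library}: {len(library)} profiles")

    params = [
        align.ScanParams(gap_open=go, gap_extend=ge, label=lab)
        for go, ge, lab in config.scan_params
    ]
    with _stage("scan"):
        hits = align.scan_library(query, library, params, config.score_threshold)
    for p in params:
        n = sum(1 for h in hits if h.params_label == p.label)
        log_lines.append(
            f"# params {p.label} (gap_open={p.gap_open}, gap_extend={p.gap_extend}):"
            f" {n} alignments >= threshold {config.score_threshold}"
        )

    with _stage("score"):
        raw = scoring.raw_residue_scores(hits, len(query))
        track = scoring.normalize_track(raw, query_name=query_name)
        regions = scoring.detect_enriched_regions(
            track, min_length=config.min_region_length, merge_gap=config.merge_gap
        )
    log_lines.append(
        f"# track: total={track.total:.0f} positive_count={track.positive_count} "
        f"norm_avg_score={track.norm_avg_score:.4f}"
    )
    log_lines.append(f"# regions called: {len(regions)}")

    paths = {
        "track": out / "track.tsv",
        "regions": out / "regions.bed",
        "alignments": out / "alignments.tsv",
        "log": out / "sitescan.log",
    }
    paths["track"].write_text(scoring.track_to_tsv(track, query))
    paths["regions"].write_text(scoring.regions_to_bed(regions, query_name))
    paths["alignments"].write_text(align.alignments_to_tsv(hits))

    if config.structure is not None:
        with _stage("paint"):
            pdb_lines = Path(config.structure).read_text().splitlines(keepends=True)
            painted = scoring.paint_structure(
                track,
                [ln.rstrip("\n") for ln in pdb_lines],
                chain=config.chain,
                residue_offset=config.residue_offset,
            )
        paths["painted"] = out / "painted.pdb"
        paths["painted"].write_text("\n".join(painted) + "\n")

    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths


def run_trajmetrics(config: RunConfig) -> dict[str, Path]:
    """One invocation computing the full trajectory metric bundle."""
    if config.trajectory is None:
        raise InputError("run_trajmetrics requires a 'trajectory' path")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read-trajectory"):
        trajectory = traj_mod.read_trajectory(config.trajectory, config.traj_format)
    topo = trajectory.topology

    criteria = HBondCriteria(
        max_distance=config.hbond_max_distance,
        max_angle_deviation=config.hbond_max_angle_deviation,
    )
    header = [
        f"# trajectory {config.trajectory} frames={trajectory.n_frames} "
        f"atoms={len(topo)}",
        f"# hbond criteria: distance<={criteria.max_distance} A, "
        f"angle deviation<={criteria.max_angle_deviation} deg",
        f"# contact cutoff: {config.contact_cutoff} A; hydration radius: "
        f"{config.hydration_radius} A",
        f"# superposed: {config.superpose}",
    ]

    if config.superpose:
        with _stage("superpose"):
            trajectory = traj_mod.superpose_frames(trajectory)

    paths: dict[str, Path] = {}

    with _stage("rmsf"):
        series = traj_mod.rmsf(trajectory, per_residue=True)
    paths["rmsf"] = out / "rmsf.tsv"
    with open(paths["rmsf"], "w") as fh:
        fh.write("\n".join(header) + "\nresidue\trmsf_A\n")
        for label, value in series.items():
            fh.write(f"{label}\t{value:.4f}\n")

    ligand = topo.selections.get("ligand", np.empty(0, int))
    lines = list(header)
    if config.hbond_donors and config.hbond_acceptors:
        with _stage("hbond"):
            donors = parse_selection(topo, config.hbond_donors)
            acceptors = parse_selection(topo, config.hbond_acceptors)
            occ, _flags = traj_mod.hbond_occupancy(trajectory, donors, acceptors, criteria)
        lines.append(f"hbond_occupancy_pct\t{occ:.2f}")
    if ligand.size:
        with _stage("contacts"):
            table = traj_mod.contact_occupancy(
                trajectory, ligand, cutoff=config.contact_cutoff
            )
        paths["contacts"] = out / "contacts.tsv"
        with open(paths["contacts"], "w") as fh:
            fh.write("\n".join(header) + "\n")
            table.to_csv(fh, sep="\t", index=False)
    if config.tail_atom:
        with _stage("penetration"):
            tail = parse_selection(topo, config.tail_atom)
            depth = traj_mod.penetration_depth(trajectory, int(tail[0]))
        lines.append(f"penetration_depth_A\t{depth:.4f}")
    if config.hydration_site:
        with _stage("hydration"):
            site = parse_selection(topo, config.hydration_site)
            counts, mean = traj_mod.pocket_hydration(
                trajectory, site, radius=config.hydration_radius
            )
        lines.append(f"mean_pocket_waters\t{mean:.4f}")
        paths["hydration"] = out / "hydration.tsv"
        with open(paths["hydration"], "w") as fh:
            fh.write("\n".join(header) + "\nframe\twaters\n")
            for f, c in enumerate(counts):
                fh.write(f"{f + 1}\t{c}\n")

    paths["summary"] = out / "traj_summary.tsv"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
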