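"""Per-residue positional scores, normalization, and region calling.

Every alignment returned by the library scan contributes 2 to a query
residue aligned as an identity and 1 as a positive substitution; summing
over all alignments gives the raw positional score SC_raw. Three
normalization steps follow:

1. ``NS_residue = SC_raw - SUM_totalscore / LEN_query`` — centre on the
   average residue score, isolating residues scoring above it.
2. ``ASC_query = SUM_PNS / NR_residue`` — the average over the positively
   normalized residues, a per-sequence representative score.
3. ``NORM_avgscore = ASC_query * 100 / LEN_query`` — a length-normalized
   percentage, comparable across proteins of different size.

Contiguous runs of positively normalized residues are called as enriched
regions (the analogue of the 31–50 stretch, peaking at Lys45, seen when
myoglobin is scanned against a fatty-acid-binding-protein profile
library), and the normalized track can be painted onto a PDB structure's
B-factor column for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import IDENTITY, POSITIVE, LocalAlignment
from .errors import InputError, MappingError


@dataclass
class ResidueScoreTrack:
    """Raw and normalized per-residue scores plus the summary statistics."""

    query_name: str
    raw: np.ndarray            # SC_raw, non-negative ints
    normalized: np.ndarray     # NS_residue
    total: float               # SUM_totalscore
    positive_sum: float        # SUM_PNS
    positive_count: int        # NR_residue
    avg_query_score: float     # ASC_query (== AS_query)
    norm_avg_score: float      # NORM_avgscore

    @property
    def length(self) -> int:
        return int(self.raw.shape[0])


@dataclass
class EnrichedRegion:
    """A run of positively normalized residues; 0-based half-open."""

    start: int
    end: int
    peak_residue: int
    mean_score: float


def raw_residue_scores(
    alignments: list[LocalAlignment], query_length: int
) -> np.ndarray:
    """Sum identity (2) / positive (1) contributions per query residue.

    Gap and "other" columns contribute 0. Raises if any alignment column
    indexes a query residue outside ``[0, query_length)``.
    """
    if query_length <= 0:
        raise InputError("query_length must be positive")
    raw = np.zeros(query_length, dtype=int)
    for a in alignments:
        for q, _p, cls in a.columns:
            if q is None:
                continue
            if not (0 <= q < query_length):
                raise InputError(
                    f"alignment {a.profile_name!r} touches query index {q}, "
                    f"outside a length-{query_length} query"
                )
            if cls == IDENTITY:
                raw[q] += 2
            elif cls == POSITIVE:
                raw[q] += 1
    return raw


def normalize_track(raw, query_name: str = "query") -> ResidueScoreTrack:
    """Apply the three normalization steps to a raw score vector.

    When no residue scores above the average (a constant raw track),
    ``ASC_query`` and ``NORM_avgscore`` are defined as 0.
    """
    raw = np.asarray(raw)
    if raw.ndim != 1 or raw.shape[0] == 0:
        raise InputError("raw score vector must be non-empty and 1-D")
    length = raw.shape[0]
    total = float(raw.sum())
    normalized = raw - total / length
    pos_mask = normalized > 0
    positive_count = int(pos_mask.sum())
    positive_sum = float(normalized[pos_mask].sum())
    avg_query_score = positive_sum / positive_count if positive_count else 0.0
    norm_avg_score = avg_query_score * 100.0 / length
    return ResidueScoreTrack(
        query_name=query_name,
        raw=raw.astype(int),
        normalized=normalized.astype(float),
        total=total,
        positive_sum=positive_sum,
        positive_count=positive_count,
        avg_query_score=avg_query_score,
        norm_avg_score=norm_avg_score,
    )


def detect_enriched_regions(
    track: ResidueScoreTrack, min_length: int = 5, merge_gap: int = 2
) -> list[EnrichedRegion]:
    """Call maximal runs of positively normalized residues.

    Runs separated by at most ``merge_gap`` non-positive residues are
    merged; merged runs shorter than ``min_length`` are discarded. Regions
    are returned sorted by descending mean normalized score (ties: by
    start). The peak residue is the arg-max of the normalized score within
    the region, smallest index on ties.
    """
    ns = track.normalized
    pos = ns > 0
    runs: list[list[int]] = []  # [start, end) pairs, mutable for merging
    i = 0
    while i < len(ns):
        if pos[i]:
            j = i
            while j < len(ns) and pos[j]:
                j += 1
            if runs and i - runs[-1][1] <= merge_gap:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j
        else:
            i += 1
    regions = []
    for start, end in runs:
        if end - start < min_length:
            continue
        seg = ns[start:end]
        peak = start + int(np.argmax(seg))
        regions.append(
            EnrichedRegion(start=start, end=end, peak_residue=peak,
                           mean_score=float(seg.mean()))
        )
    regions.sort(key=lambda r: (-r.mean_score, r.start))
    return regions


# --------------------------------------------------------------------------
# Structure painting and exports
# --------------------------------------------------------------------------

def paint_structure(
    track: ResidueScoreTrack,
    pdb_lines: list[str],
    chain: str,
    residue_offset: int = 0,
) -> list[str]:
    """Write normalized scores into the B-factor column of a PDB chain.

    Track index ``i`` maps to PDB residue number ``i + 1 + residue_offset``.
    Every ATOM record of ``chain`` must map into the track, else a
    :class:`MappingError` lists the unmatched residue numbers. HETATM and
    all non-coordinate records pass through unchanged; scores are clamped
    to the format's printable range [-99.99, 999.99].
    """
    out: list[str] = []
    unmatched: set[int] = set()
    for line in pdb_lines:
        if line.startswith("ATOM") and len(line) >= 66 and line[21] == chain:
            resseq = int(line[22:26])
            idx = resseq - 1 - residue_offset
            if not (0 <= idx < track.length):
                unmatched.add(resseq)
                out.append(line)
                continue
            b = float(np.clip(track.normalized[idx], -99.99, 999.99))
            out.append(line[:60] + f"{b:6.2f}" + line[66:])
        else:
            out.append(line)
    if unmatched:
        raise MappingError(
            f"chain {chain!r}: residues {sorted(unmatched)} have no track entry "
            f"(track length {track.length}, offset {residue_offset})"
        )
    return out


def track_to_tsv(track: ResidueScoreTrack, sequence: str) -> str:
    """4-column export: residue number (1-based), letter, raw, normalized."""
    if len(sequence) != track.length:
        raise InputError(
            f"sequence length {len(sequence)} != track length {track.length}"
        )
    lines = ["residue\tletter\traw\tnormalized"]
    for i in range(track.length):
        lines.append(
            f"{i + 1}\t{sequence[i]}\t{int(track.raw[i])}\t{track.normalized[i]:.6f}"
        )
    return "\n".join(lines) + "\n"


def regions_to_bed(regions: list[EnrichedRegion], name: str) -> str:
    """BED-like export (0-based half-open), score = mean normalized score."""
    lines = []
    for k, r in enumerate(regions):
        lines.append(
            f"{name}\t{r.start}\t{r.end}\tregion_{k + 1}\t{r.mean_score:.4f}\t"
            f"peak={r.peak_residue + 1}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
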