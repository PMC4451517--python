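"""Smith–Waterman local alignment of query sequences against PSSMs.

The scan mirrors the profile-library screening step of the binding-site
prediction pipeline: a query (e.g. a myoglobin sequence) is locally aligned
against every profile in a library under two classical parameter sets —
(BLOSUM62, gap open 10, gap extend 0.5) and (BLOSUM45, gap open 11, gap
extend 1). Substitution scores come from the PSSM columns themselves; the
named BLOSUM sets contribute their gap penalties and label the two passes.

Each aligned column is classified as *identity* (query residue equals the
profile consensus), *positive* (non-identity with a strictly positive PSSM
score for the query residue) or *other*; gap columns are *gap*. These
classes feed the downstream 2/1 residue scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .pssm import AA_INDEX, ProfileLibrary, ProfileMatrix

IDENTITY = "identity"
POSITIVE = "positive"
OTHER = "other"
GAPCOL = "gap"

#: Single-letter opcodes for the CIGAR-like column-class string.
CLASS_OPCODE = {IDENTITY: "I", POSITIVE: "P", OTHER: "O", GAPCOL: "G"}
OPCODE_CLASS = {v: k for k, v in CLASS_OPCODE.items()}


@dataclass(frozen=True)
class ScanParams:
    """Gap parameters for one alignment pass.

    A gap of length ``k`` costs ``gap_open + k * gap_extend``.
    """

    gap_open: float
    gap_extend: float
    label: str

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise InputError(
                f"require gap_open >= gap_extend > 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )


#: The two passes used by the published screen.
DEFAULT_SCAN_PARAMS = (
    ScanParams(gap_open=10.0, gap_extend=0.5, label="BLOSUM62"),
    ScanParams(gap_open=11.0, gap_extend=1.0, label="BLOSUM45"),
)


@dataclass
class LocalAlignment:
    """One optimal query-vs-profile local alignment.

    ``columns`` is an ordered list of ``(query_index | None,
    profile_index | None, class)`` triples; spans are 0-based half-open.
    An empty alignment (no positive-scoring cell) has score 0, empty spans
    and no columns.
    """

    profile_name: str
    query_span: tuple[int, int]
    profile_span: tuple[int, int]
    columns: list[tuple[int | None, int | None, str]] = field(default_factory=list)
    score: float = 0.0
    params_label: str = ""

    @property
    def is_empty(self) -> bool:
        return not self.columns

    def cigar(self) -> str:
        """Run-length encoded column-class string, e.g. ``'3I1P2O'``."""
        out: list[str] = []
        run_op, run_len = None, 0
        for _, _, cls in self.columns:
            op = CLASS_OPCODE[cls]
            if op == run_op:
                run_len += 1
            else:
                if run_op is not None:
                    out.append(f"{run_len}{run_op}")
                run_op, run_len = op, 1
        if run_op is not None:
            out.append(f"{run_len}{run_op}")
        return "".join(out)


def _validate_query(query: str) -> None:
    if not query:
        raise InputError("empty query sequence")
    for i, ch in enumerate(query):
        if ch not in AA_INDEX:
            raise InputError(f"query position {i + 1}: residue {ch!r} outside alphabet")


def _classify(profile: ProfileMatrix, p: int, residue: str) -> str:
    if residue == profile.consensus[p]:
        return IDENTITY
    if profile.scores[p, AA_INDEX[residue]] > 0:
        return POSITIVE
    return OTHER


def smith_waterman_profile(
    query: str, profile: ProfileMatrix, params: ScanParams
) -> LocalAlignment:
    """Optimal local alignment of ``query`` against one profile.

    Affine-gap dynamic programming (Gotoh three-state recurrence, with
    transitions between the two gap states allowed, so adjacent
    insertion/deletion runs are part of the search space). Substitution
    score for query residue ``q`` at profile position ``p`` is
    ``profile.scores[p][q]``.

    Tie-breaks are deterministic: among equal-scoring end cells the
    smallest ``(query_end, profile_end)`` wins; during traceback the
    preference is stop > diagonal > gap-in-query > gap-in-profile, and a
    gap run prefers closing (shorter run) over extending.
    """
    _validate_query(query)
    n, m = len(query), profile.length
    go, ge = params.gap_open, params.gap_extend
    open_cost = go + ge  # a gap of length 1 costs gap_open + gap_extend
    q_idx = np.array([AA_INDEX[c] for c in query])
    sub = profile.scores[:, q_idx].T  # sub[i-1][j-1]: query i vs profile j

    NEG = -np.inf
    M = np.full((n + 1, m + 1), 0.0)
    Iq = np.full((n + 1, m + 1), NEG)  # gap in query: profile consumed
    Ip = np.full((n + 1, m + 1), NEG)  # gap in profile: query consumed
    M[0, :] = M[:, 0] = NEG
    M[0, 0] = 0.0

    best, best_end = 0.0, None
    for i in range(1, n + 1):
        Mi, Mi1 = M[i], M[i - 1]
        Iqi = Iq[i]
        Ipi, Ipi1 = Ip[i], Ip[i - 1]
        Iqi1 = Iq[i - 1]
        row_sub = sub[i - 1]
        for j in range(1, m + 1):
            prev = max(0.0, Mi1[j - 1], Iqi1[j - 1], Ipi1[j - 1])
            Mi[j] = prev + row_sub[j - 1]
            Iqi[j] = max(max(Mi[j - 1], Ipi[j - 1]) - open_cost, Iqi[j - 1] - ge)
            Ipi[j] = max(max(Mi1[j], Iqi1[j]) - open_cost, Ipi1[j] - ge)
            if Mi[j] > best:
                best, best_end = Mi[j], (i, j)

    if best_end is None or best <= 0:
        return LocalAlignment(
            profile_name=profile.name,
            query_span=(0, 0),
            profile_span=(0, 0),
            columns=[],
            score=0.0,
            params_label=params.label,
        )

    # Traceback from the best M cell.
    cols: list[tuple[int | None, int | None, str]] = []
    i, j = best_end
    state = "M"
    while True:
        if state == "M":
            cols.append((i - 1, j - 1, _classify(profile, j - 1, query[i - 1])))
            prev = max(0.0, M[i - 1, j - 1], Iq[i - 1, j - 1], Ip[i - 1, j - 1])
            i, j = i - 1, j - 1
            if prev == 0.0:
                break
            if M[i, j] == prev:
                state = "M"
            elif Iq[i, j] == prev:
                state = "Iq"
            else:
                state = "Ip"
        elif state == "Iq":
            cols.append((None, j - 1, GAPCOL))
            val = Iq[i, j]
            j -= 1
            if M[i, j] - open_cost == val:
                state = "M"
            elif Ip[i, j] - open_cost == val:
                state = "Ip"
            else:
                state = "Iq"
        else:  # Ip
            cols.append((i - 1, None, GAPCOL))
            val = Ip[i, j]
            i -= 1
            if M[i, j] - open_cost == val:
                state = "M"
            elif Iq[i, j] - open_cost == val:
                state = "Iq"
            else:
                state = "Ip"

    cols.reverse()
    q_lo = i  # after traceback, (i, j) is the cell before the first column
    p_lo = j
    return LocalAlignment(
        profile_name=profile.name,
        query_span=(q_lo, best_end[0]),
        profile_span=(p_lo, best_end[1]),
        columns=cols,
        score=float(best),
        params_label=params.label,
    )


def scan_library(
    query: str,
    library: ProfileLibrary,
    param_sets: tuple[ScanParams, ...] | list[ScanParams] | None = None,
    score_threshold: float = 0.0,
) -> list[LocalAlignment]:
    """Align ``query`` against every profile under every parameter set.

    Returns the non-empty alignments with score >= ``score_threshold``,
    pooled across parameter sets and sorted by descending score, then
    profile name, then parameter label. One optimal alignment per
    (profile, params) pair; score-0 empty alignments are never returned.
    """
    _validate_query(query)
    if len(library) == 0:
        raise InputError("empty profile library")
    if param_sets is None:
        param_sets = DEFAULT_SCAN_PARAMS
    hits: list[LocalAlignment] = []
    for profile in library:
        for params in param_sets:
            aln = smith_waterman_profile(query, profile, params)
            if not aln.is_empty and aln.score >= score_threshold:
                hits.append(aln)
    hits.sort(key=lambda a: (-a.score, a.profile_name, a.params_label))
    return hits


# --------------------------------------------------------------------------
# TSV export / import. Spans are reported 1-based inclusive.
# --------------------------------------------------------------------------

TSV_HEADER = "profile\tquery_start\tquery_end\tprofile_start\tprofile_end\tscore\tparams\tcigar"


def alignments_to_tsv(alignments: list[LocalAlignment]) -> str:
    lines = [TSV_HEADER]
    for a in alignments:
        qs, qe = a.query_span
        ps, pe = a.profile_span
        lines.append(
            f"{a.profile_name}\t{qs + 1}\t{qe}\t{ps + 1}\t{pe}\t"
            f"{a.score:.6g}\t{a.params_label}\t{a.cigar()}"
        )
    return "\n".join(lines) + "\n"


def alignments_from_tsv(text: str) -> list[LocalAlignment]:
    """Rebuild alignments from the TSV export.

    Column classes and match-column indices are reconstructed from the
    CIGAR-like string. A ``G`` opcode does not record which sequence was
    gapped; the reader infers the per-sequence gap totals from the spans
    and assigns gap-in-query columns first. Residue scoring ignores gap
    columns, so this ambiguity is harmless downstream.
    """
    import re

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != TSV_HEADER:
        raise InputError("alignment TSV missing header")
    out: list[LocalAlignment] = []
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != 8:
            raise InputError(f"alignment TSV row has {len(f)} columns, expected 8")
        name, qs, qe, ps, pe, score, label, cigar = f
        q_lo, q_hi = int(qs) - 1, int(qe)
        p_lo, p_hi = int(ps) - 1, int(pe)
        ops = [
            (int(n), op) for n, op in re.findall(r"(\d+)([IPOG])", cigar)
        ]
        n_match = sum(n for n, op in ops if op != "G")
        gap_in_query = (p_hi - p_lo) - n_match  # G columns consuming profile
        cols: list[tuple[int | None, int | None, str]] = []
        qi, pi = q_lo, p_lo
        for count, op in ops:
            for _ in range(count):
                if op == "G":
                    if gap_in_query > 0:
                        cols.append((None, pi, GAPCOL))
                        pi += 1
                        gap_in_query -= 1
                    else:
                        cols.append((qi, None, GAPCOL))
                        qi += 1
                else:
                    cols.append((qi, pi, OPCODE_CLASS[op]))
                    qi += 1
                    pi += 1
        out.append(
            LocalAlignment(
                profile_name=name,
                query_span=(q_lo, q_hi),
                profile_span=(p_lo, p_hi),
                columns=cols,
                score=float(score),
                params_label=label,
            )
        )
    return out
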