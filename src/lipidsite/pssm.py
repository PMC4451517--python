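"""Position-specific scoring matrices (PSSMs) and libraries of them.

A :class:`ProfileMatrix` holds per-position log-odds scores (half-bit
units) for the 20 canonical amino acids, plus a consensus string. Libraries
of such profiles — in the original application, profiles built from the
fatty-acid-binding regions of FABP-family crystal structures — are the
reference against which query sequences (e.g. myoglobin) are scanned.

Profiles are built from ungapped or gapped multiple sequence alignments by
the standard count → pseudocount → log-odds construction, and serialised to
a simple tab-separated ASCII dialect (one header line per profile, one row
per position).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParseError

#: Canonical residue alphabet, in the fixed (alphabetical) column order used
#: by score matrices and the ASCII file dialect.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Amino-acid background frequencies underlying BLOSUM62 (sum to 1).
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

#: Floor for log-odds cells, half-bit units. Keeps zero-count cells finite
#: when no pseudocount is applied.
MIN_SCORE = -16.0

GAP = "-"


def round_half_bit(x: float) -> float:
    """Round to the nearest 0.5, halves away from zero."""
    return math.copysign(math.floor(abs(x) * 2.0 + 0.5) / 2.0, x)


@dataclass(eq=False)
class ProfileMatrix:
    """A position × residue log-odds score matrix with a consensus string.

    Attributes
    ----------
    name:
        Unique identifier within a library.
    scores:
        Array of shape ``(length, 20)``, columns in :data:`ALPHABET` order,
        half-bit log-odds units, every cell finite.
    consensus:
        For each position, the residue attaining the maximal score (ties
        broken by alphabet order).
    """

    name: str
    scores: np.ndarray
    consensus: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(ALPHABET):
            raise InputError(
                f"profile {self.name!r}: scores must be (length, 20), "
                f"got {self.scores.shape}"
            )
        if self.scores.shape[0] == 0:
            raise InputError(f"profile {self.name!r}: zero-length profile")
        if not np.all(np.isfinite(self.scores)):
            raise InputError(f"profile {self.name!r}: non-finite score cell")
        if len(self.consensus) != self.scores.shape[0]:
            raise InputError(
                f"profile {self.name!r}: consensus length "
                f"{len(self.consensus)} != profile length {self.length}"
            )
        argmax = self.scores.argmax(axis=1)  # first index on ties = alphabet order
        expected = "".join(ALPHABET[i] for i in argmax)
        if self.consensus != expected:
            raise InputError(
                f"profile {self.name!r}: consensus {self.consensus!r} does not "
                f"attain the per-position score maximum (expected {expected!r})"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def score(self, position: int, residue: str) -> float:
        """Score of ``residue`` at 0-based ``position``."""
        try:
            return float(self.scores[position, AA_INDEX[residue]])
        except KeyError:
            raise InputError(f"residue {residue!r} outside alphabet") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileMatrix):
            return NotImplemented
        return (
            self.name == other.name
            and self.consensus == other.consensus
            and self.scores.shape == other.scores.shape
            and bool(np.all(self.scores == other.scores))
        )


@dataclass
class ProfileLibrary:
    """An ordered collection of uniquely named profiles."""

    entries: list[ProfileMatrix] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate profile names in library: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> ProfileMatrix:
        for p in self.entries:
            if p.name == name:
                return p
        raise KeyError(name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileLibrary):
            return NotImplemented
        return self.entries == other.entries


def build_pssm(
    msa: list[str],
    pseudocount_weight: float = 1.0,
    background: dict[str, float] | None = None,
    name: str = "profile",
) -> ProfileMatrix:
    """Build a log-odds PSSM from an aligned sequence family.

    For each alignment column ``p`` and residue ``a``::

        score[p][a] = log2( (count(p,a) + w*bg[a]) / ((N_p + w) * bg[a]) )

    where ``N_p`` is the number of non-gap rows at ``p`` and ``w`` the
    pseudocount weight. Scores are stored at 0.5-bit resolution (halves
    rounded away from zero) and floored at :data:`MIN_SCORE`. Columns that
    are all-gap are dropped and positions compacted.

    Parameters
    ----------
    msa:
        Non-empty list of equal-length rows over the canonical alphabet
        plus ``'-'`` for gaps. Ambiguity codes (B, Z, X) are rejected.
    pseudocount_weight:
        Non-negative pseudocount mass ``w``; the default 1.0 keeps
        zero-count cells finite without dominating observed counts.
    background:
        Strictly positive residue frequencies summing to 1; defaults to the
        BLOSUM62 background.
    """
    if not msa:
        raise InputError("empty MSA")
    if pseudocount_weight < 0:
        raise InputError("pseudocount_weight must be non-negative")
    width = len(msa[0])
    if width == 0:
        raise InputError("MSA rows are empty")
    for r, row in enumerate(msa):
        if len(row) != width:
            raise InputError(f"ragged MSA: row {r} has length {len(row)} != {width}")
        for ch in row:
            if ch != GAP and ch not in AA_INDEX:
                raise InputError(f"row {r}: symbol {ch!r} outside alphabet")
    bg = dict(background) if background is not None else BLOSUM62_BACKGROUND
    missing = [a for a in ALPHABET if a not in bg]
    if missing:
        raise InputError(f"background missing residues: {missing}")
    bg_vec = np.array([bg[a] for a in ALPHABET], dtype=float)
    if np.any(bg_vec <= 0):
        raise InputError("background frequencies must be strictly positive")
    if abs(bg_vec.sum() - 1.0) > 1e-6:
        raise InputError(f"background frequencies sum to {bg_vec.sum()}, not 1")

    counts = np.zeros((width, len(ALPHABET)), dtype=float)
    for row in msa:
        for p, ch in enumerate(row):
            if ch != GAP:
                counts[p, AA_INDEX[ch]] += 1.0
    n_p = counts.sum(axis=1)
    keep = n_p > 0  # drop all-gap columns, compact positions
    counts, n_p = counts[keep], n_p[keep]
    if counts.shape[0] == 0:
        raise InputError("MSA contains only gap columns")

    w = float(pseudocount_weight)
    with np.errstate(divide="ignore"):
        odds = (counts + w * bg_vec) / ((n_p + w)[:, None] * bg_vec)
        raw = np.log2(odds)
    raw = np.maximum(raw, MIN_SCORE)
    scores = np.vectorize(round_half_bit)(raw)
    consensus = "".join(ALPHABET[i] for i in scores.argmax(axis=1))
    return ProfileMatrix(name=name, scores=scores, consensus=consensus)


# --------------------------------------------------------------------------
# ASCII PSSM dialect
#
#   >name length
#   pos consensus s(A) s(C) ... s(Y)        (tab-separated, pos is 1-based)
#
# Scores carry one decimal (0.5-bit storage resolution).
# --------------------------------------------------------------------------

def write_pssm_file(library: ProfileLibrary, path) -> None:
    """Serialise ``library`` to the ASCII PSSM dialect at ``path``."""
    lines: list[str] = []
    for prof in library:
        lines.append(f">{prof.name}\t{prof.length}")
        for p in range(prof.length):
            cells = "\t".join(f"{v:.1f}" for v in prof.scores[p])
            lines.append(f"{p + 1}\t{prof.consensus[p]}\t{cells}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pssm_file(path) -> ProfileLibrary:
    """Parse a library from the ASCII PSSM dialect.

    Raises :class:`ParseError` (naming the line) for malformed headers,
    wrong column counts, or non-numeric cells; :class:`InputError` for an
    empty library or duplicate names.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    entries: list[ProfileMatrix] = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if not line.startswith(">"):
            raise ParseError(f"line {i + 1}: expected '>name length' header, got {line!r}")
        parts = line[1:].split("\t")
        if len(parts) != 2:
            parts = line[1:].split()
        if len(parts) != 2:
            raise ParseError(f"line {i + 1}: malformed header {line!r}")
        name = parts[0]
        try:
            length = int(parts[1])
        except ValueError:
            raise ParseError(f"line {i + 1}: non-integer length {parts[1]!r}") from None
        if length <= 0:
            raise ParseError(f"line {i + 1}: non-positive profile length {length}")
        rows = np.empty((length, len(ALPHABET)))
        consensus = []
        for p in range(length):
            j = i + 1 + p
            if j >= len(lines):
                raise ParseError(f"line {j + 1}: unexpected end of file in profile {name!r}")
            fields = lines[j].split("\t")
            if len(fields) != 2 + len(ALPHABET):
                raise ParseError(
                    f"line {j + 1}: expected {2 + len(ALPHABET)} columns, got {len(fields)}"
                )
            try:
                pos = int(fields[0])
            except ValueError:
                raise ParseError(f"line {j + 1}: non-integer position {fields[0]!r}") from None
            if pos != p + 1:
                raise ParseError(f"line {j + 1}: position {pos}, expected {p + 1}")
            consensus.append(fields[1])
            try:
                rows[p] = [float(x) for x in fields[2:]]
            except ValueError:
                raise ParseError(f"line {j + 1}: non-numeric score cell") from None
        try:
            entries.append(ProfileMatrix(name=name, scores=rows, consensus="".join(consensus)))
        except InputError as exc:
            raise ParseError(f"profile {name!r} ending at line {i + length + 1}: {exc}") from exc
        i += 1 + length

    if not entries:
        raise InputError(f"{path}: empty PSSM file, no profiles")
    return ProfileLibrary(entries=entries)
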