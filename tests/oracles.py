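"""Independent oracles used by the test suite and the acceptance script.

The local-alignment oracle enumerates every monotone matching of query and
profile positions (with a cap on the number of gap runs) and scores it
directly from the substitution matrix and affine gap costs. It shares no
code with the dynamic-programming implementation it checks.
"""

from __future__ import annotations

import numpy as np

from lipidsite.pssm import ALPHABET, ProfileMatrix, round_half_bit
from lipidsite.align import ScanParams


def brute_force_local_score(
    sub: np.ndarray, gap_open: float, gap_extend: float, max_gap_runs: int = 2
) -> float:
    """Best local alignment score by exhaustive enumeration.

    ``sub[i][j]`` is the substitution score of query residue ``i`` against
    profile position ``j``. An alignment is a non-empty monotone set of
    matched (i, j) pairs; skipped positions between consecutive pairs form
    gap runs, each costing ``gap_open + run_length * gap_extend``. At most
    ``max_gap_runs`` runs are allowed. Returns max(0, best).
    """
    n, m = sub.shape
    best = 0.0

    def extend(last_i: int, last_j: int, score: float, runs: int) -> None:
        nonlocal best
        for i in range(last_i + 1, n):
            for j in range(last_j + 1, m):
                di, dj = i - last_i, j - last_j
                r = (di > 1) + (dj > 1)
                if runs + r > max_gap_runs:
                    continue
                cost = 0.0
                if di > 1:
                    cost += gap_open + (di - 1) * gap_extend
                if dj > 1:
                    cost += gap_open + (dj - 1) * gap_extend
                s2 = score + sub[i, j] - cost
                if s2 > best:
                    best = s2
                extend(i, j, s2, runs + r)

    for i in range(n):
        for j in range(m):
            if sub[i, j] > best:
                best = sub[i, j]
            extend(i, j, sub[i, j], 0)
    return best


def random_alignment_instance(rng: np.random.Generator):
    """A random small (query, profile, params) instance for oracle checks."""
    n = int(rng.integers(1, 9))
    m = int(rng.integers(1, 9))
    query = "".join(ALPHABET[i] for i in rng.integers(len(ALPHABET), size=n))
    # half-bit scores in [-6, 6]; positives are common enough for non-trivial
    # alignments to exist
    scores = np.vectorize(round_half_bit)(rng.uniform(-6.0, 6.0, size=(m, 20)))
    consensus = "".join(ALPHABET[i] for i in scores.argmax(axis=1))
    profile = ProfileMatrix(name="rnd", scores=scores, consensus=consensus)
    go = float(rng.choice([8.0, 9.0, 10.0, 11.0, 12.0]))
    ge = float(rng.choice([0.5, 1.0, 2.0]))
    params = ScanParams(gap_open=go, gap_extend=ge, label="rnd")
    sub = scores[:, [ALPHABET.index(c) for c in query]].T
    return query, profile, params, sub
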