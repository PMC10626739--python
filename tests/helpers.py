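"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the slowest, most transparent
route (naive loops, quadratic DP) so they share no code path with the
implementation they check.
"""

from __future__ import annotations

import numpy as np
import biotite.sequence.align as balign

_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()
_ALPH = _MATRIX.get_alphabet1()
_SCORES = _MATRIX.score_matrix()


def blosum62(a: str, b: str) -> int:
    return int(_SCORES[_ALPH.encode(a), _ALPH.encode(b)])


def local_align_score(query: str, subject: str, gap_open: int = 11, gap_ext: int = 1) -> int:
    """Quadratic Gotoh local alignment score, affine gaps.

    A gap of length g costs ``gap_open + (g - 1) * gap_ext``. Plain
    nested-loop dynamic programming over H/E/F matrices.
    """
    m, n = len(query), len(subject)
    NEG = -10**9
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (move along subject)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_ext)
            diag = H[i - 1][j - 1] + blosum62(query[i - 1], subject[j - 1])
            H[i][j] = max(0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
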