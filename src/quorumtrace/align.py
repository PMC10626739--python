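"""Pairwise protein alignment and e-value statistics for homolog retrieval.

Local (Smith-Waterman) alignment with affine gaps scores each catalog gene
against the reference set. The three retrieval statistics are:

* identity — exact matches divided by aligned columns, gap columns included
  (the BLAST reporting convention);
* subject coverage — fraction of the reference protein spanned by the local
  alignment, which guards that the functional domain is actually covered;
* e-value — Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)
  for score S, query length m and database size n residues.

The heavy DP is delegated to biotite's C implementation; this module owns
the statistics, conventions, and the result contract. Gap convention: a gap
of length g costs ``gap_open + (g - 1) * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import biotite.sequence as _bseq
import biotite.sequence.align as _balign

from .reference import VALID_RESIDUES


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for local alignment and e-value computation.

    ``karlin_lambda`` and ``karlin_K`` default to the classic gapped
    BLOSUM62 constants (0.267, 0.041).
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one local alignment, carrying the three filter statistics.

    Spans are 0-based half-open on query and subject. ``evalue`` is NaN
    until :func:`compute_evalue` fills it in (it needs the database size).
    """

    query_id: str
    subject_id: str
    score: int
    identity: float
    subject_coverage: float
    query_coverage: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    evalue: float = math.nan


@lru_cache(maxsize=4)
def _matrix(name: str) -> "_balign.SubstitutionMatrix":
    if name == "BLOSUM62":
        return _balign.SubstitutionMatrix.std_protein_matrix()
    alph = _bseq.ProteinSequence.alphabet
    return _balign.SubstitutionMatrix(alph, alph, name)


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    seq = seq.upper()
    if not set(seq) <= VALID_RESIDUES:
        for pos, ch in enumerate(seq):
            if ch not in VALID_RESIDUES:
                raise ValueError(f"{label}: invalid residue {ch!r} at position {pos}")
    return seq


def align_pair(
    query: str,
    subject: str,
    params: AlignmentParams = AlignmentParams(),
    query_id: str = "query",
    subject_id: str = "subject",
    local: bool = True,
) -> AlignmentResult:
    """Optimal pairwise alignment of two protein sequences.

    Local (default) alignment is used for homolog retrieval; ``local=False``
    gives a global alignment, used e.g. to verify realized identity of
    simulated homologs. Identity is matches / aligned columns (gaps count
    as columns); subject coverage is subject residues inside the aligned
    span / subject length.
    """
    query = _check_sequence(query, f"query {query_id!r}")
    subject = _check_sequence(subject, f"subject {subject_id!r}")
    matrix = _matrix(params.substitution_matrix)
    alns = _balign.align_optimal(
        _bseq.ProteinSequence(query),
        _bseq.ProteinSequence(subject),
        matrix,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        local=local,
        terminal_penalty=False,
        max_number=1,
    )
    aln = alns[0]
    trace = aln.trace
    if len(trace) == 0:  # no positive-scoring cell: empty local alignment
        return AlignmentResult(
            query_id, subject_id, score=0, identity=0.0,
            subject_coverage=0.0, query_coverage=0.0,
            query_span=(0, 0), subject_span=(0, 0),
        )
    q_idx, s_idx = trace[:, 0], trace[:, 1]
    both = (q_idx >= 0) & (s_idx >= 0)
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    sa = np.frombuffer(subject.encode(), dtype=np.uint8)
    matches = int(np.sum(qa[q_idx[both]] == sa[s_idx[both]]))
    columns = len(trace)
    q_cov_res = q_idx[q_idx >= 0]
    s_cov_res = s_idx[s_idx >= 0]
    q_span = (int(q_cov_res.min()), int(q_cov_res.max()) + 1)
    s_span = (int(s_cov_res.min()), int(s_cov_res.max()) + 1)
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=int(aln.score),
        identity=matches / columns,
        subject_coverage=(s_span[1] - s_span[0]) / len(subject),
        query_coverage=(q_span[1] - q_span[0]) / len(query),
        query_span=q_span,
        subject_span=s_span,
    )


def compute_evalue(
    score: int, query_len: int, db_residues: int, params: AlignmentParams = AlignmentParams()
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S).

    ``m`` is the query length, ``n`` the total residues in the searched
    database. Strictly decreasing in score and linear in database size.
    """
    if score < 0:
        raise ValueError("score must be nonnegative")
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("query_len and db_residues must be positive")
    return params.karlin_K * query_len * db_residues * math.exp(-params.karlin_lambda * score)
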