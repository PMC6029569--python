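"""Protein local alignment and E-value statistics shared by the terminase
assignment and the reciprocal-best-hit clustering.

Scoring is BLOSUM62 with affine gaps (open 11, extend 1), the standard
gapped protein search parametrization; E-values use the Karlin-Altschul
formula with the standard gapped BLOSUM62 parameters (lambda = 0.267,
K = 0.041) and an explicit database size (sum of reference lengths) so
results are reproducible bit-exactly.
"""
from __future__ import annotations

import math
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: gapped BLOSUM62 Karlin-Altschul parameters
LAMBDA = 0.267
K = 0.041


@lru_cache(maxsize=1)
def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_score(a: str, b: str) -> float:
    """Smith-Waterman score (no traceback; fast path)."""
    return float(protein_aligner().score(a, b))


def local_alignment_span(a: str, b: str) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Score plus the aligned span (start, end) in each sequence."""
    aln = protein_aligner().align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    span_a = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    span_b = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return float(aln.score), span_a, span_b


def bit_score(raw_score: float) -> float:
    return (LAMBDA * raw_score - math.log(K)) / math.log(2)


def evalue(raw_score: float, query_len: int, database_len: int) -> float:
    """Karlin-Altschul expectation for a raw local-alignment score."""
    return query_len * database_len * 2.0 ** (-bit_score(raw_score))
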