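"""Technical-validation analytics: replicate-assembly comparison, prophage
screening of viruses against their sequenced hosts, and synteny checking.

Replicate ANI is computed from per-sequence mismatch counts as

    ANI = 1 - ((query_mismatch + subject_mismatch)/2) / ((query_len + subject_len)/2)

rounded half-up to 7 decimals, i.e. one minus the mean mismatch count over
the mean length of the pair.
"""
from __future__ import annotations

import decimal
from functools import lru_cache

import numpy as np
from Bio import Align

from ._util import (
    longest_increasing_subsequence_length,
    revcomp,
    unique_kmer_positions,
)
from .errors import TermistdError
from .types import GenomeRecord, ProphageHit, ReplicateComparison, StandardizedGenome


def ani_from_counts(qm: int, sm: int, ql: int, sl: int) -> float:
    """Replicate ANI from mismatch counts and lengths (7 decimals, half-up)."""
    value = 1.0 - ((qm + sm) / 2.0) / ((ql + sl) / 2.0)
    return float(
        decimal.Decimal(repr(value)).quantize(
            decimal.Decimal("0.0000001"), rounding=decimal.ROUND_HALF_UP
        )
    )


@lru_cache(maxsize=1)
def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _shared_kmer_fraction(a: str, b: str, k: int = 31) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / min(len(ka), len(kb))


def compare_replicates(a: GenomeRecord, b: GenomeRecord) -> ReplicateComparison:
    """Globally align two replicate assemblies and report Table-style
    comparison counts.

    SNPs are substituted columns; indel bases are gapped columns, charged to
    the sequence bearing the insertion; per-sequence mismatch counts are
    substitutions plus charged indel bases; ANI follows
    :func:`ani_from_counts`.  Pairs sharing < 90% of 31-mers are rejected as
    unalignable rather than reported as zero-ANI.
    """
    if _shared_kmer_fraction(a.sequence, b.sequence) < 0.9:
        raise TermistdError(f"{a.id} and {b.id} are not globally alignable replicates")
    aln = _global_aligner().align(a.sequence, b.sequence)[0]
    qa, qb = aln[0], aln[1]
    snp = indel = qm_extra = sm_extra = 0
    first_aligned = None
    for i, (ca, cb) in enumerate(zip(qa, qb)):
        if ca == "-" and cb == "-":
            continue
        if ca == "-":
            indel += 1
            sm_extra += 1  # b bears the insertion
        elif cb == "-":
            indel += 1
            qm_extra += 1
        else:
            if first_aligned is None:
                first_aligned = i
            if ca != cb:
                snp += 1
    qm = snp + qm_extra
    sm = snp + sm_extra
    return ReplicateComparison(
        query_id=a.id,
        subject_id=b.id,
        query_len=len(a),
        subject_len=len(b),
        query_mismatch=qm,
        subject_mismatch=sm,
        ani=ani_from_counts(qm, sm, len(a), len(b)),
        snp=snp,
        indel_bases=indel,
        start_variation=first_aligned or 0,
        length_variation=abs(len(a) - len(b)),
    )


def prophage_screen(
    virus: GenomeRecord,
    hosts: list[GenomeRecord],
    min_identity: float = 0.95,
    min_len: int = 5_000,
    k: int = 31,
    max_gap: int = 100,
    flag_cover: float = 0.9,
) -> list[ProphageHit]:
    """Screen a virus genome against host assemblies for near-identical
    embedded copies (induced prophages).

    Seeds are shared 31-mers chained along near-constant diagonals (gaps up
    to ``max_gap``); chains >= ``min_len`` at >= ``min_identity`` estimated
    identity are reported, and a virus covered over >= ``flag_cover`` of its
    length is flagged as a putative prophage."""
    hits: list[ProphageHit] = []
    vseq = virus.sequence
    vkmers: dict[str, list[int]] = {}
    for i in range(len(vseq) - k + 1):
        vkmers.setdefault(vseq[i : i + k], []).append(i)
    for host in hosts:
        hseq = host.sequence
        diagonals: dict[int, list[int]] = {}
        for j in range(len(hseq) - k + 1):
            for i in vkmers.get(hseq[j : j + k], ()):
                diagonals.setdefault(j - i, []).append(i)
        # chain matches on nearby diagonals
        chains: list[tuple[int, int, int]] = []  # (v_start, v_end, matched)
        for diag in sorted(diagonals):
            positions = sorted(diagonals[diag])
            start = prev = positions[0]
            matched = k
            for p in positions[1:]:
                if p - prev <= max_gap + k:
                    matched += min(k, p - prev)
                    prev = p
                else:
                    chains.append((start, prev + k, matched))
                    start = prev = p
                    matched = k
            chains.append((start, prev + k, matched))
        # merge chains from adjacent diagonals covering overlapping spans
        chains.sort()
        merged: list[list[int]] = []
        for s, e, m in chains:
            if merged and s <= merged[-1][1] + max_gap:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] += m
            else:
                merged.append([s, e, m])
        covered = 0
        best = None
        for s, e, m in merged:
            span = e - s
            ident = min(1.0, m / span)
            if span >= min_len and ident >= min_identity:
                covered += span
                if best is None or span > (best[1] - best[0]):
                    best = (s, e, ident)
        if best is not None:
            s, e, ident = best
            cover = covered / len(vseq)
            hits.append(
                ProphageHit(
                    virus_id=virus.id,
                    host_contig_id=host.id,
                    match_len=e - s,
                    identity=round(ident, 4),
                    virus_cover=round(cover, 4),
                    host_contig_len=len(hseq),
                    flagged=cover >= flag_cover,
                )
            )
    return hits


def synteny_check(
    a: StandardizedGenome | GenomeRecord,
    b: StandardizedGenome | GenomeRecord,
    k: int = 31,
    normalize_orientation: bool = False,
) -> float:
    """Collinearity of two genomes as the fraction of shared unique k-mers
    whose order is preserved (longest increasing subsequence / total shared).

    With ``normalize_orientation`` the better of b and its reverse
    complement is scored."""
    sa = a.contig.sequence if isinstance(a, StandardizedGenome) else a.sequence
    sb = b.contig.sequence if isinstance(b, StandardizedGenome) else b.sequence
    ua = unique_kmer_positions(sa, k)

    def _score(other: str) -> float:
        ub = unique_kmer_positions(other, k)
        shared = [(p, ub[km]) for km, p in ua.items() if km in ub]
        if not shared:
            return 0.0
        shared.sort()
        return longest_increasing_subsequence_length([q for _, q in shared]) / len(shared)

    score = _score(sb)
    if normalize_orientation:
        score = max(score, _score(revcomp(sb)))
    return score


def load_replicate_table(path=None):
    """The bundled replicate-comparison table as a pandas DataFrame."""
    import pandas as pd
    from importlib import resources

    path = path or resources.files("termistd") / "data" / "replicate_comparisons.tsv"
    return pd.read_csv(path, sep="\t", dtype={"phage": str, "ani": str})
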