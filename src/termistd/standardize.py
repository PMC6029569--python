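"""Contig standardization: choose and apply one re-linearization strategy per
genome, honoring group-level consensus.

Six strategies mirror how curated phage assemblies are presented:

* ``relinearize_at_terl_upstream_orf`` — headful/pac genomes: circularize and
  re-open at the start of the ORF immediately upstream of the large
  terminase (TerL oriented forward), which places the pac-proximal region
  (commonly the small terminase subunit) at the genome start;
* ``cut_at_coverage_feature`` — cos/DTR genomes: re-open in the middle of the
  short aberrant-coverage run marking the physical terminus;
* ``scaffold_to_reference`` — rotate/flip onto a resolved close relative
  (100% shared protein content);
* ``maintain_original`` — singletons with no distinct signal;
* ``trim_mu_ends`` — Mu-like genomes: remove the low-coverage host-DNA
  flanks;
* ``select_itr_contig`` — fixed-end linear genomes with inverted terminal
  repeats: pick the best candidate contig, no rotation.

All strategies except Mu trimming conserve the base multiset: the output is
an exact rotation and/or reverse complement of the input (asserted on every
call).
"""
from __future__ import annotations

import logging
from collections import Counter

import numpy as np
from scipy import ndimage

from ._util import circular_rotate, revcomp, unique_kmer_positions
from .errors import ParameterError, TermistdError
from .types import (
    CoverageProfile,
    GenomeRecord,
    OrfRecord,
    PackagingStrategy,
    PatternCall,
    PatternLabel,
    RearrangementPlan,
    StandardizedGenome,
    TerminaseAssignment,
)

logger = logging.getLogger(__name__)

PEAK_VALLEY_LABELS = (
    PatternLabel.SHORT_INTERNAL_PEAK,
    PatternLabel.COS_PEAK,
    PatternLabel.COS_VALLEY,
)

HEADFUL_CLASSES = (PackagingStrategy.HEADFUL_PAC,)
COS_DTR_CLASSES = (
    PackagingStrategy.COS_5,
    PackagingStrategy.COS_3,
    PackagingStrategy.DTR,
)


def _assert_conserved(original: str, result: str) -> None:
    assert Counter(original) == Counter(result), "base multiset not conserved"


def select_primary_contig(contigs: list[GenomeRecord], coverages: dict[str, float]) -> GenomeRecord:
    """The highest-mean-coverage contig is the target viral genome; lower
    coverage contigs are treated as contamination (logged). Ties break to the
    longer contig."""
    if not contigs:
        raise ParameterError("no contigs")
    ranked = sorted(contigs, key=lambda c: (-coverages.get(c.id, 0.0), -len(c), c.id))
    for c in ranked[1:]:
        logger.info("discarding low-coverage contig %s (%.1fx, %d bp)",
                    c.id, coverages.get(c.id, 0.0), len(c))
    return ranked[0]


def relinearize_at_terl_upstream_orf(
    contig: GenomeRecord,
    orfs: list[OrfRecord],
    terl: TerminaseAssignment,
) -> StandardizedGenome:
    """Circularize and re-open at the start of the ORF immediately preceding
    TerL in genome order, after orienting TerL to the forward strand."""
    L = len(contig)
    seq = contig.sequence
    terl_orf = terl.orf
    flipped = terl_orf.strand == "-"
    if flipped:
        seq = revcomp(seq)
        orfs = [_flip_orf(o, L) for o in orfs]
        terl_orf = _flip_orf(terl_orf, L)

    # ignore ORFs wholly contained inside another ORF: a gene-dense
    # annotation (as a real gene caller would produce) has no nested models,
    # and nested mini-ORFs would otherwise usurp "immediately preceding"
    def _contained(a: OrfRecord) -> bool:
        return any(
            b is not a and b.start <= a.start and a.end <= b.end
            for b in orfs
        )

    candidates = [
        o for o in orfs
        if (o.start, o.end) != (terl_orf.start, terl_orf.end) and not _contained(o)
    ]
    # "immediately preceding" = the ORF whose end is closest to (and not
    # beyond) the TerL start; ORFs running into TerL do not precede it
    preceding = [o for o in candidates if o.end <= terl_orf.start]
    if preceding:
        upstream = max(preceding, key=lambda o: (o.end, o.start))
    elif candidates:
        # wrap: the last ORF on the circle precedes TerL
        upstream = max(candidates, key=lambda o: (o.end, o.start))
    else:
        logger.info("TerL is the only ORF; re-opening at TerL itself")
        upstream = terl_orf
    origin = upstream.start % L
    result = circular_rotate(seq, origin)
    _assert_conserved(seq, result)
    plan = RearrangementPlan(
        strategy="relinearize_at_terl_upstream_orf",
        cut_pos=origin,
        orientation="flip" if flipped else "keep",
        rationale={"terminase": terl.reference_name,
                   "packaging_class": terl.packaging_class.value},
    )
    return StandardizedGenome(
        GenomeRecord(contig.id, result, circular_hint=True),
        plan,
        provenance={"original_id": contig.id,
                    "log": [f"flip={flipped}", f"origin={origin}"]},
    )


def _flip_orf(orf: OrfRecord, L: int) -> OrfRecord:
    start = orf.start % L
    end = orf.end
    length = end - start
    new_start = (L - (start + length)) % L
    return OrfRecord(orf.contig_id, new_start, new_start + length,
                     "+" if orf.strand == "-" else "-", orf.protein)


def cut_at_coverage_feature(contig: GenomeRecord, pattern: PatternCall) -> StandardizedGenome:
    """Circularize and re-open at the midpoint of a short aberrant-coverage
    run (cos peak/valley or collapsed DTR)."""
    if pattern.label not in PEAK_VALLEY_LABELS:
        raise ParameterError(f"pattern {pattern.label} is not a cut-able coverage feature")
    if pattern.anchor is None:
        raise ParameterError("pattern has no locatable anchor")
    origin = pattern.anchor % len(contig)
    result = circular_rotate(contig.sequence, origin)
    _assert_conserved(contig.sequence, result)
    plan = RearrangementPlan(
        strategy="cut_at_coverage_feature",
        cut_pos=origin,
        rationale={"pattern": pattern.label.value},
    )
    return StandardizedGenome(
        GenomeRecord(contig.id, result, circular_hint=True),
        plan,
        provenance={"original_id": contig.id, "log": [f"cut={origin}"]},
    )


def trim_mu_ends(
    contig: GenomeRecord,
    profile: CoverageProfile | None = None,
    group_alignment: list[GenomeRecord] | None = None,
    drop_fold: float = 0.25,
    identity: float = 0.95,
    k: int = 31,
) -> StandardizedGenome:
    """Remove terminal host-DNA flanks from a Mu-like assembly.

    With ``group_alignment`` (>=2 other members), termini are the bounds of
    the region conserved in all members (shared-k-mer approximation of the
    >=95%-identity conserved region).  Otherwise each terminal segment whose
    lightly-smoothed depth is <= ``drop_fold`` x the interior median is
    trimmed.
    """
    seq = contig.sequence
    L = len(seq)
    if group_alignment:
        present = np.zeros(L, dtype=bool)
        first = True
        for member in group_alignment:
            member_kmers = set()
            ms = member.sequence
            member_kmers.update(ms[i : i + k] for i in range(len(ms) - k + 1))
            rc = revcomp(ms)
            member_kmers.update(rc[i : i + k] for i in range(len(rc) - k + 1))
            here = np.zeros(L, dtype=bool)
            for i in range(L - k + 1):
                if seq[i : i + k] in member_kmers:
                    here[i : i + k] = True
            present = here if first else (present & here)
            first = False
        idx = np.flatnonzero(present)
        if idx.size == 0:
            raise TermistdError("no conserved interval shared by all group members")
        trim_left, trim_right = int(idx[0]), int(L - (idx[-1] + 1))
    elif profile is not None:
        depth = profile.depth.astype(float)
        light = ndimage.median_filter(depth, size=15, mode="nearest")
        interior = float(np.median(light[L // 4 : 3 * L // 4]))
        above = light >= drop_fold * interior
        if not above.any():
            raise TermistdError("entire profile below the interior-depth threshold")
        trim_left = int(np.argmax(above))
        trim_right = int(np.argmax(above[::-1]))
    else:
        raise ParameterError("trim_mu_ends needs a coverage profile or group members")

    result = seq[trim_left : L - trim_right] if (trim_left or trim_right) else seq
    if not result:
        raise TermistdError("trimming removed the whole contig")
    plan = RearrangementPlan(
        strategy="trim_mu_ends",
        trim_left=trim_left,
        trim_right=trim_right,
        rationale={"mode": "conserved_region" if group_alignment else "coverage"},
    )
    return StandardizedGenome(
        GenomeRecord(contig.id, result),
        plan,
        provenance={"original_id": contig.id,
                    "log": [f"trim_left={trim_left}", f"trim_right={trim_right}"]},
    )


def detect_itr(contig: GenomeRecord, min_len: int = 30, max_mismatch: int = 0) -> int | None:
    """Length of the longest inverted terminal repeat, or None if < min_len.

    The ITR length is the largest r for which the first r bases equal the
    reverse complement of the last r (up to ``max_mismatch`` mismatches,
    ending on a match).  A fully palindromic sequence caps at L//2 with a
    warning."""
    seq = contig.sequence
    L = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    budget = max_mismatch
    best = 0
    i = 0
    while i < L // 2:
        if seq[i] == comp[seq[L - 1 - i]]:
            best = i + 1
        else:
            budget -= 1
            if budget < 0:
                break
        i += 1
    if best >= L // 2:
        logger.warning("contig %s is palindromic; ITR capped at L//2", contig.id)
    return best if best >= min_len else None


def select_itr_contig(candidates: list[GenomeRecord], min_len: int = 30) -> GenomeRecord:
    """Longest candidate exhibiting an ITR; else the longest overall.
    Ties break lexicographically on id."""
    if not candidates:
        raise ParameterError("no candidate contigs")
    with_itr = [c for c in candidates if detect_itr(c, min_len=min_len) is not None]
    pool = with_itr or candidates
    return sorted(pool, key=lambda c: (-len(c), c.id))[0]


def scaffold_to_reference(
    contig: GenomeRecord,
    reference: StandardizedGenome,
    k: int = 31,
    min_shared: int = 10,
) -> StandardizedGenome:
    """Rotate/flip a contig onto a resolved close relative.

    Orientation maximizes the shared-unique-k-mer count; rotation zeroes the
    modal (contig offset - reference offset) of shared unique k-mers."""
    ref_pos = unique_kmer_positions(reference.contig.sequence, k)
    best = None
    for orientation, seq in (("keep", contig.sequence), ("flip", revcomp(contig.sequence))):
        cpos = unique_kmer_positions(seq, k)
        shared = [(p, ref_pos[km]) for km, p in cpos.items() if km in ref_pos]
        if best is None or len(shared) > len(best[2]):
            best = (orientation, seq, shared)
    orientation, seq, shared = best
    if len(shared) < min_shared:
        raise TermistdError(
            f"only {len(shared)} shared unique {k}-mers with {reference.contig.id}; "
            "not closely related enough to scaffold"
        )
    L = len(seq)
    offsets = Counter((p - rp) % L for p, rp in shared)
    delta = offsets.most_common(1)[0][0]
    result = circular_rotate(seq, delta)
    _assert_conserved(seq, result)
    plan = RearrangementPlan(
        strategy="scaffold_to_reference",
        cut_pos=delta,
        orientation=orientation,
        reference_id=reference.contig.id,
        rationale={"shared_kmers": len(shared)},
    )
    return StandardizedGenome(
        GenomeRecord(contig.id, result, circular_hint=True),
        plan,
        provenance={"original_id": contig.id,
                    "log": [f"orientation={orientation}", f"rotation={delta}"]},
    )


def maintain_original(contig: GenomeRecord, reason: str = "no distinct pattern") -> StandardizedGenome:
    plan = RearrangementPlan(strategy="maintain_original", rationale={"reason": reason})
    return StandardizedGenome(
        GenomeRecord(contig.id, contig.sequence, contig.circular_hint),
        plan,
        provenance={"original_id": contig.id, "log": ["maintained"]},
    )


def select_strategy(
    group_members: list[str],
    assignments: dict[str, TerminaseAssignment | None],
    patterns: dict[str, PatternCall],
    itr_lengths: dict[str, int | None] | None = None,
    identical_protein_partners: dict[str, set[str]] | None = None,
) -> dict[str, RearrangementPlan]:
    """Assign one standardization strategy to every member of a genome group.

    All members receive a common inferred packaging-strategy category by
    majority over (terminase class, pattern) evidence, with precedence
    mu > itr > headful > cos/DTR > maintain.  Genomes voted headful but
    lacking a terminase are scaffolded onto a resolved member when they share
    100% of proteins with one; groups mixing Mu-like and non-Mu terminases
    are flagged for manual review (error).  Decision traces are recorded in
    each plan's rationale.
    """
    itr_lengths = itr_lengths or {}
    identical_protein_partners = identical_protein_partners or {}
    for g in group_members:
        if g not in patterns:
            raise ParameterError(f"genome {g} has no pattern call")

    classes = {g: assignments[g].packaging_class
               for g in group_members if assignments.get(g) is not None}
    trace: dict = {"group": list(group_members), "classes": {g: c.value for g, c in classes.items()}}

    plans: dict[str, RearrangementPlan] = {}

    mu_members = {g for g, c in classes.items() if c is PackagingStrategy.MU_LIKE}
    if mu_members:
        if len(mu_members) < len(classes):
            raise TermistdError(
                f"group mixes Mu-like and non-Mu terminases ({trace['classes']}); "
                "flagged for manual review"
            )
        for g in group_members:
            plans[g] = RearrangementPlan(strategy="trim_mu_ends",
                                         rationale={**trace, "vote": "mu_like"})
        return plans

    if not classes and any(itr_lengths.get(g) for g in group_members):
        for g in group_members:
            plans[g] = RearrangementPlan(strategy="select_itr_contig",
                                         rationale={**trace, "vote": "itr"})
        return plans

    headful_votes, cosdtr_votes = 0, 0
    for g in group_members:
        cls = classes.get(g)
        label = patterns[g].label
        if cls in HEADFUL_CLASSES or (
            cls is None and label in (PatternLabel.GRADUAL_SHIFT, PatternLabel.EVEN)
        ):
            headful_votes += 1
        elif cls in COS_DTR_CLASSES or (
            cls is None
            and label in PEAK_VALLEY_LABELS + (PatternLabel.MULTIPLE_PEAKS,)
        ):
            cosdtr_votes += 1
    trace["votes"] = {"headful": headful_votes, "cos_dtr": cosdtr_votes}

    if headful_votes and headful_votes >= cosdtr_votes:
        for g in group_members:
            if assignments.get(g) is not None:
                plans[g] = RearrangementPlan(
                    strategy="relinearize_at_terl_upstream_orf",
                    rationale={**trace, "vote": "headful"},
                )
            else:
                partners = identical_protein_partners.get(g, set()) & {
                    m for m in group_members if assignments.get(m) is not None
                }
                if partners:
                    ref = sorted(partners)[0]
                    plans[g] = RearrangementPlan(
                        strategy="scaffold_to_reference",
                        reference_id=ref,
                        rationale={**trace, "vote": "headful", "scaffold_on": ref},
                    )
                else:
                    plans[g] = RearrangementPlan(
                        strategy="maintain_original",
                        rationale={**trace, "vote": "headful",
                                   "reason": "no terminase and no identical-proteome partner"},
                    )
    elif cosdtr_votes:
        for g in group_members:
            if patterns[g].anchor is not None and patterns[g].label in PEAK_VALLEY_LABELS:
                plans[g] = RearrangementPlan(
                    strategy="cut_at_coverage_feature",
                    cut_pos=patterns[g].anchor,
                    rationale={**trace, "vote": "cos_dtr"},
                )
            else:
                partners = identical_protein_partners.get(g, set()) & set(group_members)
                resolved = {m for m in partners if patterns[m].anchor is not None}
                if resolved:
                    ref = sorted(resolved)[0]
                    plans[g] = RearrangementPlan(
                        strategy="scaffold_to_reference", reference_id=ref,
                        rationale={**trace, "vote": "cos_dtr", "scaffold_on": ref},
                    )
                else:
                    plans[g] = RearrangementPlan(
                        strategy="maintain_original",
                        rationale={**trace, "vote": "cos_dtr", "reason": "no locatable feature"},
                    )
    else:
        for g in group_members:
            plans[g] = RearrangementPlan(
                strategy="maintain_original",
                rationale={**trace, "vote": "none",
                           "reason": "no terminase and no distinct pattern"},
            )

    strategies = {p.strategy for p in plans.values()} - {"scaffold_to_reference", "maintain_original"}
    assert len(strategies) <= 1, "group members assigned inconsistent strategies"
    return plans
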