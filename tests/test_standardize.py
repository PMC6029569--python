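from collections import Counter

import numpy as np
import pytest

from termistd import genes as gn
from termistd import standardize as st
from termistd._util import circular_rotate, revcomp
from termistd.errors import ParameterError, TermistdError
from termistd.types import (
    CoverageProfile,
    GenomeRecord,
    PackagingStrategy as PS,
    PatternCall,
    PatternLabel as PL,
    StandardizedGenome,
    TerminaseAssignment,
)
from tests.conftest import random_sequence


class TestSelectPrimaryContig:
    def test_single_contig(self):
        c = GenomeRecord("only", "ACGT" * 100)
        assert st.select_primary_contig([c], {"only": 10.0}) is c

    def test_highest_coverage_wins(self):
        a = GenomeRecord("a", "A" * 400)
        b = GenomeRecord("b", "C" * 400)
        assert st.select_primary_contig([a, b], {"a": 200.0, "b": 15.0}).id == "a"

    def test_coverage_tie_goes_to_longer(self):
        a = GenomeRecord("a", "A" * 40_000)
        b = GenomeRecord("b", "C" * 30_000)
        assert st.select_primary_contig([b, a], {"a": 50.0, "b": 50.0}).id == "a"


def _simulated_headful(seed=3):
    from termistd import simulate as sim

    spec = sim.SimGenomeSpec(length=20_000, gc=0.45,
                             terminase_class=PS.HEADFUL_PAC, seed=seed)
    return sim.make_genome(spec)


def _terl_for(contig, orfs, genome):
    terl_orf = next(o for o in orfs if o.start == genome.terl_start)
    return TerminaseAssignment(terl_orf, "Sf6", PS.HEADFUL_PAC, 500.0, 1e-100)


class TestRelinearize:
    def test_idempotent_on_standardized_contig(self):
        genome = _simulated_headful()
        orfs = gn.find_orfs(genome, circular=True)
        once = st.relinearize_at_terl_upstream_orf(
            genome, orfs, _terl_for(genome, orfs, genome)
        )
        contig = once.contig
        orfs2 = gn.find_orfs(contig, circular=True)
        terl_start2 = next(
            o.start for o in orfs2
            if o.protein == _terl_for(genome, orfs, genome).orf.protein
        )
        terl_orf2 = next(o for o in orfs2 if o.start == terl_start2)
        terl2 = TerminaseAssignment(terl_orf2, "Sf6", PS.HEADFUL_PAC, 500.0, 1e-100)
        twice = st.relinearize_at_terl_upstream_orf(contig, orfs2, terl2)
        assert twice.contig.sequence == contig.sequence

    @pytest.mark.parametrize("rotation", [1, 1_717, 9_999, 15_000])
    def test_rotation_invariant_output(self, rotation):
        genome = _simulated_headful()
        base = None
        for rot in (0, rotation):
            contig = GenomeRecord("g", circular_rotate(genome.sequence, rot), True)
            orfs = gn.find_orfs(contig, circular=True)
            terl_orf = next(
                o for o in orfs
                if o.start == (genome.terl_start - rot) % len(genome) and o.strand == "+"
            )
            terl = TerminaseAssignment(terl_orf, "Sf6", PS.HEADFUL_PAC, 500.0, 1e-100)
            out = st.relinearize_at_terl_upstream_orf(contig, orfs, terl)
            if base is None:
                base = out.contig.sequence
            else:
                assert out.contig.sequence == base

    def test_flipped_contig_is_reoriented(self):
        genome = _simulated_headful()
        flipped = GenomeRecord("g", revcomp(genome.sequence), True)
        orfs = gn.find_orfs(flipped, circular=True)
        L = len(genome)
        terl_start_flipped = (L - genome.terl_end) % L
        terl_orf = next(o for o in orfs if o.start == terl_start_flipped)
        assert terl_orf.strand == "-"
        terl = TerminaseAssignment(terl_orf, "Sf6", PS.HEADFUL_PAC, 500.0, 1e-100)
        out = st.relinearize_at_terl_upstream_orf(flipped, orfs, terl)
        assert out.plan.orientation == "flip"
        # same output as standardizing the forward contig
        fwd_orfs = gn.find_orfs(genome, circular=True)
        fwd = st.relinearize_at_terl_upstream_orf(
            genome, fwd_orfs, _terl_for(genome, fwd_orfs, genome)
        )
        assert out.contig.sequence == fwd.contig.sequence

    def test_base_multiset_conserved(self):
        genome = _simulated_headful()
        orfs = gn.find_orfs(genome, circular=True)
        out = st.relinearize_at_terl_upstream_orf(
            genome, orfs, _terl_for(genome, orfs, genome)
        )
        assert Counter(out.contig.sequence) == Counter(genome.sequence)


class TestCutAtCoverageFeature:
    def test_cut_at_feature_midpoint(self, random_genome):
        pattern = PatternCall(PL.COS_PEAK, anchor=1_050)
        out = st.cut_at_coverage_feature(random_genome, pattern)
        assert out.contig.sequence == circular_rotate(random_genome.sequence, 1_050)
        assert out.plan.cut_pos == 1_050

    def test_label_without_anchor_raises(self, random_genome):
        with pytest.raises(ParameterError):
            st.cut_at_coverage_feature(random_genome, PatternCall(PL.COS_VALLEY, None))

    def test_uncuttable_label_raises(self, random_genome):
        with pytest.raises(ParameterError):
            st.cut_at_coverage_feature(random_genome, PatternCall(PL.EVEN, 100))


class TestTrimMuEnds:
    def test_coverage_based_trim(self, rng):
        L = 20_000
        seq = random_sequence(rng, L)
        depth = np.full(L, 50)
        depth[:130] = 1
        depth[-900:] = 1
        profile = CoverageProfile("c", depth)
        out = st.trim_mu_ends(GenomeRecord("c", seq), profile=profile)
        assert abs(out.plan.trim_left - 130) <= 20
        assert abs(out.plan.trim_right - 900) <= 20
        assert out.contig.sequence == seq[out.plan.trim_left : L - out.plan.trim_right]

    def test_no_drop_returns_input_untouched(self, rng):
        seq = random_sequence(rng, 5_000)
        profile = CoverageProfile("c", np.full(5_000, 40))
        out = st.trim_mu_ends(GenomeRecord("c", seq), profile=profile)
        assert (out.plan.trim_left, out.plan.trim_right) == (0, 0)
        assert out.contig.sequence == seq

    def test_conserved_region_trim_recovers_shared_core(self, rng):
        core = random_sequence(rng, 8_000)
        contig = GenomeRecord("c", random_sequence(rng, 120) + core + random_sequence(rng, 700))
        members = [
            GenomeRecord("m1", random_sequence(rng, 90) + core + random_sequence(rng, 1_500)),
            GenomeRecord("m2", random_sequence(rng, 60) + core + random_sequence(rng, 2_500)),
        ]
        out = st.trim_mu_ends(contig, group_alignment=members)
        assert out.contig.sequence == core

    def test_empty_conserved_interval_raises(self, rng):
        contig = GenomeRecord("c", random_sequence(rng, 2_000))
        members = [GenomeRecord("m", random_sequence(rng, 2_000))]
        with pytest.raises(TermistdError):
            st.trim_mu_ends(contig, group_alignment=members)


class TestDetectItr:
    def test_planted_itr_found_exactly(self, rng):
        seq = list(random_sequence(rng, 9_800))
        planted = "".join(seq[:100])
        body = seq[100:9_700]
        # force a pairing mismatch right after the planted repeat
        body[0] = "A"
        body[-1] = "A"  # comp would need T at the mirrored position
        contig = GenomeRecord("c", planted + "".join(body) + revcomp(planted))
        assert st.detect_itr(contig) == 100

    def test_random_sequence_has_none(self, rng):
        assert st.detect_itr(GenomeRecord("c", random_sequence(rng, 10_000))) is None

    def test_palindrome_caps_at_half_length(self, rng, caplog):
        half = random_sequence(rng, 500)
        contig = GenomeRecord("c", half + revcomp(half))
        with caplog.at_level("WARNING"):
            assert st.detect_itr(contig) == 500

    def test_mismatch_budget(self, rng):
        seq = random_sequence(rng, 2_000)
        itr = seq[:60]
        tail = list(revcomp(itr))
        tail[30] = "A" if tail[30] != "A" else "C"  # one mismatch inside
        contig = GenomeRecord("c", itr + seq[60:1_940] + "".join(tail))
        # the mismatch truncates the repeat below min_len without a budget
        assert st.detect_itr(contig, max_mismatch=0) is None
        assert st.detect_itr(contig, max_mismatch=0, min_len=10) == 29
        with_budget = st.detect_itr(contig, max_mismatch=1)
        assert with_budget is not None and 60 <= with_budget <= 70


class TestSelectItrContig:
    def test_itr_contig_beats_longer_non_itr(self, rng):
        seq = random_sequence(rng, 9_800)
        itr_contig = GenomeRecord("itr10kb", seq[:100] + seq[100:9_700] + revcomp(seq[:100]))
        long_contig = GenomeRecord("plain12kb", random_sequence(rng, 12_000))
        assert st.select_itr_contig([long_contig, itr_contig]).id == "itr10kb"

    def test_no_itr_takes_longest(self, rng):
        a = GenomeRecord("a", random_sequence(rng, 8_000))
        b = GenomeRecord("b", random_sequence(rng, 9_000))
        assert st.select_itr_contig([a, b]).id == "b"

    def test_single_candidate(self, rng):
        only = GenomeRecord("x", random_sequence(rng, 5_000))
        assert st.select_itr_contig([only]) is only


class TestScaffoldToReference:
    def _reference(self, rng):
        seq = random_sequence(rng, 10_000)
        return StandardizedGenome(
            GenomeRecord("ref", seq, True),
            st.RearrangementPlan(strategy="maintain_original"),
        )

    def test_rotated_copy_recovers_reference(self, rng):
        ref = self._reference(rng)
        contig = GenomeRecord("q", circular_rotate(ref.contig.sequence, 3_456), True)
        out = st.scaffold_to_reference(contig, ref)
        assert out.contig.sequence == ref.contig.sequence

    def test_flipped_rotation_recovers_reference(self, rng):
        ref = self._reference(rng)
        contig = GenomeRecord("q", revcomp(circular_rotate(ref.contig.sequence, 777)), True)
        out = st.scaffold_to_reference(contig, ref)
        assert out.plan.orientation == "flip"
        assert out.contig.sequence == ref.contig.sequence

    def test_mutated_copy_alignment_start_exact(self, rng):
        ref = self._reference(rng)
        seq = list(circular_rotate(ref.contig.sequence, 2_000))
        for pos in rng.integers(0, len(seq), size=100):  # ~1% mutations
            seq[pos] = "ACGT"["ACGT".index(seq[pos]) - 1]
        out = st.scaffold_to_reference(GenomeRecord("q", "".join(seq), True), ref)
        # modal-offset rotation aligns position 0 exactly
        assert out.contig.sequence[:31] == ref.contig.sequence[:31]

    def test_unrelated_contig_raises(self, rng):
        ref = self._reference(rng)
        with pytest.raises(TermistdError):
            st.scaffold_to_reference(GenomeRecord("q", random_sequence(rng, 10_000)), ref)


def _pattern(label, anchor=None):
    return PatternCall(label, anchor)


def _assignment(cls):
    return TerminaseAssignment(
        gn.OrfRecord("c", 0, 300, "+", "M" * 99), "x", cls, 100.0, 1e-30
    )


class TestSelectStrategy:
    def test_headful_group_including_even_member(self):
        plans = st.select_strategy(
            ["g1", "g2", "g3"],
            {g: _assignment(PS.HEADFUL_PAC) for g in ("g1", "g2", "g3")},
            {"g1": _pattern(PL.GRADUAL_SHIFT, 5), "g2": _pattern(PL.GRADUAL_SHIFT, 9),
             "g3": _pattern(PL.EVEN)},
        )
        assert all(p.strategy == "relinearize_at_terl_upstream_orf" for p in plans.values())

    def test_singleton_without_evidence_is_maintained(self):
        plans = st.select_strategy(["g"], {"g": None}, {"g": _pattern(PL.NONE)})
        assert plans["g"].strategy == "maintain_original"

    def test_member_without_terminase_scaffolds_on_identical_partner(self):
        members = ["g1", "g2", "g3", "g4"]
        assignments = {g: _assignment(PS.HEADFUL_PAC) for g in members[:3]}
        assignments["g4"] = None
        plans = st.select_strategy(
            members,
            assignments,
            {g: _pattern(PL.GRADUAL_SHIFT, 5) for g in members},
            identical_protein_partners={"g4": {"g2"}},
        )
        assert plans["g4"].strategy == "scaffold_to_reference"
        assert plans["g4"].reference_id == "g2"
        assert plans["g1"].strategy == "relinearize_at_terl_upstream_orf"

    def test_cos_group_cut_at_feature(self):
        plans = st.select_strategy(
            ["a", "b"],
            {"a": _assignment(PS.COS_5), "b": None},
            {"a": _pattern(PL.COS_PEAK, 1_000), "b": _pattern(PL.COS_PEAK, 2_000)},
        )
        assert all(p.strategy == "cut_at_coverage_feature" for p in plans.values())

    def test_mu_group(self):
        plans = st.select_strategy(
            ["a", "b"],
            {"a": _assignment(PS.MU_LIKE), "b": _assignment(PS.MU_LIKE)},
            {"a": _pattern(PL.TERMINAL_DROP_MU, 100), "b": _pattern(PL.TERMINAL_DROP_MU, 80)},
        )
        assert all(p.strategy == "trim_mu_ends" for p in plans.values())

    def test_contradictory_mu_and_non_mu_raises(self):
        with pytest.raises(TermistdError):
            st.select_strategy(
                ["a", "b"],
                {"a": _assignment(PS.MU_LIKE), "b": _assignment(PS.HEADFUL_PAC)},
                {"a": _pattern(PL.TERMINAL_DROP_MU, 1), "b": _pattern(PL.EVEN)},
            )

    def test_itr_group_without_terminases(self):
        plans = st.select_strategy(
            ["a", "b"],
            {"a": None, "b": None},
            {"a": _pattern(PL.EVEN), "b": _pattern(PL.EVEN)},
            itr_lengths={"a": 100, "b": 100},
        )
        assert all(p.strategy == "select_itr_contig" for p in plans.values())

    def test_missing_pattern_raises(self):
        with pytest.raises(ParameterError):
            st.select_strategy(["a"], {"a": None}, {})
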