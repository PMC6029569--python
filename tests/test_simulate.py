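import numpy as np
import pytest

from termistd import simulate as sim
from termistd._util import revcomp
from termistd.errors import ParameterError
from termistd.types import GenomeRecord, PackagingStrategy as PS


def _plain_genome(L=10_000, seed=0):
    spec = sim.SimGenomeSpec(length=L, gc=0.5, seed=seed)
    return sim.make_genome(spec)


class TestMakeGenome:
    def test_deterministic_under_fixed_seed(self):
        spec = sim.SimGenomeSpec(length=40_000, gc=0.43, seed=7)
        a = sim.make_genome(spec)
        b = sim.make_genome(sim.SimGenomeSpec(length=40_000, gc=0.43, seed=7))
        assert a.sequence == b.sequence

    def test_gc_within_sampling_bound(self):
        g = sim.make_genome(sim.SimGenomeSpec(length=40_000, gc=0.43, seed=3))
        gc = (g.sequence.count("G") + g.sequence.count("C")) / len(g)
        assert 0.41 <= gc <= 0.45

    def test_exact_requested_length(self):
        g = sim.make_genome(sim.SimGenomeSpec(length=23_456, gc=0.5, seed=1))
        assert len(g) == 23_456

    def test_planted_terminase_round_trip(self):
        from termistd.genes import assign_terminase, find_orfs

        g = sim.make_genome(
            sim.SimGenomeSpec(length=30_000, gc=0.45,
                              terminase_class=PS.HEADFUL_PAC, seed=11)
        )
        orfs = find_orfs(g, circular=True)
        hit = assign_terminase(orfs)
        assert hit is not None
        assert hit.packaging_class is PS.HEADFUL_PAC
        assert hit.orf.start == g.terl_start

    def test_pac_defaults_to_upstream_orf_start(self):
        g = sim.make_genome(
            sim.SimGenomeSpec(length=30_000, terminase_class=PS.HEADFUL_PAC, seed=2)
        )
        assert g.pac_site == g.upstream_orf_start

    @pytest.mark.parametrize("bad", [
        sim.SimGenomeSpec(length=500),
        sim.SimGenomeSpec(gc=0.0),
        sim.SimGenomeSpec(gc=1.5),
        sim.SimGenomeSpec(pac_site=100_000),
    ])
    def test_invalid_spec_raises(self, bad):
        with pytest.raises(ParameterError):
            sim.make_genome(bad)


class TestHeadfulPackaging:
    def test_series_starts_and_lengths(self):
        g = _plain_genome(10_000)
        g.pac_site = 0
        params = sim.PackagingParams(headful_fraction=1.05, series_len=4)
        virions = sim.package_virions(g, PS.HEADFUL_PAC, n=4, params=params)
        assert [v.truth_start for v in virions] == [0, 500, 1000, 1500]
        assert all(len(v) == 10_500 for v in virions)

    def test_concatemer_window_oracle(self):
        # every virion equals the corresponding window of the rolled-out
        # concatemer, enumerated by brute force
        g = _plain_genome(10_000)
        g.pac_site = 137
        params = sim.PackagingParams(headful_fraction=1.05, series_len=4)
        virions = sim.package_virions(g, PS.HEADFUL_PAC, n=8, params=params)
        monomer = int(1.05 * 10_000)
        concat = g.sequence * 10
        for j, v in enumerate(virions):
            offset = 137 + (j % 4) * monomer
            assert v.sequence == concat[offset : offset + monomer]

    def test_terminal_redundancy(self):
        g = _plain_genome(10_000)
        g.pac_site = 0
        v = sim.package_virions(g, PS.HEADFUL_PAC, n=1,
                                params=sim.PackagingParams(headful_fraction=1.08))[0]
        assert v.sequence[:800] == v.sequence[10_000 : 10_800]

    def test_invalid_fraction_raises(self):
        g = _plain_genome()
        with pytest.raises(ParameterError):
            sim.package_virions(g, PS.HEADFUL_PAC,
                                params=sim.PackagingParams(headful_fraction=1.0))


class TestOtherStrategies:
    def test_cos_monomers_are_unit_length_rotations(self):
        g = _plain_genome()
        params = sim.PackagingParams(terminus=1234)
        virions = sim.package_virions(g, PS.COS_5, n=5, params=params)
        expected = g.sequence[1234:] + g.sequence[:1234]
        assert all(v.sequence == expected for v in virions)

    def test_dtr_duplicates_prefix(self):
        g = _plain_genome()
        v = sim.package_virions(g, PS.DTR, n=1,
                                params=sim.PackagingParams(dtr_len=250))[0]
        assert len(v) == 10_250
        assert v.sequence[:250] == v.sequence[10_000:]

    def test_itr_termini_are_reverse_complements(self):
        g = _plain_genome()
        for v in sim.package_virions(g, PS.ITR, n=3,
                                     params=sim.PackagingParams(itr_len=100)):
            assert v.sequence[:100] == revcomp(v.sequence[-100:])

    def test_mu_flank_ranges_and_variability(self, rng):
        g = _plain_genome()
        host = GenomeRecord("h", "".join(rng.choice(list("ACGT"), size=20_000)))
        virions = sim.package_virions(g, PS.MU_LIKE, n=100, seed=5, host=host)
        lefts = {v.host_flank_left for v in virions}
        rights = {v.host_flank_right for v in virions}
        assert all(50 <= v.host_flank_left <= 150 for v in virions)
        assert all(500 <= v.host_flank_right <= 3_000 for v in virions)
        assert len(lefts) > 10 and len(rights) > 50

    def test_mu_without_host_raises(self):
        with pytest.raises(ParameterError):
            sim.package_virions(_plain_genome(), PS.MU_LIKE)


class TestEndChemistry:
    def test_cos3_full_chew_shortens_by_overhang(self):
        g = _plain_genome()
        virions = sim.package_virions(g, PS.COS_3, n=10)
        out = sim.end_chemistry(virions, PS.COS_3, c=12, p_chem=1.0, p_lig=0.0)
        assert all(len(v) == 10_000 - 12 for v in out)
        assert all(v.sequence == g.sequence[12:] for v in out)

    def test_cos5_endfill_duplicates_overhang(self):
        g = _plain_genome()
        virions = sim.package_virions(g, PS.COS_5, n=10)
        out = sim.end_chemistry(virions, PS.COS_5, c=12, p_chem=1.0, p_lig=0.0)
        assert all(len(v) == 10_012 for v in out)
        assert all(v.sequence[-12:] == v.sequence[:12] for v in out)

    def test_identity_when_disabled(self):
        g = _plain_genome()
        virions = sim.package_virions(g, PS.COS_5, n=5)
        out = sim.end_chemistry(virions, PS.COS_5, p_chem=0.0, p_lig=0.0)
        assert [v.sequence for v in out] == [v.sequence for v in virions]

    def test_non_cos_strategy_raises(self):
        g = _plain_genome()
        virions = sim.package_virions(g, PS.DTR, n=1)
        with pytest.raises(ParameterError):
            sim.end_chemistry(virions, PS.DTR)

    def test_cos5_coverage_exceeds_flanks_after_mapping(self):
        # overhang interval mean exceeds flanking median on the mapped profile
        from termistd.coverage import map_reads, per_base_coverage

        g = _plain_genome(seed=9)
        virions = sim.package_virions(g, PS.COS_5, n=20)
        virions = sim.end_chemistry(virions, PS.COS_5, c=12, p_chem=0.8, p_lig=0.0, seed=1)
        reads = sim.shear_reads(virions, 2_000, seed=2)
        placements, _ = map_reads(reads, g, circular=True)
        depth = per_base_coverage(placements, len(g), circular=True).depth
        overhang_mean = depth[:12].mean()
        flank_median = np.median(depth[1_000:5_000])
        assert overhang_mean > flank_median


class TestShearReads:
    def test_zero_error_mates_are_substrings(self):
        g = _plain_genome()
        virions = sim.package_virions(g, PS.COS_5, n=3)
        for p in sim.shear_reads(virions, 200, seed=1):
            source = virions[0].sequence
            assert p.mate1 in source
            assert revcomp(p.mate2) in source

    def test_mean_depth_matches_lander_waterman(self):
        g = sim.make_genome(sim.SimGenomeSpec(length=40_000, gc=0.5, seed=4))
        virions = sim.package_virions(g, PS.COS_5, n=10)
        n_pairs = sim.n_pairs_for_depth(virions, depth=50)
        reads = sim.shear_reads(virions, n_pairs, seed=3)
        total = sum(len(p.mate1) + len(p.mate2) for p in reads)
        depth = total / 40_000
        assert 45 <= depth <= 55

    def test_byte_identical_fastq_under_fixed_seed(self, tmp_path):
        from termistd import seqio

        g = _plain_genome()
        virions = sim.package_virions(g, PS.COS_5, n=3)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        seqio.write_fastq(sim.shear_reads(virions, 100, seed=5), p1)
        seqio.write_fastq(sim.shear_reads(virions, 100, seed=5), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_virion_list(self):
        assert sim.shear_reads([], 100) == []

    def test_negative_error_rate_raises(self):
        with pytest.raises(ParameterError):
            sim.shear_reads([], 10, error_rate=-0.1)

    def test_error_rate_introduces_substitutions(self):
        g = _plain_genome()
        virions = sim.package_virions(g, PS.COS_5, n=1)
        reads = sim.shear_reads(virions, 500, error_rate=0.02, seed=6)
        mismatched = sum(p.mate1 not in virions[0].sequence for p in reads)
        assert mismatched > 100  # P(150-base read error-free) ~ 0.05
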