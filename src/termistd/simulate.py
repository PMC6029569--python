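"""Synthetic packaged-genome and read simulator.

Each packaging strategy leaves a characteristic fingerprint in the population
of packaged physical genomes (virions), and hence in the per-base coverage of
reads mapped back onto a draft assembly:

* **headful (pac)** — ~100-110% genome-length monomers are cut sequentially
  from a concatemer starting at a conserved *pac* site; terminal redundancy
  plus series structure yields elevated coverage downstream of *pac*.
* **cos (5'/3')** — unit-length monomers with fixed complementary
  single-strand overhangs; library end-chemistry (end-fill of 5' overhangs,
  exonucleolytic loss of 3' overhangs) duplicates or deletes the overhang
  bases, producing a narrow coverage peak or valley at the cos site.
* **DTR** — a short direct terminal repeat duplicated at both genome ends;
  collapsed by assembly into a single copy carrying ~2x coverage.
* **ITR** — fixed-end linear genomes whose termini are reverse complements.
* **Mu-like** — replicative transposition packages variable stretches of host
  chromosome at both genome ends; only the one junction the assembler chose
  is represented in the contig, so flanks show near-zero coverage.

Fragment positions in :func:`shear_reads` are drawn uniformly per molecule
with clipping at the termini, which emulates end-repair capture of terminal
fragments: coverage stays flat up to molecule ends (with a mild terminal
over-representation of about insert/read-length), the behaviour real
terminus-detection protocols rely on.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp, rng_from_seed
from .errors import ParameterError
from .genes import load_archetypes, reverse_translate
from .types import GenomeRecord, PackagingStrategy, ReadPair, SimulatedVirion

_BASES = np.array(list("ACGT"))


@dataclass
class SimGenomeSpec:
    """Parameters of one simulated reference genome.

    Realistic ranges follow the sequenced collection: lengths from ~10 kb to
    ~350 kb, GC 37-58%.
    """

    length: int = 40_000
    gc: float = 0.43
    terminase_class: PackagingStrategy | None = None
    pac_site: int | None = None
    seed: int = 0
    terl_mutation_rate: float = 0.0
    upstream_orf_aa: int = 120

    def validate(self) -> None:
        if self.length < 1_000:
            raise ParameterError(f"genome length {self.length} < 1,000")
        if not 0.0 < self.gc < 1.0:
            raise ParameterError(f"gc {self.gc} outside (0, 1)")
        if self.pac_site is not None and self.pac_site >= self.length:
            raise ParameterError("pac_site beyond genome length")
        if not 0.0 <= self.terl_mutation_rate <= 0.5:
            raise ParameterError("terl_mutation_rate outside [0, 0.5]")


@dataclass
class SimGenome(GenomeRecord):
    """A simulated reference circle with the planted-gene ground truth."""

    terl_start: int | None = None
    terl_end: int | None = None
    terl_strand: str = "+"
    upstream_orf_start: int | None = None
    upstream_orf_end: int | None = None
    pac_site: int | None = None
    terminase_class: PackagingStrategy | None = None


@dataclass
class PackagingParams:
    """Strategy-specific packaging knobs.

    Defaults: headful fraction 1.08 with series length 3 — a short packaging
    series (2-5 headfuls per concatemer, P22-like) near the ~110% redundancy
    bound, which produces the visibly elevated coverage downstream of *pac*
    that headful phages show in practice (longer series at lower redundancy
    flatten the modulation below the sampling-noise floor of a ~50x
    library); 12-base cos overhangs (lambda-like scale); 300-base DTR
    (T7/N4 scale); 100-base ITR; Mu host flanks of 50-150 bp (left) and
    500-3,000 bp (right).
    """

    headful_fraction: float = 1.08
    series_len: int = 3
    cos_overhang: int = 12
    dtr_len: int = 300
    itr_len: int = 100
    mu_flank_left: tuple[int, int] = (50, 150)
    mu_flank_right: tuple[int, int] = (500, 3_000)
    terminus: int = 0  # genome terminus coordinate on the reference circle


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return protein
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = list(protein)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = aa.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_genome(spec: SimGenomeSpec) -> SimGenome:
    """Generate a random circular genome, optionally planting a marker
    terminase gene (plus a small ORF immediately upstream of it).

    The marker is a reverse-translated copy of the bundled archetype protein
    for ``spec.terminase_class``, optionally mutated at the protein level, so
    the gene-calling/terminase-assignment round trip is testable.  For
    headful genomes the *pac* site defaults to the start of the upstream ORF
    (headful phages commonly initiate packaging in or near the small
    terminase subunit, which lies upstream of TerL).
    """
    spec.validate()
    rng = rng_from_seed(spec.seed)
    seq = list(_random_bases(rng, spec.length, spec.gc))
    genome = SimGenome("sim", "".join(seq), circular_hint=True)
    genome.terminase_class = spec.terminase_class
    genome.pac_site = spec.pac_site

    if spec.terminase_class is not None:
        archetypes = load_archetypes()
        candidates = [a for a in archetypes if a.packaging_class == spec.terminase_class]
        if not candidates:
            raise ParameterError(
                f"no bundled archetype for class {spec.terminase_class}"
            )
        arch = candidates[0]
        protein = _mutate_protein(arch.protein, spec.terl_mutation_rate, rng)
        upstream_protein = "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=spec.upstream_orf_aa)
        )

        def _gene(p: str) -> str:
            return "ATG" + reverse_translate(p, rng) + "TAA"

        # in-frame guard stop, then upstream ORF and TerL, contiguous
        construct = "TAA" + _gene(upstream_protein) + _gene(protein)
        if len(construct) > spec.length // 2:
            raise ParameterError("genome too short for the planted marker construct")
        locus = int(rng.integers(0, spec.length - len(construct)))
        up_start = locus + 3
        up_end = up_start + 3 * (len(upstream_protein) + 2)
        terl_start = up_end
        terl_end = terl_start + 3 * (len(protein) + 2)
        seq[locus : locus + len(construct)] = construct
        genome.sequence = "".join(seq)
        genome.upstream_orf_start = up_start
        genome.upstream_orf_end = up_end
        genome.terl_start = terl_start
        genome.terl_end = terl_end
        if spec.pac_site is None and spec.terminase_class is PackagingStrategy.HEADFUL_PAC:
            genome.pac_site = up_start
    return genome


def package_virions(
    genome: GenomeRecord,
    strategy: PackagingStrategy,
    n: int = 50,
    seed: int = 0,
    params: PackagingParams | None = None,
    host: GenomeRecord | None = None,
) -> list[SimulatedVirion]:
    """Package ``n`` virion monomers from a circularly interpretable genome."""
    params = params or PackagingParams()
    rng = rng_from_seed(seed)
    S = genome.sequence
    L = len(S)
    t = params.terminus % L
    rot = S[t:] + S[:t]
    virions: list[SimulatedVirion] = []

    if strategy is PackagingStrategy.HEADFUL_PAC:
        f = params.headful_fraction
        if not 1.0 < f <= 1.10:
            raise ParameterError(f"headful fraction {f} outside (1.00, 1.10]")
        pac = getattr(genome, "pac_site", None) or 0
        monomer = int(math.floor(f * L))
        concat = S * (monomer * params.series_len // L + 3)
        for j in range(n):
            i = j % params.series_len
            start = (pac + i * monomer) % L
            # slice the rolled-out concatemer beginning at the series offset
            offset = pac + i * monomer
            virions.append(
                SimulatedVirion(
                    id=f"virion{j}",
                    sequence=concat[offset : offset + monomer],
                    truth_start=start,
                    truth_end_type=strategy,
                )
            )
    elif strategy in (PackagingStrategy.COS_5, PackagingStrategy.COS_3):
        for j in range(n):
            virions.append(
                SimulatedVirion(f"virion{j}", rot, truth_start=t, truth_end_type=strategy)
            )
    elif strategy is PackagingStrategy.DTR:
        d = params.dtr_len
        seq = rot + rot[:d]
        for j in range(n):
            virions.append(
                SimulatedVirion(f"virion{j}", seq, truth_start=t, truth_end_type=strategy)
            )
    elif strategy is PackagingStrategy.ITR:
        r = params.itr_len
        body = list(rot[: L - r])
        # terminate the repeat exactly at r: break any chance pairing of the
        # first base beyond the ITR with its mirror position
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        if body[r] == comp[body[L - r - 1]]:
            body[r] = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}[body[r]]
        seq = "".join(body) + revcomp("".join(body[:r]))
        for j in range(n):
            virions.append(
                SimulatedVirion(f"virion{j}", seq, truth_start=t, truth_end_type=strategy)
            )
    elif strategy is PackagingStrategy.MU_LIKE:
        if host is None:
            raise ParameterError("mu_like packaging requires a host genome for the flanks")
        H = host.sequence
        lo_l, hi_l = params.mu_flank_left
        lo_r, hi_r = params.mu_flank_right
        if len(H) < hi_l + hi_r + 1:
            raise ParameterError("host sequence too short for the configured flank ranges")
        for j in range(n):
            lf = int(rng.integers(lo_l, hi_l + 1))
            rf = int(rng.integers(lo_r, hi_r + 1))
            al = int(rng.integers(0, len(H) - lf))
            ar = int(rng.integers(0, len(H) - rf))
            virions.append(
                SimulatedVirion(
                    f"virion{j}",
                    H[al : al + lf] + rot + H[ar : ar + rf],
                    truth_start=lf,
                    truth_end_type=strategy,
                    host_flank_left=lf,
                    host_flank_right=rf,
                )
            )
    else:
        raise ParameterError(f"strategy {strategy} cannot be simulated")
    return virions


def end_chemistry(
    virions: list[SimulatedVirion],
    strategy: PackagingStrategy,
    c: int = 12,
    p_chem: float = 1.0,
    p_lig: float = 0.02,
    seed: int = 0,
) -> list[SimulatedVirion]:
    """Apply library-prep end chemistry to cos virions.

    5' overhangs are end-filled, duplicating the ``c`` overhang bases at the
    far end of a fraction ``p_chem`` of unligated molecules (coverage peak at
    the cos site); 3' overhangs are degraded, deleting them from a fraction
    ``p_chem`` (coverage valley).  A fraction ``p_lig`` of molecules ligate
    into circles before shearing, represented as a random re-opening of the
    circle so reads can span the cos junction.
    """
    if strategy not in (PackagingStrategy.COS_5, PackagingStrategy.COS_3):
        raise ParameterError("end_chemistry applies to cos_5/cos_3 virions only")
    rng = rng_from_seed(seed)
    out = []
    for v in virions:
        seq = v.sequence
        if rng.random() < p_lig:
            cut = int(rng.integers(0, len(seq)))
            seq = seq[cut:] + seq[:cut]
        elif rng.random() < p_chem:
            if strategy is PackagingStrategy.COS_3:
                seq = seq[c:]
            else:
                seq = seq + seq[:c]
        out.append(
            SimulatedVirion(
                v.id, seq, v.truth_start, v.truth_end_type,
                v.host_flank_left, v.host_flank_right,
            )
        )
    return out


def n_pairs_for_depth(virions, depth: float, read_len: int = 150) -> int:
    """Lander-Waterman pair count for a target mean depth on the assembly.

    Reads from the whole virion population pile onto one contig of roughly
    the mean virion length, so the pair count uses that mean."""
    mean_len = sum(len(v) for v in virions) / len(virions)
    return max(1, int(round(depth * mean_len / (2 * read_len))))


def shear_reads(
    virions: list[SimulatedVirion],
    n_pairs: int,
    insert_min: int = 100,
    insert_max: int = 300,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[ReadPair]:
    """Shear virions into paired-end reads.

    Inserts are uniform in ``[insert_min, insert_max]``; insert start
    positions are uniform with clipping at the molecule termini (see module
    docstring); base errors are i.i.d. substitutions at ``error_rate``.
    Deterministic under a fixed seed.
    """
    if error_rate < 0 or error_rate > 0.05:
        raise ParameterError(f"error_rate {error_rate} outside [0, 0.05]")
    if insert_max < insert_min:
        raise ParameterError("insert_max < insert_min")
    if not virions:
        return []
    rng = rng_from_seed(seed)
    lengths = np.array([len(v) for v in virions], dtype=float)
    weights = lengths / lengths.sum()
    qual = "?" if error_rate == 0 else chr(33 + min(41, int(round(-10 * math.log10(error_rate)))))
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        v = virions[int(rng.choice(len(virions), p=weights))]
        M = len(v)
        ins = int(rng.integers(insert_min, insert_max + 1))
        a = int(rng.integers(-(ins - 1), M))
        start, end = max(a, 0), min(a + ins, M)
        frag = v.sequence[start:end]
        if len(frag) < 31:  # too short to be informative; resample position
            a = int(rng.integers(0, max(1, M - ins + 1)))
            start, end = a, min(a + ins, M)
            frag = v.sequence[start:end]
        mate1 = frag[:read_len]
        mate2 = revcomp(frag)[:read_len]
        if error_rate > 0:
            mate1 = _add_errors(mate1, error_rate, rng)
            mate2 = _add_errors(mate2, error_rate, rng)
        pairs.append(
            ReadPair(
                id=f"{v.id}:pair{i}",
                mate1=mate1,
                mate2=mate2,
                truth_positions=(start, max(start, end - read_len)),
                insert=end - start,
                qual1=qual * len(mate1),
                qual2=qual * len(mate2),
            )
        )
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        if out[i] == "N":
            continue
        alt = "ACGT".replace(out[i], "")
        out[i] = alt[rng.integers(3)]
    return "".join(out)


def make_draft_contig(
    genome: GenomeRecord,
    strategy: PackagingStrategy,
    virions: list[SimulatedVirion],
    seed: int = 0,
    params: PackagingParams | None = None,
) -> tuple[GenomeRecord, dict]:
    """Emulate the de novo assembly outcome for each packaging strategy.

    Circularly permuted or junction-spanning read populations (headful, cos,
    DTR) assemble into the full circle at an arbitrary rotation (the DTR is
    collapsed into a single copy); ITR genomes assemble into the fixed-end
    linear monomer; Mu-like genomes assemble into the phage flanked by the
    one pair of host junctions the assembler happened to extend.

    Returns the contig and a ground-truth dict (rotation offset, terminus
    coordinate on the contig, phage span for Mu).
    """
    params = params or PackagingParams()
    rng = rng_from_seed(seed)
    L = len(genome)
    if strategy in (
        PackagingStrategy.HEADFUL_PAC,
        PackagingStrategy.COS_5,
        PackagingStrategy.COS_3,
        PackagingStrategy.DTR,
    ):
        rho = int(rng.integers(0, L))
        contig = GenomeRecord("contig", genome.sequence[rho:] + genome.sequence[:rho], True)
        terminus = getattr(genome, "pac_site", None) or 0
        if strategy is not PackagingStrategy.HEADFUL_PAC:
            terminus = params.terminus % L
        return contig, {"rotation": rho, "terminus_on_contig": (terminus - rho) % L}
    if strategy is PackagingStrategy.ITR:
        return GenomeRecord("contig", virions[0].sequence, False), {"itr_len": params.itr_len}
    if strategy is PackagingStrategy.MU_LIKE:
        v = virions[0]
        return (
            GenomeRecord("contig", v.sequence, False),
            {"phage_start": v.host_flank_left, "phage_len": L,
             "flank_left": v.host_flank_left, "flank_right": v.host_flank_right},
        )
    raise ParameterError(f"strategy {strategy} cannot be simulated")


def write_truth_table(virions, path) -> None:
    """TSV of per-virion ground truth (id, strategy, start, flank lengths)."""
    with open(path, "w") as fh:
        fh.write("virion_id\tstrategy\ttruth_start\thost_flank_left\thost_flank_right\n")
        for v in virions:
            fh.write(
                f"{v.id}\t{v.truth_end_type.value}\t{v.truth_start}\t"
                f"{v.host_flank_left}\t{v.host_flank_right}\n"
            )
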