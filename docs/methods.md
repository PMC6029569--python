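# Methods

This note records the models behind `termistd`, the tunable parameters
that matter, and the reasoning behind the design choices that were
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The packaged-genome simulator

The simulator (`termistd.simulate`) generates a random circular reference
of configurable length and GC (defaults 40 kb, 43% — the middle of the
realistic range for marine *Vibrio* phages, whose sequenced genomes run
from ~10 kb at 37% GC to ~349 kb at 58%), optionally planting a marker
terminase gene: a reverse-translated copy of a bundled archetype protein,
preceded immediately by a small planted ORF standing in for the small
terminase subunit. For headful genomes the *pac* site defaults to the
start of that upstream ORF, reflecting that headful phages commonly
initiate packaging in or near the small terminase gene.

The archetype set (`data/synthetic_terl_archetypes.faa`) is **synthetic**:
random proteins with a typical globular amino-acid composition, one per
named archetype (Sf6, 933W, T4, P22 → headful; lambda, P2 → 5′ cos;
HK97 → 3′ cos; T7, N4 → DTR; Mu → Mu-like). They carry no real phage
sequence and exist so the similarity-search machinery is exercised
end-to-end; both the FASTA and the class map are user-replaceable with a
curated reference set.

### Virion populations

* **headful** — virions of ⌊f·L⌋ bases cut serially from a rolled-out
  concatemer starting at *pac*; virion *i* of a series starts at
  (pac + i·⌊f·L⌋) mod L. Defaults f = 1.08, series length k = 3.
  A short series near the cited ~110% redundancy bound (2–5 headfuls per
  concatemer, P22-like) produces the visibly elevated coverage region
  downstream of *pac* that headful phages show in real read mappings;
  long series at ~105% flatten the modulation to ±10%, which is below
  the sampling-noise floor of a 50× short-insert library (see *Noise
  model* below) and would make the simulated signature undetectable by
  any classifier — i.e. it would fail to emulate the phenomenon being
  modelled.
* **cos (5′/3′)** — identical unit-length monomers opened at the cos
  coordinate. Library end chemistry is applied separately
  (`end_chemistry`): with probability `p_lig` (default 0.02, "low
  frequency ligation") a molecule circularizes before shearing; otherwise
  with probability `p_chem` (default 1.0 — the polymerase/exonuclease
  treatment runs to completion on unligated ends) the c-base overhang
  (default c = 12, λ-scale) is duplicated at the far end (5′ end-fill,
  → coverage peak) or deleted (3′ exonuclease, → coverage valley).
* **DTR** — the first d bases duplicated at the 3′ end (default d = 300,
  T7/N4 scale). The draft contig collapses the repeat, so it maps as a
  ~2× feature.
* **ITR** — fixed-end linear monomers whose first r bases are the
  reverse complement of the last r (default r = 100). The base just
  inside the repeat is adjusted, if necessary, so the repeat terminates
  at exactly r; otherwise chance complementarity would make the planted
  ITR length ill-defined.
* **Mu-like** — each virion carries host flanks drawn from *different*
  random positions of a supplied host sequence (left 50–150 bp, right
  500–3,000 bp). Because every virion's junction differs, only the one
  junction represented in the draft contig recruits reads — which is
  precisely what produces the sharp terminal drops to near-zero coverage
  on real Mu-like assemblies.

`make_draft_contig` emulates the assembly outcome per strategy:
circularly permuted or junction-spanning populations (headful, cos, DTR)
yield the full circle at a random rotation (DTR collapsed); ITR yields
the linear monomer; Mu yields the phage flanked by one virion's host
junctions.

### Reads and the noise model

Inserts are uniform in [100, 300] bp with 150+150 nt mates; base errors
are i.i.d. substitutions. Insert start positions are uniform **with
clipping at the molecule termini**, emulating end-repair capture of
terminal fragments: coverage stays flat up to molecule ends, with a mild
(~insert/read-length ≈ 1.2–1.3×) terminal over-representation. An
unclipped uniform model would instead suppress coverage within a read
length of every molecule end — and would make the 5′-cos peak physically
impossible, since the filled overhang sits exactly at the molecule ends.
Real terminus-detection protocols rely on terminal read pile-ups, so the
clipped model is the faithful one.

Two consequences matter downstream. First, mates always tile their
fragment completely and overlap when the insert is shorter than 300 bp,
so per-base depth is a compound process: its variance is ≈ 2–3× Poisson
with a correlation length of roughly the insert. At 50× this means ±20%
excursions at the few-hundred-base scale are routine — the noise floor
the classifier is calibrated against. Second, duplication-type features
(filled cos overhangs, collapsed DTRs) have a hard amplitude ceiling of
2×: each molecule carries at most two copies of the duplicated bases.

## Read mapping and coverage

The mapper places each mate by exact k-mer seed (k = 31, seeds tried at
k-spaced offsets) plus ungapped verification with a mismatch budget
(8% of the read length, minimum 2). Circular contigs are mapped against
the doubled sequence and placements folded modulo L; multi-mapping mates
go deterministically to the leftmost hit with an ambiguity count (this
matters inside collapsed repeats). Junction-spanning reads that do not
fit the contig ungapped are left unplaced, as a real strict mapper would
leave them. Per-base depth counts mates covering each base and conserves
mass (Σdepth = Σ placed-mate lengths). For real data, SAM placements or a
bedGraph can be imported instead.

## Coverage-signature classification

`classify_pattern` is a deterministic cascade; every threshold is a named
key on `ClassifierConfig`. The order is: Mu terminal drops (linear
contigs only) → single short peak (cos_peak ≤ 100 bp core, else
short_internal_peak) → short valley (cos_valley) → multiple peaks →
gradual shift (headful) → even → none.

**Peaks and valleys.** A candidate core is a run (≥ 6 bp, ≤ 2% of L,
gaps ≤ 10 bp merged) of the 5-base-median depth beyond a fold of the
2-kb-blockwise median baseline (≥ 1.35× for peaks, ≤ 0.5× for valleys).
Qualification is by **edge sharpness**: the run extreme against the mean
of the 25 bases immediately adjacent on both sides must be ≥ 1.6×
(peaks) or ≤ 0.3× (valleys). Rationale: true duplication/deletion
features are base-exact, so their full amplitude appears within a few
bases, while sampling excursions are smooth at the insert-length scale
and carry their elevation into the adjacent flanks. Measured at the
default study conditions (40 kb, 50×, error-free), true peak edges are
≥ 1.73 and the worst observed noise excursion reaches 1.55; true valley
edges are ≤ 0.11 against noise dips ≥ 0.45. An amplitude-only rule
cannot work here: the physical 2× ceiling of duplication features
overlaps the tail of the compound sampling noise, so a threshold placed
at 2× would sit exactly on the signal and reject half the true features.
Detected valleys are masked out of the peak adjacency so a deep valley
does not make its own shoulders look like sharp peaks, and terminal runs
on linear contigs are ignored (end artifacts of repeat collapse and
terminal-fragment capture, not cut sites). The cos vs DTR size decision
(≤ 100 bp) uses the strongly elevated core width, which is robust to the
run spreading over the adjacent terminal pile-up.

**Gradual shift.** Fitted on ~4-kb-binned log-depth (coarse bins because
of the insert-length noise correlation): the best circular rotation under
a non-increasing isotonic fit must explain ≥ 50% of the binned variance,
with fit range ≥ 1.1×, a contiguous top-quartile/bottom-quartile window
contrast ≥ 1.15, and the fitted decline covering ≥ 60% of the circle.
Step-like "shifts" satisfy this by construction and are deliberately
folded into the same class — both are headful-consistent. The anchor is
then refined at base resolution by a least-squares two-level circular
step fit (sweeping the elevated-window length over 5–60% of L), whose
elevated-window start estimates the *pac*-proximal maximum to within a
couple of hundred bases at 50×.

**Even** requires a ≤ 1.5 max/min ratio of 4-kb bin means. The Mu rule
accepts terminal segments of up to 10% of L per side (sized to admit
right flanks of a few kb on a ~40-kb genome) that drop to ≤ 25% of the
interior median with a ≥ 4× step.

## Standardization

* `relinearize_at_terl_upstream_orf` orients TerL to the forward strand
  (an addition — presentation is strand-agnostic otherwise) and re-opens
  the circle at the start of the ORF immediately preceding TerL. Two
  annotation-hygiene rules make "immediately preceding" well defined with
  a naive 6-frame ORF caller: ORFs wholly contained in another ORF are
  ignored (a real gene caller emits no nested models), and an ORF must
  *end* at or before the TerL start to precede it — among those, the one
  with the greatest end wins. Output is an exact rotation (± reverse
  complement) of the input; conservation is asserted on every call.
* `cut_at_coverage_feature` re-opens at the detected feature midpoint;
  for a cos genome this lands half an overhang (~6 bp) from the physical
  terminus, for a DTR half a repeat (~150 bp).
* `trim_mu_ends` trims terminal segments whose lightly smoothed depth is
  ≤ 25% of the interior median, or, given ≥ 2 group members, trims to
  the interval whose 31-mers are shared with every member (a shared-k-mer
  approximation of the ≥ 95%-identity conserved region).
* `detect_itr`/`select_itr_contig` return the longest candidate contig
  exhibiting an ITR (≥ 30 bp, exact by default), else the longest.
* `scaffold_to_reference` picks the orientation maximizing shared unique
  31-mers and the rotation zeroing their modal offset; fewer than 10
  shared unique k-mers is an error, not a silent guess.
* `select_strategy` assigns one strategy per genome group with precedence
  Mu > ITR > headful > cos/DTR > maintain, voting over (terminase class,
  pattern) pairs. Headful-voted genomes without a terminase scaffold onto
  a resolved member sharing 100% of proteins when one exists. Groups
  mixing Mu-like and non-Mu terminases are flagged for manual review
  (error) rather than resolved silently. The full decision trace is
  recorded in each plan.

## Grouping

Protein clusters are connected components of the cross-genome reciprocal
best-hit graph (BLOSUM62, gap open 11/extend 1; E ≤ 1e-5 with database
size = the searched proteome; aligned span ≥ 75% of the longer protein).
Genome groups are connected components of the genome graph at Jaccard
≥ 0.35 over cluster sets. Connected components replace Markov/flow
clustering deliberately: deterministic, dependency-free, and sufficient
for group-consensus strategy selection; the trade-off is that chained
similarity merges clusters transitively (documented and tested). A
shared-5-mer prefilter skips alignments between unrelated proteins.

## QC

* `ani_from_counts` is the closed form
  1 − ((qm + sm)/2) / ((ql + sl)/2), rounded **half-up to 7 decimals**
  (matching the printed precision of the source table; the bundled
  36-row fixture reproduces every printed value).
* `compare_replicates` globally aligns the pair (match 1, mismatch −2,
  gap open −10, extend −0.5 — invented but fixed constants; the
  acceptance-relevant quantity is the count-based ANI, not the aligner),
  counts substituted columns as SNPs and gapped columns as indel bases,
  and charges each gapped position to the sequence bearing the insertion
  — one consistent choice where the source table's asymmetric mismatch
  columns leave the attribution rule unstated. Pairs sharing < 90% of
  31-mers are rejected as unalignable rather than reported as zero-ANI.
* `prophage_screen` chains shared 31-mers along near-constant diagonals
  (gaps ≤ 100 bp), reports chains ≥ 5 kb at ≥ 95% estimated identity,
  and flags a virus covered over ≥ 90% of its length — a threshold
  chosen so the known positive case (~94% cover) flags while partial
  homology does not.
* `synteny_check` scores the fraction of shared unique 31-mers in
  preserved order (longest increasing subsequence / total shared).

## Naming

The register grammar maps size-fraction codes to pore sizes
({45,46,47} → 0.2 µm, {48,49,50} → 1 µm, {51,52,53} → 5 µm,
{54,55,56} → 63 µm) and water samples A/B/C by first/second/third of
each triple. The printed sample mapping lists only nine of the twelve
codes; the 1-µm codes follow the same positional pattern and are mapped
accordingly. Two cosmetic register variants — a "<Genus> phage " prefix
and a trailing dot after the lineage letter — are preserved on parse so
re-serialization is byte-identical.

## Problem sizes and determinism

The validation round trip runs six packaging strategies × 10 seeds at
L = 40 kb and 50× error-free coverage — the genome scale and depth at
which the signature classes are cleanly separated, and small enough that
the whole suite completes in about a minute. All randomness flows from
a single integer seed per operation; the pipeline manifest hashes every
output so re-runs are bit-identical.

## What the synthetic data does and does not show

The simulator emulates the coverage *signatures* of packaging biology,
not phage genomes: its sequences are random DNA (so called ORFs outside
the planted genes are spurious minis), its terminase archetypes are
synthetic, its insert-size distribution is uniform rather than
library-shaped, and it has no GC bias, no quality-by-cycle error model,
no indel errors, and no real concatemer replication biology. Passing the
round-trip tests therefore shows that the inference machinery recovers
planted signals under realistic sampling noise — not that the thresholds
are calibrated for any particular real instrument or library prep. On
real data the classifier thresholds (all exposed as config keys) may
need adjustment, single-label classification cannot express the rare
combined signatures seen in real collections (e.g. a headful genome with
an additional short internal peak), and group numbering is arbitrary
rather than reproducing any published group identifiers.
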