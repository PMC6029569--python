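"""Shared domain containers.

Coordinates are 0-based half-open everywhere in memory; conversions to
1-based formats (GFF3, SAM) are localized to the writers in :mod:`termistd.seqio`.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import ParameterError

_ALPHABET = frozenset("ACGTN")


class PackagingStrategy(str, enum.Enum):
    """Genome packaging strategy of a tailed phage.

    The label drives both simulation (which termini a virion carries) and
    standardization (how a draft contig is re-linearized).  ``unknown`` is an
    inference outcome only and is never simulated.
    """

    HEADFUL_PAC = "headful_pac"
    COS_5 = "cos_5"
    COS_3 = "cos_3"
    DTR = "dtr"
    ITR = "itr"
    MU_LIKE = "mu_like"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: strategies that can be handed to the simulator
SIMULATABLE_STRATEGIES = (
    PackagingStrategy.HEADFUL_PAC,
    PackagingStrategy.COS_5,
    PackagingStrategy.COS_3,
    PackagingStrategy.DTR,
    PackagingStrategy.ITR,
    PackagingStrategy.MU_LIKE,
)


@dataclass
class GenomeRecord:
    """A nucleotide sequence with an identifier.

    ``circular_hint`` marks contigs that should be interpreted as circular
    (e.g. assemblies of circularly permuted reads).
    """

    id: str
    sequence: str
    circular_hint: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ParameterError(f"empty sequence for record {self.id!r}")
        if not _ALPHABET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise ParameterError(
                f"record {self.id!r} contains non-ACGTN characters {bad}; "
                "normalize on read (see seqio.read_fasta)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimulatedVirion:
    """One packaged physical genome with its ground truth."""

    id: str
    sequence: str
    truth_start: int
    truth_end_type: PackagingStrategy
    host_flank_left: int = 0
    host_flank_right: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """A simulated paired-end read.

    ``truth_positions`` are the (mate1_start, mate2_start) 0-based placements
    on the source virion; mate2 is the reverse complement of the far end of
    the fragment.
    """

    id: str
    mate1: str
    mate2: str
    truth_positions: tuple[int, int]
    insert: int
    qual1: str = ""
    qual2: str = ""


@dataclass
class Placement:
    """An ungapped read placement on a contig (0-based half-open)."""

    read_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int = 0


@dataclass
class CoverageProfile:
    """Per-base read depth along one contig."""

    contig_id: str
    depth: "object"  # numpy int array, length == contig length
    circular: bool = False

    def __post_init__(self) -> None:
        import numpy as np

        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ParameterError("coverage profile must be a non-empty 1-D array")
        if (self.depth < 0).any():
            raise ParameterError("coverage depth must be non-negative")

    def __len__(self) -> int:
        return int(self.depth.size)


class PatternLabel(str, enum.Enum):
    """Read-coverage signature classes (single label per contig)."""

    EVEN = "even"
    GRADUAL_SHIFT = "gradual_shift"
    SHORT_INTERNAL_PEAK = "short_internal_peak"
    COS_VALLEY = "cos_valley"
    COS_PEAK = "cos_peak"
    TERMINAL_DROP_MU = "terminal_drop_mu"
    MULTIPLE_PEAKS = "multiple_peaks"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class PatternCall:
    """Classified coverage signature for one contig."""

    label: PatternLabel
    anchor: int | None
    features: dict = field(default_factory=dict)


@dataclass
class OrfRecord:
    """An open reading frame on forward contig coordinates.

    ``start``/``end`` span start codon through stop codon inclusive
    (half-open); the stop codon is part of the span but not of ``protein``.
    For ORFs wrapping the origin of a circular contig, ``end`` may exceed the
    contig length.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    protein: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class TerminaseAssignment:
    """Best archetype hit for a putative large-terminase ORF."""

    orf: OrfRecord
    reference_name: str
    packaging_class: PackagingStrategy
    bit_score: float
    evalue: float


@dataclass
class RearrangementPlan:
    """Chosen standardization strategy and its coordinates for one genome."""

    strategy: str
    cut_pos: int | None = None
    orientation: str = "keep"  # keep / flip
    trim_left: int = 0
    trim_right: int = 0
    reference_id: str | None = None
    rationale: dict = field(default_factory=dict)


@dataclass
class StandardizedGenome:
    """A standardized contig plus the plan and provenance that produced it."""

    contig: GenomeRecord
    plan: RearrangementPlan
    provenance: dict = field(default_factory=dict)


@dataclass
class ReplicateComparison:
    """Pairwise replicate-assembly comparison (one report row)."""

    query_id: str
    subject_id: str
    query_len: int
    subject_len: int
    query_mismatch: int
    subject_mismatch: int
    ani: float
    snp: int
    indel_bases: int
    start_variation: int
    length_variation: int


@dataclass
class ProphageHit:
    """A high-identity match of a virus genome inside a host contig."""

    virus_id: str
    host_contig_id: str
    match_len: int
    identity: float
    virus_cover: float
    host_contig_len: int
    flagged: bool = False
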