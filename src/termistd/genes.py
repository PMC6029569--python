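"""ORF calling and terminase-archetype assignment.

The ORF caller is deliberately simple (no ribosome-binding-site scoring, no
GC frame model): maximal ORFs in all six frames, from the first start codon
(ATG/GTG/TTG) after each stop to the next stop, translation table 11.
Terminase assignment aligns every called protein against a small set of
archetype large-terminase (TerL) references, each labelled with the
packaging class of its phage; the best hit under an E-value cutoff predicts
the genome packaging strategy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ._util import revcomp
from .align import bit_score, evalue, local_score
from .errors import ParameterError
from .types import GenomeRecord, OrfRecord, PackagingStrategy, TerminaseAssignment

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

#: translation table 11 (= standard table for coding codons)
_CODON_TABLE = {}


def _build_codon_table() -> dict[str, str]:
    if _CODON_TABLE:
        return _CODON_TABLE
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1
    return _CODON_TABLE


def translate(nt: str) -> str:
    """Translate a coding sequence (table 11); ``X`` for ambiguous codons."""
    table = _build_codon_table()
    return "".join(
        table.get(nt[i : i + 3], "X") for i in range(0, len(nt) - len(nt) % 3, 3)
    )


#: synonymous codons per amino acid, for reverse translation
_SYNONYMS: dict[str, list[str]] = {}


def _synonyms() -> dict[str, list[str]]:
    if not _SYNONYMS:
        for codon, aa in _build_codon_table().items():
            if aa != "*":
                _SYNONYMS.setdefault(aa, []).append(codon)
    return _SYNONYMS


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous coding sequence for ``protein`` (no stop appended)."""
    syn = _synonyms()
    return "".join(syn[aa][rng.integers(len(syn[aa]))] for aa in protein)


def _scan_strand(seq: str, min_nt: int):
    """Yield (start, end, protein) for maximal ORFs on one strand."""
    table = _build_codon_table()
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            aa = table.get(codon, "X")
            if aa == "*":
                if start is not None and pos + 3 - start >= min_nt:
                    yield start, pos + 3, translate(seq[start:pos])
                start = None
            elif start is None and codon in START_CODONS:
                start = pos


def find_orfs(contig: GenomeRecord, circular: bool = False, min_aa: int = 60) -> list[OrfRecord]:
    """Call maximal ORFs in all six frames, sorted by start coordinate.

    Coordinates are forward-strand 0-based half-open spanning start through
    stop codon; the reported protein translates the span minus the stop, with
    alternative starts (GTG/TTG) reported as their table-11 amino acid.  On
    circular contigs ``end`` may exceed the contig length for ORFs that wrap
    the origin.
    """
    L = len(contig)
    min_nt = 3 * (min_aa + 1)
    # Circular contigs are scanned on the tripled sequence, keeping ORFs that
    # start in the middle copy: each circular ORF (shorter than L) appears
    # there exactly once, with a full lap of upstream context so its start is
    # maximal even across the origin.
    seq = contig.sequence * 3 if circular else contig.sequence
    orfs: list[OrfRecord] = []

    for start, end, protein in _scan_strand(seq, min_nt):
        if circular:
            if not L <= start < 2 * L:
                continue
            orfs.append(OrfRecord(contig.id, start - L, end - L, "+", protein))
        else:
            orfs.append(OrfRecord(contig.id, start, end, "+", protein))

    rc = revcomp(seq)
    n = len(seq)
    for start, end, protein in _scan_strand(rc, min_nt):
        # map reverse-strand interval back to forward coordinates
        fwd_start, fwd_end = n - end, n - start
        if circular:
            if not L <= fwd_start < 2 * L:
                continue
            orfs.append(OrfRecord(contig.id, fwd_start - L, fwd_end - L, "-", protein))
        else:
            orfs.append(OrfRecord(contig.id, fwd_start, fwd_end, "-", protein))

    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


@dataclass
class Archetype:
    """One labelled reference terminase protein."""

    name: str
    protein: str
    packaging_class: PackagingStrategy


def load_archetypes(fasta_path=None, class_map_path=None) -> list[Archetype]:
    """Load the terminase archetype reference set.

    Defaults to the bundled *synthetic* archetype proteins (random sequences
    with realistic composition standing in for curated public TerL
    references) plus their packaging-class map; both files are
    user-replaceable.
    """
    data = resources.files("termistd") / "data"
    fasta_path = fasta_path or data / "synthetic_terl_archetypes.faa"
    class_map_path = class_map_path or data / "terl_class_map.tsv"

    classes: dict[str, PackagingStrategy] = {}
    with open(class_map_path) as fh:
        next(fh)
        for line in fh:
            name, cls = line.split()
            classes[name] = PackagingStrategy(cls)

    archetypes: list[Archetype] = []
    name, chunks = None, []
    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    archetypes.append(Archetype(name, "".join(chunks), classes[name]))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        archetypes.append(Archetype(name, "".join(chunks), classes[name]))
    return archetypes


def assign_terminase(
    orfs: list[OrfRecord],
    refs: list[Archetype] | None = None,
    evalue_cutoff: float = 1e-3,
) -> TerminaseAssignment | None:
    """Best archetype hit across all ORFs, or None below significance.

    Every ORF protein is locally aligned against every reference; the
    E-value uses database size = sum of reference lengths.  Ties on E-value
    break by higher bit score, then lexicographic reference name.
    """
    if refs is None:
        refs = load_archetypes()
    if not refs:
        raise ParameterError("empty archetype reference set")
    if not orfs:
        logger.warning("assign_terminase called with no ORFs")
        return None
    db_len = sum(len(r.protein) for r in refs)
    best: TerminaseAssignment | None = None
    best_key = None
    for orf in orfs:
        if not orf.protein:
            continue
        for ref in refs:
            score = local_score(orf.protein, ref.protein)
            e = evalue(score, len(orf.protein), db_len)
            if e >= evalue_cutoff:
                continue
            key = (e, -score, ref.name)
            if best_key is None or key < best_key:
                best_key = key
                best = TerminaseAssignment(
                    orf=orf,
                    reference_name=ref.name,
                    packaging_class=ref.packaging_class,
                    bit_score=bit_score(score),
                    evalue=e,
                )
    return best
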