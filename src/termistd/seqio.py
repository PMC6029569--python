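"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython; bedGraph, GFF3 and minimal
SAM output are thin enough to handle directly.  All in-memory coordinates are
0-based half-open; the GFF3/SAM writers own the 1-based conversions.
"""
from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .errors import FormatError
from .types import CoverageProfile, GenomeRecord, OrfRecord, Placement, ReadPair

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGTN")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _normalize(seq: str, record_id: str) -> str:
    """Uppercase and collapse IUPAC ambiguity codes (and anything else) to N."""
    seq = seq.upper()
    if _VALID.issuperset(seq):
        return seq
    n_bad = sum(c not in _VALID for c in seq)
    logger.warning("record %s: %d non-ACGTN characters collapsed to N", record_id, n_bad)
    return "".join(c if c in _VALID else "N" for c in seq)


def read_fasta(path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Lowercase is normalized to uppercase and IUPAC ambiguity codes to ``N``
    (with a logged count).  Duplicate ids raise :class:`FormatError`; an
    empty file yields an empty list.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(GenomeRecord(rec.id, _normalize(str(rec.seq), rec.id)))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path) -> list[ReadPair]:
    """Read an interleaved FASTQ file (mate1, mate2, mate1, ...)."""
    with _open_text(path) as fh:
        recs = list(SeqIO.parse(fh, "fastq"))
    if len(recs) % 2:
        raise FormatError(f"interleaved FASTQ {path} has an odd number of records")
    pairs = []
    for r1, r2 in zip(recs[::2], recs[1::2]):
        pairs.append(
            ReadPair(
                id=r1.id.removesuffix("/1"),
                mate1=str(r1.seq),
                mate2=str(r2.seq),
                truth_positions=(-1, -1),
                insert=-1,
                qual1="".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"]),
                qual2="".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def read_fastq_pair(path1, path2) -> list[ReadPair]:
    """Read paired FASTQ from separate mate-1/mate-2 files."""
    with _open_text(path1) as f1, _open_text(path2) as f2:
        recs1 = list(SeqIO.parse(f1, "fastq"))
        recs2 = list(SeqIO.parse(f2, "fastq"))
    if len(recs1) != len(recs2):
        raise FormatError("mate files have different record counts")
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        pairs.append(
            ReadPair(
                id=r1.id.removesuffix("/1"),
                mate1=str(r1.seq),
                mate2=str(r2.seq),
                truth_positions=(-1, -1),
                insert=-1,
                qual1="".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"]),
                qual2="".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def write_fastq(pairs, path1, path2=None) -> None:
    """Write read pairs as FASTQ; interleaved if ``path2`` is omitted.

    ``.gz`` suffixes trigger gzip compression.
    """

    def _rec(read_id, mate, seq, qual):
        qual = qual or "?" * len(seq)  # constant Q30
        rec = SeqRecord(Seq(seq), id=f"{read_id}/{mate}", description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        return rec

    if path2 is None:
        with _open_text(path1, "wt") as fh:
            for p in pairs:
                SeqIO.write(_rec(p.id, 1, p.mate1, p.qual1), fh, "fastq")
                SeqIO.write(_rec(p.id, 2, p.mate2, p.qual2), fh, "fastq")
    else:
        with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
            for p in pairs:
                SeqIO.write(_rec(p.id, 1, p.mate1, p.qual1), f1, "fastq")
                SeqIO.write(_rec(p.id, 2, p.mate2, p.qual2), f2, "fastq")


def read_bedgraph_coverage(path, contig_len: int) -> CoverageProfile:
    """Expand a bedGraph into a per-base :class:`CoverageProfile`.

    Intervals are 0-based half-open and must tile ``[0, contig_len)`` without
    overlap after expansion; gaps are filled with zero depth.
    """
    depth = np.zeros(contig_len, dtype=np.int64)
    covered = np.zeros(contig_len, dtype=bool)
    contig_id = "coverage"
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            try:
                chrom, start, end, value = line.split()[:4]
                start, end = int(start), int(end)
                value = int(float(value))
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: malformed bedGraph line") from exc
            if end > contig_len:
                raise FormatError(
                    f"{path}:{line_no}: interval end {end} beyond contig length {contig_len}"
                )
            if covered[start:end].any():
                raise FormatError(f"{path}:{line_no}: overlapping bedGraph intervals")
            covered[start:end] = True
            depth[start:end] = value
            contig_id = chrom
    return CoverageProfile(contig_id, depth)


def write_bedgraph(profile: CoverageProfile, path) -> None:
    """Write a coverage profile as run-length-encoded bedGraph."""
    depth = profile.depth
    boundaries = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [depth.size]])
    with _open_text(path, "wt") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{profile.contig_id}\t{s}\t{e}\t{depth[s]}\n")


def write_gff3(orfs, path) -> None:
    """Write ORFs as GFF3 CDS features (1-based inclusive coordinates)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for i, orf in enumerate(orfs):
            fh.write(
                "\t".join(
                    [
                        orf.contig_id,
                        "termistd",
                        "CDS",
                        str(orf.start + 1),
                        str(orf.end),
                        ".",
                        orf.strand,
                        "0",
                        f"ID=orf{i + 1};protein={orf.protein}",
                    ]
                )
                + "\n"
            )


def read_gff3_orfs(path) -> list[OrfRecord]:
    """Read CDS features written by :func:`write_gff3` back into ORF records."""
    orfs = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            orfs.append(
                OrfRecord(
                    contig_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    protein=attrs.get("protein", ""),
                )
            )
    return orfs


def write_sam_placements(placements, contig: GenomeRecord, path) -> None:
    """Write ungapped placements as a minimal single-reference SAM file."""
    with _open_text(path, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{contig.id}\tLN:{len(contig)}\n")
        for p in placements:
            flag = 16 if p.strand == "-" else 0
            length = p.end - p.start
            seq = contig.sequence[p.start : p.end]
            if p.strand == "-":
                seq = revcomp(seq)
            fh.write(
                f"{p.read_id}\t{flag}\t{contig.id}\t{p.start + 1}\t60\t{length}M\t*\t0\t0\t{seq}\t*\tNM:i:{p.mismatches}\n"
            )


def read_sam_placements(path) -> list[Placement]:
    """Adapter: import mapped reads from a minimal SAM file as placements."""
    placements = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 11:
                raise FormatError(f"short SAM line in {path}")
            flag = int(cols[1])
            if flag & 4:  # unmapped
                continue
            start = int(cols[3]) - 1
            length = len(cols[9]) if cols[9] != "*" else 0
            placements.append(
                Placement(
                    read_id=cols[0],
                    start=start,
                    end=start + length,
                    strand="-" if flag & 16 else "+",
                )
            )
    return placements
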