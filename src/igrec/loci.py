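"""Putative Ig loci on GRCh38 and extraction of overlapping read pairs.

Five regions of the GRCh38 reference (the IGH locus, Ig pseudogene loci and
two unlocalized contigs on chromosomes 14-16) capture essentially all reads
that contribute to Ig transcript reconstruction, so extracting just those
reads before assembly shrinks the problem by two orders of magnitude.

Coordinate convention (deliberate and load-bearing): intervals are half-open
with an *exclusive* start -- a 1-based alignment position p overlaps the
interval iff ``start < p <= end`` -- so that ``length == end - start``
exactly. Equivalently, (start, end) is a 0-based half-open interval, the
same convention as BED and pysam. The two whole-contig loci are stored with
start 0 (their first 1-based base, printed as 1 in genome annotations, is
exclusive start 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pysam

from .align import revcomp
from .io import ReadPair


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval (exclusive start / 0-based half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def first_pos(self) -> int:
        """First included position, 1-based."""
        return self.start + 1

    def overlaps(self, chrom: str, ref_start0: int, ref_end0: int) -> bool:
        """Overlap with a 0-based half-open alignment span (>= 1 bp)."""
        return chrom == self.chrom and ref_start0 < self.end and ref_end0 > self.start


def interval_length(iv: GenomicInterval) -> int:
    """Length in nt under the exclusive-start convention (end - start)."""
    return iv.length


@dataclass(frozen=True)
class LociTable:
    intervals: tuple[GenomicInterval, ...]

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, chrom: str, ref_start0: int, ref_end0: int) -> bool:
        return any(iv.overlaps(chrom, ref_start0, ref_end0) for iv in self.intervals)


def builtin_loci() -> LociTable:
    """The five built-in putative Ig loci on GRCh38."""
    return LociTable(
        (
            GenomicInterval("chr14", 105_550_001, 106_880_000),
            GenomicInterval("chr15", 21_710_000, 22_190_000),
            GenomicInterval("chr16", 31_950_001, 33_970_000),
            GenomicInterval("chr14_KI270726v1_random", 0, 43_739),
            GenomicInterval("chr16_KI270728v1_random", 0, 1_872_759),
        )
    )


def load_bed_loci(path: str | Path) -> LociTable:
    """User-override loci from BED (0-based half-open, i.e. stored as-is)."""
    ivs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    if not ivs:
        raise ValueError(f"no intervals found in {path}")
    return LociTable(tuple(ivs))


def _original_read(aln: pysam.AlignedSegment) -> tuple[str, str]:
    """Sequence and quality in original sequencing orientation."""
    seq = aln.query_sequence or ""
    if aln.query_qualities is not None:
        qual = "".join(chr(q + 33) for q in aln.query_qualities)
    else:
        qual = "I" * len(seq)
    if aln.is_reverse:
        seq = revcomp(seq)
        qual = qual[::-1]
    return seq, qual


def extract_ig_reads(
    alignment_path: str | Path,
    loci: Optional[LociTable] = None,
) -> list[ReadPair]:
    """Extract read pairs overlapping the Ig loci from SAM/BAM.

    A pair is emitted iff at least one mate's primary alignment overlaps
    >= 1 bp of >= 1 locus; the partner is emitted regardless of where (or
    whether) it aligned (mate rescue). Secondary and supplementary
    alignments never decide membership and are never emitted; duplicate-
    flagged reads are retained. Sequences are restored to original read
    orientation. Pairs are returned sorted by read name; single-end input is
    an error.
    """
    loci = loci if loci is not None else builtin_loci()
    path = str(alignment_path)

    selected: set[str] = set()
    with pysam.AlignmentFile(path, require_index=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.is_paired:
                raise ValueError(
                    "single-end input: Ig extraction requires paired-end alignments"
                )
            if aln.is_unmapped or aln.reference_name is None:
                continue
            if loci.overlaps(aln.reference_name, aln.reference_start, aln.reference_end):
                selected.add(aln.query_name)

    mates: dict[str, dict[int, tuple[str, str]]] = {}
    with pysam.AlignmentFile(path, require_index=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.query_name in selected and aln.query_sequence:
                mate = 1 if aln.is_read1 else 2
                mates.setdefault(aln.query_name, {})[mate] = _original_read(aln)

    pairs: list[ReadPair] = []
    for name in sorted(mates):
        rec = mates[name]
        if 1 in rec and 2 in rec:
            pairs.append(ReadPair(name, rec[1][0], rec[1][1], rec[2][0], rec[2][1]))
        else:
            warnings.warn(f"read {name}: mate missing from alignment file; pair skipped")
    return pairs
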