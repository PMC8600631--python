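"""IMGT-style germline allele database for human IGH V, D and J segments.

Alleles follow IMGT nomenclature: ``<gene>*<two-digit allele>``, e.g.
``IGHV3-74*01``. The segment class (V, D or J) is encoded by the fourth
character of the gene name. Databases may be loaded from plain FASTA
(``>IGHV3-74*01``) or from raw IMGT downloads with pipe-delimited 16-field
headers (``>X12345|IGHV3-74*01|Homo sapiens|F|...``); IMGT alignment gap dots
are stripped so that all downstream coordinates refer to the ungapped
nucleotide sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Segment(str, Enum):
    """Ig heavy-chain gene segment class."""

    V = "V"
    D = "D"
    J = "J"


_ALLELE_RE = re.compile(r"^(IGH([VDJ])[A-Za-z0-9./-]*)\*(\d{2})$")

#: Region labels allowed in a V-allele CDR/framework map, in order.
REGION_LABELS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")


class GermlineError(ValueError):
    """Raised for malformed germline databases or allele names."""


def parse_allele_name(header: str) -> tuple[str, str, Segment]:
    """Split an IMGT allele name into (gene, allele suffix, segment).

    >>> parse_allele_name("IGHV2-70*01")
    ('IGHV2-70', '01', <Segment.V: 'V'>)
    """
    if not header:
        raise GermlineError("empty allele name")
    m = _ALLELE_RE.match(header)
    if m is None:
        if "*" not in header:
            raise GermlineError(f"allele name {header!r} lacks an '*' allele suffix")
        raise GermlineError(
            f"allele name {header!r} is not an IGH V/D/J allele "
            "(expected e.g. 'IGHV3-74*01')"
        )
    gene, seg, suffix = m.group(1), m.group(2), m.group(3)
    return gene, suffix, Segment(seg)


@dataclass(frozen=True)
class GermlineAllele:
    """One germline allele: the reference against which SHM is counted.

    ``cdr_fr_map`` optionally partitions a V allele into framework and CDR
    intervals (half-open, on the ungapped sequence); it is used by the read
    simulator to enrich SHM in CDRs and is never required for classification.
    """

    name: str
    gene: str
    segment: Segment
    sequence: str
    cdr_fr_map: Optional[tuple[tuple[str, int, int], ...]] = None

    def __post_init__(self) -> None:
        gene, _suffix, seg = parse_allele_name(self.name)
        if gene != self.gene:
            raise GermlineError(f"gene {self.gene!r} inconsistent with name {self.name!r}")
        if seg != self.segment:
            raise GermlineError(f"segment {self.segment} inconsistent with name {self.name!r}")
        if not self.sequence:
            raise GermlineError(f"allele {self.name}: empty sequence")
        if set(self.sequence) - set("ACGTN"):
            raise GermlineError(
                f"allele {self.name}: sequence contains characters outside A/C/G/T/N"
            )
        if self.cdr_fr_map is not None:
            prev_end = 0
            for label, start, end in self.cdr_fr_map:
                if label not in REGION_LABELS:
                    raise GermlineError(f"allele {self.name}: unknown region label {label!r}")
                if not (0 <= start < end <= len(self.sequence)):
                    raise GermlineError(
                        f"allele {self.name}: region {label} ({start},{end}) out of bounds"
                    )
                if start < prev_end:
                    raise GermlineError(
                        f"allele {self.name}: region {label} overlaps the previous region"
                    )
                prev_end = end

    def cdr_positions(self) -> set[int]:
        """0-based positions falling in a CDR interval (empty set if unmapped)."""
        if self.cdr_fr_map is None:
            return set()
        out: set[int] = set()
        for label, start, end in self.cdr_fr_map:
            if label.startswith("CDR"):
                out.update(range(start, end))
        return out


class GermlineDB:
    """Validated, indexed collection of germline alleles."""

    def __init__(self, alleles: Iterable[GermlineAllele] = ()) -> None:
        self.alleles: dict[str, GermlineAllele] = {}
        self.by_segment: dict[Segment, list[GermlineAllele]] = {s: [] for s in Segment}
        for a in alleles:
            self.add(a)

    def add(self, allele: GermlineAllele) -> None:
        if allele.name in self.alleles:
            raise GermlineError(f"duplicate allele name {allele.name!r}")
        self.alleles[allele.name] = allele
        self.by_segment[allele.segment].append(allele)

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, name: str) -> bool:
        return name in self.alleles

    def __getitem__(self, name: str) -> GermlineAllele:
        return self.alleles[name]

    def segment(self, seg: Segment | str) -> list[GermlineAllele]:
        """Alleles of one segment class, in insertion order."""
        return list(self.by_segment[Segment(seg)])

    def validate_complete(self) -> None:
        """Require at least one allele per segment class (precondition for
        annotation)."""
        missing = [s.value for s in Segment if not self.by_segment[s]]
        if missing:
            raise GermlineError(
                f"germline database lacks segment class(es): {', '.join(missing)}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GermlineDB):
            return NotImplemented
        return self.alleles == other.alleles


def _header_allele_name(header: str, record_number: int) -> str:
    token = header.split()[0] if header.split() else ""
    if "|" in token:
        fields = token.split("|")
        if len(fields) < 2 or not fields[1]:
            raise GermlineError(
                f"record {record_number}: cannot find allele name in IMGT header {header!r}"
            )
        token = fields[1]
    if not token:
        raise GermlineError(f"record {record_number}: empty FASTA header")
    return token


def load_germline(path: str | Path) -> GermlineDB:
    """Load a germline FASTA into a validated :class:`GermlineDB`.

    Accepts plain headers (first whitespace token is the allele name) and
    IMGT pipe-delimited headers (second pipe field is the allele name),
    auto-detected per record. Sequences are upper-cased and IMGT gap dots
    removed. Duplicate allele names, unparseable headers and empty files are
    hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = GermlineDB()
    n = 0
    for n, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        name = _header_allele_name(rec.description, n)
        try:
            gene, _suffix, seg = parse_allele_name(name)
        except GermlineError as e:
            raise GermlineError(f"record {n}: {e}") from None
        seq = str(rec.seq).upper().replace(".", "")
        db.add(GermlineAllele(name=name, gene=gene, segment=seg, sequence=seq))
    if n == 0:
        raise GermlineError(f"no FASTA records found in {path}")
    return db


def write_germline(db: GermlineDB, path: str | Path) -> None:
    """Write a database back to plain FASTA (one record per allele)."""
    records = [
        SeqRecord(Seq(a.sequence), id=a.name, description="")
        for a in db.alleles.values()
    ]
    SeqIO.write(records, str(path), "fasta")
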