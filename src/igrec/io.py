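"""Paired-FASTQ and contig FASTA readers/writers shared by the pipeline
stages."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ReadPair(NamedTuple):
    """One paired-end read with per-mate sequence and quality strings."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> int:
    """Write synchronized ``_1``/``_2`` FASTQ files (Phred+33). Returns the
    number of pairs written."""
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Read two synchronized FASTQ files; mate ids must agree in order."""
    out: list[ReadPair] = []
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for r1, r2 in zip(f1, f2, strict=True):
            n1, n2 = _strip_mate_suffix(r1.name), _strip_mate_suffix(r2.name)
            if n1 != n2:
                raise ValueError(f"FASTQ files are not mate-synchronized: {n1!r} vs {n2!r}")
            out.append(
                ReadPair(n1, r1.sequence.upper(), r1.quality or "", r2.sequence.upper(), r2.quality or "")
            )
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> int:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    return SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
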