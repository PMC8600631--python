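"""End-to-end orchestration: extract -> trim -> assemble -> screen ->
quantify -> annotate -> classify, with per-stage outputs and a manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .align import EvalueParams, ScoringScheme
from .annotate import VDJAnnotation, annotate
from .assemble import AssemblyConfig, Contig, assemble
from .germline import GermlineDB, load_germline
from .io import ReadPair, read_fastq_pairs, write_fasta, write_fastq_pairs
from .loci import LociTable, builtin_loci, extract_ig_reads
from .quant import AbundanceRecord, filter_ig_contigs, quantify_tpm
from .report import SampleReport, annotations_to_frame, build_sample_report

logger = logging.getLogger("igrec")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs. Exactly one of ``alignment`` or
    the FASTQ pair must be given."""

    germline_fasta: str
    out_dir: str
    sample_id: str = "sample"
    alignment: Optional[str] = None
    fastq1: Optional[str] = None
    fastq2: Optional[str] = None
    loci_bed: Optional[str] = None
    seed: int = 0
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    max_e: float = 20.0
    seed_size: int = 16
    quant_k: int = 31
    mean_fragment: float = 200.0
    min_d_match: int = 5
    cutoff: float = 98.0
    cutoff_inclusive: bool = False
    quality_trim: bool = True
    quality_floor: int = 20

    def validate(self) -> None:
        if (self.alignment is None) == (self.fastq1 is None or self.fastq2 is None):
            raise ValueError("provide either an alignment file or a FASTQ pair")
        for p in (self.germline_fasta, self.alignment, self.fastq1, self.fastq2, self.loci_bed):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def quality_trim_pairs(
    pairs: Sequence[ReadPair], q_floor: int = 20, min_length: int = 26
) -> list[ReadPair]:
    """3'-trim bases below ``q_floor`` (Phred+33); drop pairs in which either
    mate falls under ``min_length``."""

    def trim(seq: str, qual: str) -> tuple[str, str]:
        if not qual:
            return seq, qual
        end = len(seq)
        while end > 0 and ord(qual[end - 1]) - 33 < q_floor:
            end -= 1
        return seq[:end], qual[:end]

    out = []
    for p in pairs:
        s1, q1 = trim(p.seq1, p.qual1)
        s2, q2 = trim(p.seq2, p.qual2)
        if len(s1) >= min_length and len(s2) >= min_length:
            out.append(ReadPair(p.name, s1, q1, s2, q2))
    return out


@dataclass
class PipelineResult:
    report: SampleReport
    contigs: list[Contig]
    annotations: list[VDJAnnotation]
    abundances: list[AbundanceRecord]
    manifest: dict


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage, writing each stage's output under ``cfg.out_dir``.

    Any stage error aborts with the failing stage named; outputs written
    before the failure are retained.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "sample_id": cfg.sample_id,
        "stages": {},
    }
    stage = "load_germline"
    try:
        db = load_germline(cfg.germline_fasta)
        db.validate_complete()

        stage = "extract"
        if cfg.alignment is not None:
            loci: Optional[LociTable] = None
            if cfg.loci_bed:
                from .loci import load_bed_loci

                loci = load_bed_loci(cfg.loci_bed)
            pairs = extract_ig_reads(cfg.alignment, loci)
            write_fastq_pairs(pairs, out / "extracted_1.fastq", out / "extracted_2.fastq")
        else:
            pairs = read_fastq_pairs(cfg.fastq1, cfg.fastq2)
        manifest["stages"]["extract"] = {"read_pairs": len(pairs)}

        stage = "quality_trim"
        if cfg.quality_trim:
            pairs = quality_trim_pairs(pairs, cfg.quality_floor, cfg.assembly.k + 1)
        manifest["stages"]["quality_trim"] = {"read_pairs": len(pairs)}

        stage = "assemble"
        contigs = assemble(pairs, cfg.assembly)
        write_fasta([(c.id, c.sequence) for c in contigs], out / "contigs.fasta")
        manifest["stages"]["assemble"] = {"contigs": len(contigs)}

        stage = "screen"
        hits = filter_ig_contigs(
            contigs, db, max_e=cfg.max_e, scheme=cfg.scoring, seed_size=cfg.seed_size
        )
        ig_contigs = [h.contig for h in hits]
        manifest["stages"]["screen"] = {"ig_contigs": len(ig_contigs)}

        stage = "quantify"
        abundances: list[AbundanceRecord] = []
        if ig_contigs:
            abundances = quantify_tpm(ig_contigs, pairs, k=cfg.quant_k, mean_fragment=cfg.mean_fragment)
            pd_frame = [dataclasses.asdict(r) for r in abundances]
            import pandas as pd

            pd.DataFrame(pd_frame).to_csv(out / "abundance.tsv", sep="\t", index=False)
        manifest["stages"]["quantify"] = {"records": len(abundances)}

        stage = "annotate"
        annotations = []
        for c in ig_contigs:
            a = annotate(
                c, db, scheme=cfg.scoring, max_e=cfg.max_e, min_d_match=cfg.min_d_match
            )
            if a is not None:
                annotations.append(a)
        tpms = {r.transcript_id: r.tpm for r in abundances}
        annotations_to_frame(annotations, tpms).to_csv(out / "annotations.tsv", sep="\t", index=False)
        manifest["stages"]["annotate"] = {"annotated": len(annotations)}

        stage = "classify"
        report = build_sample_report(
            cfg.sample_id, annotations, abundances, cfg.cutoff, cfg.cutoff_inclusive
        )
        (out / "report.json").write_text(report.to_json())
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        report=report,
        contigs=contigs,
        annotations=annotations,
        abundances=abundances,
        manifest=manifest,
    )
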