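"""Clonotype grouping, SHM status classification, per-sample reporting and
cohort concordance metrics.

The clinical call: a sample is *unmutated* (uCLL, adverse prognosis) when
the dominant productive transcript's V identity to its best germline allele
exceeds 98%, and *mutated* (mCLL) otherwise. The strict ``>`` is the stated
clinical definition; an inclusive ``>=`` variant is selectable, and calls
within +/- 0.5 percentage points of the cutoff carry a borderline flag
because the two conventions (and assay noise) can flip them.

Clonotypes group transcripts by the exact key (V gene, J gene, junction
nucleotide string): the strictest reproducible criterion. An identity-
threshold variant can be enabled for noisy data via ``junction_identity``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats

import edlib

from .annotate import VDJAnnotation
from .germline import parse_allele_name
from .quant import AbundanceRecord, DominantSelection, dominant_transcript, within_one_log10

MUTATED = "mutated"
UNMUTATED = "unmutated"


@dataclass(frozen=True)
class Clonotype:
    v_gene: str
    j_gene: str
    junction_key: str
    member_transcripts: tuple[str, ...]
    summed_tpm: float


@dataclass
class SampleReport:
    sample_id: str
    status: str  # "ok" or "no_ig_transcript"
    shm_status: Optional[str] = None
    mutation_percent: Optional[float] = None
    v_call: Optional[str] = None
    d_call: Optional[str] = None
    j_call: Optional[str] = None
    dominant_id: Optional[str] = None
    dominant_productive: bool = False
    dominant_tie: bool = False
    borderline_flag: bool = False
    n_ig_transcripts: int = 0
    n_clonotypes: int = 0
    colisted_transcripts: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    n_agree: int
    accuracy: float
    sensitivity: float
    specificity: float
    pearson_r: Optional[float] = None


def classify_shm(v_identity_percent: float, cutoff: float = 98.0, inclusive: bool = False) -> str:
    """Unmutated iff identity > cutoff (or >= with ``inclusive``)."""
    if not 0.0 <= v_identity_percent <= 100.0:
        raise ValueError("identity must be in [0, 100]")
    if inclusive:
        return UNMUTATED if v_identity_percent >= cutoff else MUTATED
    return UNMUTATED if v_identity_percent > cutoff else MUTATED


def is_borderline(v_identity_percent: float, cutoff: float = 98.0, margin: float = 0.5) -> bool:
    return abs(v_identity_percent - cutoff) <= margin


def group_clonotypes(
    annotations: Sequence[VDJAnnotation],
    tpms: Optional[Mapping[str, float]] = None,
    junction_identity: Optional[float] = None,
) -> list[Clonotype]:
    """Group complete annotations into clonotypes.

    Default: exact (V gene, J gene, junction string) key. With
    ``junction_identity`` set (e.g. 0.9), same-V/J groups whose junctions
    reach that identity are merged (single-linkage) -- off by default.
    """
    tpms = tpms or {}
    keyed: dict[tuple[str, str, str], list[VDJAnnotation]] = {}
    for a in annotations:
        if not a.complete:
            continue
        v_gene = parse_allele_name(a.v_call)[0]
        j_gene = parse_allele_name(a.j_call)[0]
        keyed.setdefault((v_gene, j_gene, a.junction), []).append(a)

    groups: list[tuple[tuple[str, str, str], list[VDJAnnotation]]] = list(keyed.items())
    if junction_identity is not None:
        merged: list[tuple[tuple[str, str, str], list[VDJAnnotation]]] = []
        for key, members in sorted(groups):
            for mkey, mmembers in merged:
                if key[:2] != mkey[:2]:
                    continue
                d = edlib.align(key[2], mkey[2], task="distance")["editDistance"]
                denom = max(len(key[2]), len(mkey[2]), 1)
                if 1.0 - d / denom >= junction_identity:
                    mmembers.extend(members)
                    break
            else:
                merged.append((key, list(members)))
        groups = merged

    out = [
        Clonotype(
            v_gene=key[0],
            j_gene=key[1],
            junction_key=key[2],
            member_transcripts=tuple(sorted(a.transcript_id for a in members)),
            summed_tpm=sum(tpms.get(a.transcript_id, 0.0) for a in members),
        )
        for key, members in groups
    ]
    return sorted(out, key=lambda c: (-c.summed_tpm, c.v_gene, c.j_gene, c.junction_key))


def build_sample_report(
    sample_id: str,
    annotations: Sequence[VDJAnnotation],
    records: Sequence[AbundanceRecord],
    cutoff: float = 98.0,
    inclusive: bool = False,
) -> SampleReport:
    """Aggregate one sample: dominant clone, SHM status, transcript and
    clonotype counts, one-log10 co-reported set."""
    if not annotations:
        return SampleReport(sample_id=sample_id, status="no_ig_transcript")
    ann_by_id = {a.transcript_id: a for a in annotations}
    records = [r for r in records if r.transcript_id in ann_by_id]
    if not records:
        return SampleReport(sample_id=sample_id, status="no_ig_transcript")

    productive = {a.transcript_id: a.productive for a in annotations}
    sel: DominantSelection = dominant_transcript(records, productive)
    dom = ann_by_id[sel.transcript_id]
    tpms = {r.transcript_id: r.tpm for r in records}
    clonotypes = group_clonotypes(annotations, tpms)

    return SampleReport(
        sample_id=sample_id,
        status="ok",
        shm_status=classify_shm(dom.v_identity_percent, cutoff, inclusive),
        mutation_percent=dom.mutation_percent,
        v_call=dom.v_call,
        d_call=dom.d_call,
        j_call=dom.j_call,
        dominant_id=dom.transcript_id,
        dominant_productive=sel.productive,
        dominant_tie=sel.tie,
        borderline_flag=is_borderline(dom.v_identity_percent, cutoff),
        n_ig_transcripts=len(annotations),
        n_clonotypes=len(clonotypes),
        colisted_transcripts=tuple(sorted(within_one_log10(records))) if any(r.tpm > 0 for r in records) else (),
    )


def concordance(
    calls: Mapping[str, str],
    reference: Mapping[str, str],
    calls_mutation_percent: Optional[Mapping[str, float]] = None,
    reference_mutation_percent: Optional[Mapping[str, float]] = None,
    positive: str = UNMUTATED,
) -> ConcordanceResult:
    """Agreement of pipeline SHM calls with reference (e.g. Sanger) calls.

    ``positive`` is the class counted as positive for sensitivity and
    specificity (unmutated by default -- the prognostically adverse class).
    Pearson's r is computed on paired mutation percentages when both maps
    are provided.
    """
    ids = sorted(set(calls) & set(reference))
    if not ids:
        raise ValueError("no shared sample ids between calls and reference")
    tp = sum(1 for i in ids if reference[i] == positive and calls[i] == positive)
    fn = sum(1 for i in ids if reference[i] == positive and calls[i] != positive)
    tn = sum(1 for i in ids if reference[i] != positive and calls[i] != positive)
    fp = sum(1 for i in ids if reference[i] != positive and calls[i] == positive)
    n = len(ids)
    n_agree = tp + tn
    r: Optional[float] = None
    if calls_mutation_percent is not None and reference_mutation_percent is not None:
        shared = sorted(set(calls_mutation_percent) & set(reference_mutation_percent) & set(ids))
        if len(shared) >= 2:
            x = [calls_mutation_percent[i] for i in shared]
            y = [reference_mutation_percent[i] for i in shared]
            r = float(stats.pearsonr(x, y).statistic)
    return ConcordanceResult(
        n=n,
        n_agree=n_agree,
        accuracy=n_agree / n,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        pearson_r=r,
    )


def annotations_to_frame(
    annotations: Sequence[VDJAnnotation],
    tpms: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """AIRR-style table (one decimal on identity, as reported clinically)."""
    tpms = tpms or {}
    rows = []
    for a in annotations:
        rows.append(
            {
                "sequence_id": a.transcript_id,
                "v_call": a.v_call,
                "d_call": a.d_call if a.d_call is not None else "NA",
                "j_call": a.j_call if a.j_call is not None else "NA",
                "productive": a.productive,
                "v_identity": round(a.v_identity_percent, 1),
                "mutation_percent": round(a.mutation_percent, 1),
                "junction": a.junction,
                "tpm": tpms.get(a.transcript_id),
            }
        )
    return pd.DataFrame(rows)
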