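"""Ground-truthed simulator of Ig heavy-chain transcripts and RNA-seq reads.

The generative model mirrors V-D-J recombination and affinity maturation:
one V, one D and one J germline segment are concatenated in order, with
uniform exonucleolytic trimming at the joined ends (V 3', D both ends,
J 5'), untemplated N nucleotides inserted at the V-D and D-J junctions, and
point somatic hypermutation (substitutions only) applied to the V portion,
enriched in CDR intervals when the allele carries a CDR/framework map. A
fixed synthetic constant-region stub is appended so that transcripts extend
past J, as real mRNAs do. Paired-end reads are drawn from normal-length
fragments with uniform substitution sequencing errors.

Every transcript carries a :class:`TruthRecord` from which the emitted
sequence can be reconstructed byte-for-byte, so downstream stages (assembly,
quantification, annotation, classification) are testable without any
external data. All randomness flows from a single mandatory seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import revcomp
from .germline import GermlineAllele, GermlineDB, Segment
from .io import ReadPair, write_fastq_pairs

_BASES = "ACGT"

#: Fixed synthetic constant-region stub (60 nt) appended after J.
CONSTANT_REGION_STUB = (
    "GCCTCCACCAAGGGCCCATCGGTCTTCCCCCTGGCACCCTCCTCCAAGAGCACCTCTGG"
)

#: Codons that do not encode a stop (used to build stop-free V frames).
_SAFE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample.

    Junctional geometry (trim maxima 5 nt, N-insertion maxima 10 nt) follows
    common repertoire conventions; the dominant clone receives ``depth`` read
    pairs (default 1e4, the coverage regime in which assembly of the dominant
    Ig transcript is reliable). ``shm_rate`` is the per-base substitution
    probability on the framework of the V segment; CDR positions mutate at
    ``shm_rate * cdr_multiplier`` (capped at 1). The seed is mandatory: there
    is no wall-clock default.
    """

    seed: int
    v_trim_max: int = 5
    d_trim_max: int = 5
    j_trim_max: int = 5
    n1_max: int = 10
    n2_max: int = 10
    shm_rate: float = 0.05
    cdr_multiplier: float = 3.0
    include_d: float = 0.9
    read_length: int = 75
    mean_fragment: float = 200.0
    sd_fragment: float = 30.0
    depth: int = 10_000
    error_rate: float = 0.001
    n_minor_clones: int = 2
    minor_abundance_log10_span: float = 2.0
    force_productive: bool = True
    constant_region: str = CONSTANT_REGION_STUB
    status_cutoff: float = 98.0

    def __post_init__(self) -> None:
        for name in ("shm_rate", "include_d", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cdr_multiplier < 1.0:
            raise ValueError("cdr_multiplier must be >= 1")
        if self.read_length > self.mean_fragment:
            raise ValueError("read_length must not exceed mean_fragment")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class TruthRecord:
    """Complete generative record of one transcript.

    ``shm_positions`` holds (1-based position on the germline V, germline
    base, mutated base); ``true_mutation_percent`` is 100 * |SHM| over the
    retained V length; ``expected_status`` applies the configured identity
    cutoff to that truth value.
    """

    v_allele: str
    d_allele: Optional[str]
    j_allele: str
    v_trim_3: int
    d_trim_5: int
    d_trim_3: int
    j_trim_5: int
    n1_seq: str
    n2_seq: str
    shm_positions: tuple[tuple[int, str, str], ...]
    true_mutation_percent: float
    expected_status: str


@dataclass(frozen=True)
class SimTranscript:
    id: str
    sequence: str
    truth: TruthRecord


def reconstruct_transcript(db: GermlineDB, truth: TruthRecord, constant_region: str = CONSTANT_REGION_STUB) -> str:
    """Rebuild a transcript sequence from its truth record (invariant: equals
    the emitted ``SimTranscript.sequence`` exactly)."""
    v = db[truth.v_allele].sequence
    v_kept = list(v[: len(v) - truth.v_trim_3])
    for pos1, ref, alt in truth.shm_positions:
        assert v_kept[pos1 - 1] == ref
        v_kept[pos1 - 1] = alt
    parts = ["".join(v_kept), truth.n1_seq]
    if truth.d_allele is not None:
        d = db[truth.d_allele].sequence
        parts.append(d[truth.d_trim_5 : len(d) - truth.d_trim_3])
        parts.append(truth.n2_seq)
    j = db[truth.j_allele].sequence
    parts.append(j[truth.j_trim_5 :])
    parts.append(constant_region)
    return "".join(parts)


# ---------------------------------------------------------------------------
# Synthetic germline fixture database
# ---------------------------------------------------------------------------

_V_NAMES = ("IGHV1-18*01", "IGHV2-70*01", "IGHV3-74*01", "IGHV4-59*01")
_D_NAMES = ("IGHD2-15*01", "IGHD3-10*01", "IGHD5-18*01", "IGHD6-19*01")
_J_NAMES = ("IGHJ3*02", "IGHJ4*02", "IGHJ5*02", "IGHJ6*02")


def synthetic_germline_db(seed: int = 0) -> GermlineDB:
    """Miniature synthetic germline database (4 V, 4 D, 4 J alleles).

    Sequences are random (V alleles stop-free in frame 0, 294 nt; D 12-32 nt;
    J 48-57 nt) and carry IMGT-style names; they are synthetic stand-ins
    generated here, not IMGT downloads. V alleles include a plausible
    CDR/framework map so CDR-enriched SHM can be exercised.
    """
    rng = np.random.default_rng(seed)
    db = GermlineDB()
    cdr_map = (
        ("FR1", 0, 78),
        ("CDR1", 78, 102),
        ("FR2", 102, 153),
        ("CDR2", 153, 177),
        ("FR3", 177, 294),
    )
    for name in _V_NAMES:
        codons = rng.integers(0, len(_SAFE_CODONS), size=98)
        seq = "".join(_SAFE_CODONS[i] for i in codons)
        gene = name.split("*")[0]
        db.add(GermlineAllele(name, gene, Segment.V, seq, cdr_map))
    # D and J fixture alleles avoid stop trinucleotides in every frame, as
    # germline segments selected for expression effectively do; this keeps
    # the productive-rearrangement rejection sampler efficient.
    for name in _D_NAMES:
        length = int(rng.integers(12, 33))
        db.add(GermlineAllele(name, name.split("*")[0], Segment.D, _stop_free_all_frames(rng, length)))
    for name in _J_NAMES:
        length = int(rng.integers(48, 58))
        db.add(GermlineAllele(name, name.split("*")[0], Segment.J, _stop_free_all_frames(rng, length)))
    return db


# ---------------------------------------------------------------------------
# Transcript simulation
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n)) if n else ""


def _stop_free_all_frames(rng: np.random.Generator, length: int) -> str:
    """Random sequence with no stop-codon trinucleotide in any frame."""
    stops = ("TAA", "TAG", "TGA")
    for _ in range(10_000):
        seq = _random_bases(rng, length)
        if not any(seq[i : i + 3] in stops for i in range(length - 2)):
            return seq
    raise RuntimeError("could not draw a stop-free sequence")  # pragma: no cover


def _apply_shm(
    rng: np.random.Generator,
    v_seq: str,
    rate: float,
    cdr_multiplier: float,
    cdr_positions: set[int],
) -> tuple[str, tuple[tuple[int, str, str], ...]]:
    if rate == 0.0:
        return v_seq, ()
    out = list(v_seq)
    hits: list[tuple[int, str, str]] = []
    u = rng.random(len(v_seq))
    for i, ch in enumerate(v_seq):
        p = rate * cdr_multiplier if i in cdr_positions else rate
        if u[i] < min(p, 1.0):
            alt = _BASES[(("ACGT".index(ch)) + 1 + rng.integers(0, 3)) % 4]
            out[i] = alt
            hits.append((i + 1, ch, alt))
    return "".join(out), tuple(hits)


def _is_productive_prefix(seq: str, j_end: int) -> bool:
    """Frame-preserving, stop-free from the V start (frame 0) through J end."""
    if j_end % 3 != 0:
        return False
    prot = str(Seq(seq[:j_end]).translate())
    return "*" not in prot


def simulate_transcript(
    db: GermlineDB,
    cfg: SimConfig,
    rng: np.random.Generator,
    transcript_id: str = "sim_1",
    v_name: Optional[str] = None,
    d_name: Optional[str] = None,
    j_name: Optional[str] = None,
    shm_rate: Optional[float] = None,
) -> SimTranscript:
    """Simulate one recombined, hypermutated transcript.

    Allele names may be pinned for tests; otherwise alleles are drawn
    uniformly. With ``cfg.force_productive`` the junction geometry and SHM
    draw are rejection-sampled (bounded retries) until the rearrangement is
    in frame and stop-free from the V start through the J end.
    """
    db.validate_complete()
    rate = cfg.shm_rate if shm_rate is None else shm_rate

    def pick(seg: Segment, name: Optional[str]) -> GermlineAllele:
        if name is not None:
            return db[name]
        alleles = sorted(db.segment(seg), key=lambda a: a.name)
        return alleles[int(rng.integers(0, len(alleles)))]

    v = pick(Segment.V, v_name)
    j = pick(Segment.J, j_name)
    use_d = rng.random() < cfg.include_d
    d = pick(Segment.D, d_name) if (use_d or d_name is not None) else None

    for _attempt in range(500):
        t_v = int(rng.integers(0, cfg.v_trim_max + 1))
        t_j = int(rng.integers(0, cfg.j_trim_max + 1))
        if len(v.sequence) - t_v < 1 or len(j.sequence) - t_j < 1:
            continue
        if d is not None:
            t_d5 = int(rng.integers(0, cfg.d_trim_max + 1))
            t_d3 = int(rng.integers(0, cfg.d_trim_max + 1))
            if len(d.sequence) - t_d5 - t_d3 < 1:
                continue
            d_kept = d.sequence[t_d5 : len(d.sequence) - t_d3]
            n2 = _random_bases(rng, int(rng.integers(0, cfg.n2_max + 1)))
        else:
            t_d5 = t_d3 = 0
            d_kept = ""
            n2 = ""
        n1 = _random_bases(rng, int(rng.integers(0, cfg.n1_max + 1)))

        v_kept = v.sequence[: len(v.sequence) - t_v]
        mutated_v, shm = _apply_shm(rng, v_kept, rate, cfg.cdr_multiplier, v.cdr_positions())
        core = mutated_v + n1 + d_kept + n2 + j.sequence[t_j:]
        if cfg.force_productive and not _is_productive_prefix(core, len(core)):
            continue
        seq = core + cfg.constant_region
        tmp = 100.0 * len(shm) / len(v_kept)
        status = "unmutated" if (100.0 - tmp) > cfg.status_cutoff else "mutated"
        truth = TruthRecord(
            v_allele=v.name,
            d_allele=d.name if d is not None else None,
            j_allele=j.name,
            v_trim_3=t_v,
            d_trim_5=t_d5,
            d_trim_3=t_d3,
            j_trim_5=t_j,
            n1_seq=n1,
            n2_seq=n2,
            shm_positions=shm,
            true_mutation_percent=tmp,
            expected_status=status,
        )
        return SimTranscript(id=transcript_id, sequence=seq, truth=truth)
    raise RuntimeError(
        "could not simulate a transcript under the configured constraints "
        "(trimming/productivity rejection exhausted)"
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _effective_length(length: int, mean_fragment: float) -> int:
    return max(int(round(length - mean_fragment + 1)), 1)


def simulate_reads(
    transcripts: Sequence[SimTranscript | tuple[str, str]],
    tpms: Sequence[float],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[ReadPair]:
    """Draw paired-end reads from transcripts at the given true abundances.

    Fragment lengths are Normal(mean_fragment, sd_fragment) clamped to
    [read_length, transcript length]; read 2 is the reverse complement of the
    fragment 3' end. Per-transcript pair counts are multinomial with weights
    TPM_i x effective_length_i (fragments start uniformly over the effective
    length), scaled so the top-TPM transcript receives ``cfg.depth`` pairs in
    expectation. Read names encode transcript of origin, fragment start and
    fragment length (``tid|start|flen|index``) for oracle tests.
    """
    items: list[tuple[str, str]] = []
    for t in transcripts:
        tid, seq = (t.id, t.sequence) if isinstance(t, SimTranscript) else t
        items.append((tid, seq))
    if not items:
        raise ValueError("at least one transcript required")
    if len(items) != len(tpms):
        raise ValueError("transcripts and tpms must align")

    rl = cfg.read_length
    usable: list[tuple[str, str, float]] = []
    for (tid, seq), tpm in zip(items, tpms):
        if len(seq) < rl:
            warnings.warn(f"transcript {tid} shorter than read_length; skipped")
            continue
        usable.append((tid, seq, float(tpm)))
    if not usable:
        return []

    weights = np.array([tpm * _effective_length(len(seq), cfg.mean_fragment) for _, seq, tpm in usable])
    if weights.sum() == 0:
        return []
    dom = int(np.argmax([tpm for _, _, tpm in usable]))
    total = int(round(cfg.depth * weights.sum() / weights[dom]))
    counts = rng.multinomial(total, weights / weights.sum()) if len(usable) > 1 else np.array([total])

    q = chr(30 + 33)
    pairs: list[ReadPair] = []
    for (tid, seq, _tpm), c in zip(usable, counts):
        L = len(seq)
        if c == 0:
            continue
        flens = np.clip(
            np.rint(rng.normal(cfg.mean_fragment, cfg.sd_fragment, size=c)).astype(int),
            rl,
            L,
        )
        starts = rng.integers(0, L - flens + 1)
        err = rng.random((c, 2 * rl)) < cfg.error_rate
        err_alt = rng.integers(1, 4, size=(c, 2 * rl))
        for i in range(c):
            s, f = int(starts[i]), int(flens[i])
            r1 = seq[s : s + rl]
            r2 = revcomp(seq[s + f - rl : s + f])
            if err[i].any():
                r1l, r2l = list(r1), list(r2)
                for pos in np.nonzero(err[i])[0]:
                    target = r1l if pos < rl else r2l
                    p = int(pos) % rl
                    target[p] = _BASES[(_BASES.index(target[p]) + int(err_alt[i, pos])) % 4]
                r1, r2 = "".join(r1l), "".join(r2l)
            pairs.append(ReadPair(f"{tid}|{s}|{f}|{i}", r1, q * rl, r2, q * rl))
    return pairs


# ---------------------------------------------------------------------------
# Whole-sample simulation
# ---------------------------------------------------------------------------


@dataclass
class SimSample:
    """One simulated sample: transcripts with truth, true TPMs and reads.

    Transcript 0 is the dominant clone."""

    transcripts: list[SimTranscript]
    tpms: list[float]
    reads: list[ReadPair]

    @property
    def dominant(self) -> SimTranscript:
        return self.transcripts[0]

    def truth_dict(self) -> dict:
        return {
            "transcripts": [
                {"id": t.id, "sequence": t.sequence, "tpm": tpm, **asdict(t.truth)}
                for t, tpm in zip(self.transcripts, self.tpms)
            ]
        }

    def write(self, outdir: str | Path, prefix: str = "sample") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fq1 = outdir / f"{prefix}_1.fastq"
        fq2 = outdir / f"{prefix}_2.fastq"
        truth = outdir / f"{prefix}.truth.json"
        write_fastq_pairs(self.reads, fq1, fq2)
        truth.write_text(json.dumps(self.truth_dict(), indent=1, sort_keys=True))
        return {"fastq1": fq1, "fastq2": fq2, "truth": truth}


def simulate_sample(db: GermlineDB, cfg: SimConfig) -> SimSample:
    """Simulate a clonally dominated sample: one dominant clone at ``depth``
    read pairs plus ``n_minor_clones`` minor clones with TPMs spread evenly
    down to ``minor_abundance_log10_span`` log10 below the dominant.

    Clones draw distinct V/D/J alleles while the database allows it, so each
    rearrangement assembles into its own contig.
    """
    rng = np.random.default_rng(cfg.seed)
    n_clones = 1 + cfg.n_minor_clones

    def sample_names(seg: Segment) -> list[Optional[str]]:
        names = sorted(a.name for a in db.segment(seg))
        if len(names) >= n_clones:
            idx = rng.permutation(len(names))[:n_clones]
            return [names[i] for i in idx]
        warnings.warn(f"fewer {seg.value} alleles than clones; sampling with replacement")
        return [names[int(rng.integers(0, len(names)))] for _ in range(n_clones)]

    v_names = sample_names(Segment.V)
    d_names = sample_names(Segment.D)
    j_names = sample_names(Segment.J)

    transcripts = [
        simulate_transcript(
            db, cfg, rng, transcript_id=f"clone_{i}", v_name=v_names[i], d_name=d_names[i], j_name=j_names[i]
        )
        for i in range(n_clones)
    ]
    weights = [1.0] + [
        10.0 ** (-cfg.minor_abundance_log10_span * i / max(cfg.n_minor_clones, 1))
        for i in range(1, n_clones)
    ]
    total = sum(weights)
    tpms = [1e6 * w / total for w in weights]
    reads = simulate_reads(transcripts, tpms, cfg, rng)
    return SimSample(transcripts=transcripts, tpms=tpms, reads=reads)
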