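import numpy as np
import pytest
from scipy import stats

from igrec.io import ReadPair
from igrec.align import revcomp
from igrec.simulate import (
    SimConfig,
    reconstruct_transcript,
    simulate_reads,
    simulate_sample,
    simulate_transcript,
)


def _identity_cfg(**kw):
    base = dict(
        seed=0,
        v_trim_max=0,
        d_trim_max=0,
        j_trim_max=0,
        n1_max=0,
        n2_max=0,
        shm_rate=0.0,
        include_d=1.0,
        error_rate=0.0,
        force_productive=False,
    )
    base.update(kw)
    return SimConfig(**base)


def test_identity_configuration_is_exact_concatenation(db, rng):
    cfg = _identity_cfg()
    t = simulate_transcript(db, cfg, rng, v_name="IGHV3-74*01", d_name="IGHD5-18*01", j_name="IGHJ6*02")
    v = db["IGHV3-74*01"].sequence
    d = db["IGHD5-18*01"].sequence
    j = db["IGHJ6*02"].sequence
    assert t.sequence == v + d + j + cfg.constant_region
    assert t.truth.true_mutation_percent == 0.0
    assert t.truth.shm_positions == ()


def test_same_seed_same_config_byte_identical(db):
    cfg = SimConfig(seed=42)
    a = simulate_sample(db, cfg)
    b = simulate_sample(db, cfg)
    assert [t.sequence for t in a.transcripts] == [t.sequence for t in b.transcripts]
    assert a.reads == b.reads
    assert a.tpms == b.tpms


def test_truth_record_reconstructs_sequence(db):
    for seed in range(10):
        sample = simulate_sample(db, SimConfig(seed=seed, shm_rate=0.06))
        for t in sample.transcripts:
            assert reconstruct_transcript(db, t.truth) == t.sequence


def test_shm_count_matches_binomial_expectation(db):
    """At rate 0.054 on the (uniform-rate) V segment, the pooled mutation
    count over 200 draws must fall inside the 99% binomial CI."""
    v_len = len(db["IGHV3-74*01"].sequence)
    cfg = _identity_cfg(shm_rate=0.054, cdr_multiplier=1.0)
    total = 0
    n_draws = 200
    rng = np.random.default_rng(2024)
    for _ in range(n_draws):
        t = simulate_transcript(db, cfg, rng, v_name="IGHV3-74*01")
        total += len(t.truth.shm_positions)
    n = n_draws * v_len
    mean = n * 0.054
    sd = np.sqrt(n * 0.054 * 0.946)
    z = stats.norm.ppf(0.995)
    assert mean - z * sd <= total <= mean + z * sd


def test_cdr_enrichment_when_multiplier_above_one(db, rng):
    """SHM density inside CDR intervals must exceed framework density."""
    allele = db["IGHV1-18*01"]
    cdr = allele.cdr_positions()
    n_cdr = len(cdr)
    n_fr = len(allele.sequence) - n_cdr
    cfg = _identity_cfg(shm_rate=0.02, cdr_multiplier=4.0)
    cdr_hits = fr_hits = 0
    for _ in range(100):
        t = simulate_transcript(db, cfg, rng, v_name=allele.name)
        for pos1, _, _ in t.truth.shm_positions:
            if pos1 - 1 in cdr:
                cdr_hits += 1
            else:
                fr_hits += 1
    # one-sided binomial test: under uniform rates, P(hit in CDR) = n_cdr/len
    p_null = n_cdr / (n_cdr + n_fr)
    res = stats.binomtest(cdr_hits, cdr_hits + fr_hits, p_null, alternative="greater")
    assert res.pvalue < 1e-6


def test_empirical_shm_rate_converges(db):
    """Law of large numbers: pooled per-base rate within 3 sigma of target."""
    cfg = _identity_cfg(shm_rate=0.03, cdr_multiplier=1.0)
    rng = np.random.default_rng(99)
    v_len = len(db["IGHV2-70*01"].sequence)
    hits = 0
    n_draws = 300
    for _ in range(n_draws):
        t = simulate_transcript(db, cfg, rng, v_name="IGHV2-70*01")
        hits += len(t.truth.shm_positions)
    n = n_draws * v_len
    assert abs(hits - n * 0.03) <= 3 * np.sqrt(n * 0.03 * 0.97)


def test_single_transcript_depth_and_containment(db, rng):
    cfg = _identity_cfg(depth=1000)
    t = simulate_transcript(db, cfg, rng)
    reads = simulate_reads([t], [1e6], cfg, rng)
    assert len(reads) == 1000
    for r in reads:
        assert r.seq1 in t.sequence
        assert revcomp(r.seq2) in t.sequence


def test_error_free_reads_match_source_exactly(db, rng):
    cfg = _identity_cfg(depth=200)
    t = simulate_transcript(db, cfg, rng)
    for r in simulate_reads([t], [1e6], cfg, rng):
        tid, start, flen, _ = r.name.split("|")
        s, f = int(start), int(flen)
        assert r.seq1 == t.sequence[s : s + cfg.read_length]
        assert r.seq2 == revcomp(t.sequence[s + f - cfg.read_length : s + f])


def test_two_transcript_ratio_within_multinomial_ci(db, rng):
    """Equal-length transcripts at 9:1 TPM: pair counts split 9:1 within a
    99% CI."""
    cfg = _identity_cfg(depth=1000)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    seq2 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    reads = simulate_reads([("a", seq), ("b", seq2)], [9e5, 1e5], cfg, rng)
    n_a = sum(1 for r in reads if r.name.startswith("a|"))
    n = len(reads)
    sd = np.sqrt(n * 0.9 * 0.1)
    assert abs(n_a - 0.9 * n) <= stats.norm.ppf(0.995) * sd


def test_short_transcript_skipped_with_warning(db, rng):
    cfg = _identity_cfg(depth=10)
    with pytest.warns(UserWarning, match="shorter than read_length"):
        reads = simulate_reads([("tiny", "ACGT")], [1e6], cfg, rng)
    assert reads == []


def test_seed_is_mandatory():
    with pytest.raises(TypeError):
        SimConfig()  # type: ignore[call-arg]


def test_sample_write_roundtrip(db, tmp_path):
    sample = simulate_sample(db, SimConfig(seed=7, depth=200))
    paths = sample.write(tmp_path)
    from igrec.io import read_fastq_pairs

    pairs = read_fastq_pairs(paths["fastq1"], paths["fastq2"])
    assert len(pairs) == len(sample.reads)
    assert pairs[0].seq1 == sample.reads[0].seq1
    assert paths["truth"].exists()
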