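import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igrec.annotate import annotate
from igrec.quant import AbundanceRecord
from igrec.report import (
    MUTATED,
    UNMUTATED,
    build_sample_report,
    classify_shm,
    concordance,
    group_clonotypes,
    is_borderline,
)
from igrec.simulate import SimConfig, simulate_sample, simulate_transcript


def test_classification_rule_and_boundary():
    assert classify_shm(99.7) == UNMUTATED  # 0.3% mutation
    assert classify_shm(94.6) == MUTATED  # 5.4% mutation
    assert classify_shm(98.0) == MUTATED  # strict '>' at the cutoff
    assert is_borderline(98.0)
    assert classify_shm(98.0, inclusive=True) == UNMUTATED
    assert not is_borderline(99.0)
    with pytest.raises(ValueError):
        classify_shm(101.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=0, max_value=100),
    b=st.floats(min_value=0, max_value=100),
)
def test_classification_is_monotone(a, b):
    """Higher identity never flips towards 'mutated' relative to lower."""
    hi, lo = max(a, b), min(a, b)
    if classify_shm(hi) == MUTATED:
        assert classify_shm(lo) == MUTATED


def _annotations_for(db, layouts):
    """Build annotations from constructed contigs: layout = (id, v, d, j, n1)."""
    anns = []
    for cid, v_name, d_name, j_name, n1 in layouts:
        v = db[v_name].sequence
        d = db[d_name].sequence if d_name else ""
        j = db[j_name].sequence
        a = annotate((cid, v + n1 + d + j), db)
        assert a is not None and a.complete
        anns.append(a)
    return anns


def test_clonotype_grouping_exact_key(db):
    anns = _annotations_for(
        db,
        [
            ("t1", "IGHV1-18*01", "IGHD2-15*01", "IGHJ3*02", "TTTTTT"),
            ("t2", "IGHV1-18*01", "IGHD2-15*01", "IGHJ3*02", "TTTTTT"),
            ("t3", "IGHV1-18*01", "IGHD2-15*01", "IGHJ3*02", "TTTTTA"),
            ("t4", "IGHV2-70*01", "IGHD3-10*01", "IGHJ4*02", "CCCC"),
        ],
    )
    clonotypes = group_clonotypes(anns, {"t1": 100.0, "t2": 50.0, "t3": 10.0, "t4": 5.0})
    assert len(clonotypes) == 3
    top = clonotypes[0]
    assert top.member_transcripts == ("t1", "t2")
    assert top.summed_tpm == 150.0
    # every transcript belongs to exactly one clonotype
    members = [tid for c in clonotypes for tid in c.member_transcripts]
    assert sorted(members) == ["t1", "t2", "t3", "t4"]


def test_clonotype_recovery_from_simulated_sample(db):
    sample = simulate_sample(db, SimConfig(seed=21, error_rate=0.0, depth=500))
    anns = [annotate((t.id, t.sequence), db) for t in sample.transcripts]
    clonotypes = group_clonotypes([a for a in anns if a and a.complete])
    assert len(clonotypes) == len(sample.transcripts)


def test_sample_report_counts_and_status(db):
    anns = _annotations_for(
        db,
        [
            ("t1", "IGHV1-18*01", "IGHD2-15*01", "IGHJ3*02", "TTTTTT"),
            ("t2", "IGHV1-18*01", "IGHD2-15*01", "IGHJ3*02", "TTTTTT"),
            ("t3", "IGHV1-18*01", "IGHD2-15*01", "IGHJ3*02", "TTTTTA"),
            ("t4", "IGHV2-70*01", "IGHD3-10*01", "IGHJ4*02", "CCCC"),
            ("t5", "IGHV3-74*01", "IGHD5-18*01", "IGHJ6*02", "GG"),
        ],
    )
    records = [AbundanceRecord(f"t{i}", 10, 100, tpm) for i, tpm in
               [(1, 5e5), (2, 2e5), (3, 1e5), (4, 1e5), (5, 1e5)]]
    report = build_sample_report("s1", anns, records)
    assert report.status == "ok"
    assert report.n_ig_transcripts == 5
    assert report.n_clonotypes == 4
    assert report.n_clonotypes <= report.n_ig_transcripts
    assert report.shm_status == UNMUTATED  # germline-identical dominant
    assert report.mutation_percent == pytest.approx(0.0)
    assert set(report.colisted_transcripts) == {"t1", "t2", "t3", "t4", "t5"}


def test_empty_screen_yields_sentinel_report():
    report = build_sample_report("s_empty", [], [])
    assert report.status == "no_ig_transcript"
    assert report.shm_status is None


def test_concordance_perfect_agreement():
    calls = {f"s{i}": UNMUTATED if i % 2 else MUTATED for i in range(16)}
    res = concordance(calls, dict(calls))
    assert (res.n, res.n_agree) == (16, 16)
    assert res.accuracy == 1.0
    assert res.sensitivity == 1.0
    assert res.specificity == 1.0


def test_concordance_constructed_cohort():
    """TP=14, TN=36, FP=1, FN=0 with 'unmutated' positive: sensitivity 1.0,
    specificity 36/37, accuracy 50/51."""
    reference = {}
    calls = {}
    for i in range(14):
        reference[f"u{i}"] = UNMUTATED
        calls[f"u{i}"] = UNMUTATED
    for i in range(36):
        reference[f"m{i}"] = MUTATED
        calls[f"m{i}"] = MUTATED
    reference["fp"] = MUTATED
    calls["fp"] = UNMUTATED
    res = concordance(calls, reference)
    assert res.n == 51
    assert res.n_agree == 50
    assert res.sensitivity == pytest.approx(1.0)
    assert res.specificity == pytest.approx(36 / 37, abs=1e-9)
    assert round(res.specificity, 3) == 0.973
    assert res.accuracy == pytest.approx(50 / 51)


def test_concordance_pearson_on_identical_vectors():
    calls = {"a": MUTATED, "b": UNMUTATED, "c": MUTATED}
    pct = {"a": 5.4, "b": 0.3, "c": 8.8}
    res = concordance(calls, dict(calls), pct, dict(pct))
    assert res.pearson_r == pytest.approx(1.0)


def test_concordance_disjoint_ids_is_error():
    with pytest.raises(ValueError):
        concordance({"a": MUTATED}, {"b": MUTATED})


def test_end_to_end_status_recovery_small_cohort(db):
    """Simulated uCLL/mCLL samples classified correctly from the true
    transcripts (annotation + abundance route)."""
    from igrec.quant import quantify_tpm
    from igrec.assemble import Contig

    rates = [0.001, 0.003, 0.05, 0.08]
    for i, rate in enumerate(rates):
        sample = simulate_sample(db, SimConfig(seed=100 + i, shm_rate=rate, depth=1000))
        contigs = [Contig(t.id, t.sequence, 1.0, 0) for t in sample.transcripts]
        records = quantify_tpm(contigs, sample.reads)
        anns = [annotate((t.id, t.sequence), db) for t in sample.transcripts]
        report = build_sample_report(f"s{i}", [a for a in anns if a], records)
        assert report.shm_status == sample.dominant.truth.expected_status
        assert report.mutation_percent == pytest.approx(
            sample.dominant.truth.true_mutation_percent, abs=0.5
        )
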