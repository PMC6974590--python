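"""QC chain: per-stage behaviour, boundaries, idempotence."""

from __future__ import annotations

import numpy as np
import pytest

from cnvburden.qc_filter import (
    QcConfig,
    exclude_outlier_samples,
    filter_blacklist,
    filter_probes,
    filter_rare,
    filter_size,
    run_qc,
)
from cnvburden.types import CnvCall, CnvType, GeneModel, SampleRecord, Sex, Status


def _call(sample, chrom, start, end, cnv_type=CnvType.GAIN, probes=60, cohort="A"):
    return CnvCall(sample, cohort, chrom, start, end, cnv_type, probes)


def _sample(sid, cohort="A", status=Status.CONTROL):
    return SampleRecord(sid, cohort, status, Sex.FEMALE, 50.0, 25.0)


# ---------------------------------------------------------------------------
# size
# ---------------------------------------------------------------------------

def test_size_filter_is_strictly_greater():
    calls = [
        _call("S1", "chr1", 0, 100_000),       # exactly 100 kb: removed
        _call("S2", "chr1", 0, 100_001),       # one base over: kept
        _call("S3", "chr1", 0, 99_999),
    ]
    kept = filter_size(calls, 100_000)
    assert [c.sample_id for c in kept] == ["S2"]


def test_size_filter_empty_input():
    assert filter_size([], 100_000) == []


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

def test_probe_filter_boundary_and_per_cohort_threshold():
    cfg = QcConfig(min_probes={"SHIP-2": 100})
    calls = [
        _call("S1", "chr1", 0, 200_000, probes=49),                  # below 50
        _call("S2", "chr1", 0, 200_000, probes=50),                  # at 50: kept
        _call("S3", "chr1", 0, 200_000, probes=99, cohort="SHIP-2"),
        _call("S4", "chr1", 0, 200_000, probes=100, cohort="SHIP-2"),
    ]
    kept = filter_probes(calls, cfg)
    assert [c.sample_id for c in kept] == ["S2", "S4"]


# ---------------------------------------------------------------------------
# blacklist
# ---------------------------------------------------------------------------

def test_blacklist_single_base_overlap_removes_but_abutment_keeps():
    bl = [GeneModel("B", "chr1", 1000, 2000)]
    calls = [
        _call("S1", "chr1", 1999, 300_000),   # 1 bp overlap: removed
        _call("S2", "chr1", 2000, 300_000),   # abuts: kept
        _call("S3", "chr1", 500, 1000),       # abuts on the left: kept
        _call("S4", "chr2", 1000, 2000),      # other chromosome: kept
    ]
    kept = filter_blacklist(calls, bl)
    assert [c.sample_id for c in kept] == ["S2", "S3", "S4"]


def test_blacklist_empty_is_identity():
    calls = [_call("S1", "chr1", 0, 200_000)]
    assert filter_blacklist(calls, []) == calls


# ---------------------------------------------------------------------------
# outlier samples
# ---------------------------------------------------------------------------

def test_outlier_uses_population_sd_single_pass():
    """Counts [0,0,0,0,20]: mean 4, population SD 8, cutoff at 3 SD is 28 —
    the 20-call sample survives."""
    samples = [_sample(f"S{i}") for i in range(5)]
    calls = [_call("S4", "chr1", i * 1_000_000, i * 1_000_000 + 200_000)
             for i in range(20)]
    retained, excluded = exclude_outlier_samples(calls, samples, 3.0)
    assert excluded == {}
    assert len(retained) == 5


def test_outlier_sd_is_population_not_sample():
    """Counts [0]*9 + [9]: mean 0.9, population SD 2.7 (cutoff at 2.85 SD
    = 8.595 < 9 → excluded) while the sample SD 2.846 would give cutoff
    9.011 > 9 → kept. Discriminates the SD convention exactly."""
    samples = [_sample(f"S{i}") for i in range(10)]
    calls = [_call("S9", "chr1", i * 1_000_000, i * 1_000_000 + 200_000)
             for i in range(9)]
    retained, excluded = exclude_outlier_samples(calls, samples, 2.85)
    assert set(excluded) == {"S9"}
    assert len(retained) == 9


def test_outlier_all_equal_counts_no_exclusion():
    samples = [_sample(f"S{i}") for i in range(4)]
    calls = [_call(f"S{i}", "chr1", 0, 200_000) for i in range(4)]
    _, excluded = exclude_outlier_samples(calls, samples, 3.0)
    assert excluded == {}


def test_outlier_is_per_cohort_and_upper_only():
    samples = [_sample(f"A{i}", "A") for i in range(10)]
    samples += [_sample(f"B{i}", "B") for i in range(10)]
    # cohort A: one sample with 30 calls among singletons -> excluded there;
    # cohort B: everyone quiet -> untouched by A's outlier.
    calls = [_call(f"A{i}", "chr1", 0, 200_000, cohort="A") for i in range(9)]
    calls += [_call("A9", "chr1", i * 1_000_000, i * 1_000_000 + 200_000,
                    cohort="A") for i in range(30)]
    calls += [_call("B0", "chr1", 0, 200_000, cohort="B")]
    _, excluded = exclude_outlier_samples(calls, samples, 3.0)
    assert set(excluded) == {"A9"}


def test_outlier_tiny_cohort_skipped_with_warning(caplog):
    samples = [_sample("S1", "LONE")]
    with caplog.at_level("WARNING"):
        retained, excluded = exclude_outlier_samples([], samples, 3.0)
    assert retained == samples and excluded == {}
    assert any("<2 samples" in r.message for r in caplog.records)


def test_outlier_detects_injected_outlier_in_simulated_cohort():
    rng = np.random.default_rng(42)
    samples = [_sample(f"S{i}") for i in range(500)]
    calls = []
    for s in samples[:-1]:
        for _ in range(rng.poisson(0.5)):
            start = int(rng.integers(0, 5_000_000))
            calls.append(_call(s.sample_id, "chr1", start, start + 200_000))
    for j in range(25):  # ~10x the Poisson mean
        calls.append(_call("S499", "chr1", j * 1_000_000, j * 1_000_000 + 200_000))
    _, excluded = exclude_outlier_samples(calls, samples, 3.0)
    assert set(excluded) == {"S499"}


# ---------------------------------------------------------------------------
# rarity
# ---------------------------------------------------------------------------

def _cohort(n):
    return [_sample(f"S{i}") for i in range(n)]


def test_rare_filter_removes_common_region_keeps_singleton():
    samples = _cohort(100)
    common = [_call(f"S{i}", "chr1", 1_000_000, 1_200_000) for i in range(3)]
    single = [_call("S50", "chr2", 1_000_000, 1_200_000)]
    kept, regions = filter_rare(common + single, samples, QcConfig())
    assert [c.sample_id for c in kept] == ["S50"]
    row = regions[regions["chrom"] == "chr2"].iloc[0]
    assert bool(row["singleton"]) and not bool(row["removed"])
    assert row["frequency"] == pytest.approx(0.01)  # 1/100 == threshold: kept


def test_rare_filter_threshold_is_strictly_greater():
    samples = _cohort(100)
    # exactly 1% (1 carrier of 100) is kept; 2% is removed
    kept, _ = filter_rare(
        [_call("S1", "chr1", 0, 200_000), _call("S2", "chr1", 0, 200_000)],
        samples, QcConfig(),
    )
    assert kept == []


def test_rare_filter_reciprocal_overlap_boundary():
    """Two 200 kb calls shifted by exactly 100 kb have reciprocal overlap
    exactly 0.5 — at the >= threshold they cluster into one region."""
    samples = _cohort(100)
    a = _call("S1", "chr1", 0, 200_000)
    b = _call("S2", "chr1", 100_000, 300_000)
    _, regions = filter_rare([a, b], samples, QcConfig())
    assert len(regions) == 1
    assert regions.iloc[0]["n_carriers"] == 2
    # one base less of overlap and they are separate regions
    b2 = _call("S2", "chr1", 100_001, 300_001)
    _, regions2 = filter_rare([a, b2], samples, QcConfig())
    assert len(regions2) == 2


def test_rare_filter_single_linkage_chains():
    """A-B and B-C overlap >= 50% pairwise but A-C do not; single linkage
    still merges all three into one region."""
    samples = _cohort(100)
    a = _call("S1", "chr1", 0, 200_000)
    b = _call("S2", "chr1", 80_000, 280_000)
    c = _call("S3", "chr1", 160_000, 360_000)
    _, regions = filter_rare([a, b, c], samples, QcConfig())
    assert len(regions) == 1 and regions.iloc[0]["n_carriers"] == 3


def test_rare_filter_types_do_not_mix():
    samples = _cohort(100)
    g = _call("S1", "chr1", 0, 200_000, CnvType.GAIN)
    l = _call("S2", "chr1", 0, 200_000, CnvType.LOSS)
    _, regions = filter_rare([g, l], samples, QcConfig())
    assert len(regions) == 2
    assert set(regions["cnv_type"]) == {"GAIN", "LOSS"}


def test_rare_filter_frequency_counts_carriers_not_calls():
    samples = _cohort(100)
    # one sample with two identical calls: 1 carrier -> kept at 1%
    calls = [_call("S1", "chr1", 0, 200_000), _call("S1", "chr1", 0, 200_000)]
    kept, regions = filter_rare(calls, samples, QcConfig())
    assert len(kept) == 2
    assert regions.iloc[0]["n_carriers"] == 1 and regions.iloc[0]["n_calls"] == 2


# ---------------------------------------------------------------------------
# full chain on the hand fixture
# ---------------------------------------------------------------------------

def test_hand_fixture_stage_counts(hand_qc_result):
    kept, kept_samples, report = hand_qc_result
    assert report.stage_counts == {
        "input": 13,
        "after_size": 11,
        "after_probes": 10,
        "after_blacklist": 9,
        "after_outlier_samples": 9,
        "after_rarity": 6,
    }
    assert report.excluded_samples == {}
    assert len(kept_samples) == 6
    assert report.per_cohort_type_counts == {"TOY": {"GAIN": 3, "LOSS": 3}}


def test_chain_is_idempotent(hand_qc_result, hand_qc_config):
    kept, kept_samples, _ = hand_qc_result
    again, again_samples, report = run_qc(kept, kept_samples, hand_qc_config)
    assert again == kept
    assert again_samples == kept_samples
    assert len(set(report.stage_counts.values())) == 1  # nothing removed


def test_stage_counts_monotone_nonincreasing(hand_qc_result):
    _, _, report = hand_qc_result
    counts = list(report.stage_counts.values())
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_config_validation():
    with pytest.raises(ValueError):
        QcConfig(min_size_bp=0)
    with pytest.raises(ValueError):
        QcConfig(max_frequency=0.0)
    with pytest.raises(ValueError):
        QcConfig(outlier_sd=-1)
    with pytest.raises(ValueError):
        QcConfig(reciprocal_overlap=1.5)
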