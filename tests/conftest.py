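"""Shared fixtures, including a fully hand-enumerable toy dataset.

The hand dataset is constructed so every QC stage count, carrier table and
candidate-chain count can be verified on paper:

Genes (0-based half-open), 50 kb each:
    G_A chr1 1,000,000   G_B chr1 2,000,000   G_C chr1 3,000,000
    G_D chr2 1,000,000   G_E chr2 2,000,000   G_F chr2 3,000,000
Sets: lipid = {A,B,C,D}; small_intestine = {B,C,D,E}; random = {F}.
Samples (cohort TOY): cases S1 (M), S2 (F), S3 (F);
                      controls S4 (M), S5 (F), S6 (F).

Calls and their planned QC fates (blacklist chr1 9,000,000–9,010,000;
min size 100 kb strict, min probes 50, outlier SD 3, max frequency 0.40):

    c1  S1 LOSS chr1 1,990,000–2,140,000 p60  keep → hits G_B
    c2  S2 GAIN chr1 3,000,000–3,200,000 p55  keep → hits G_C
    c3  S4 GAIN chr1 3,010,000–3,220,000 p70  keep → hits G_C
    c4  S3 LOSS chr2   990,000–1,140,000 p52  keep → hits G_D
    c5  S5 LOSS chr2   990,000–1,140,000 p52  keep → hits G_D
    c6  S6 GAIN chr2 2,000,000–2,150,000 p80  keep → hits G_E
    c7  S1 GAIN chr1   500,000–  590,000 p60  size 90,000 → size stage
    c8  S2 LOSS chr1   700,000–  800,000 p60  size exactly 100,000 → size stage
    c9  S3 LOSS chr2 5,000,000–5,200,000 p49  → probe stage
    c10 S4 GAIN chr1 8,950,000–9,100,000 p60  → blacklist stage
    c11 S1 GAIN chr2 6,000,000–6,200,000 p60 ┐ identical region, 3 carriers
    c12 S2 GAIN chr2 6,000,000–6,200,000 p60 │ of 6 samples = 0.5 > 0.40
    c13 S5 GAIN chr2 6,000,000–6,200,000 p60 ┘ → rarity stage

Stage counts: 13 → 11 → 10 → 9 → 9 (no outliers: counts [2,2,1,1,2,1],
mean 1.5, population SD 0.5, cutoff 3.0) → 6.
"""

from __future__ import annotations

import pytest

from cnvburden.overlap_annot import annotate_calls, build_gene_index
from cnvburden.qc_filter import QcConfig, run_qc
from cnvburden.types import (
    CnvCall,
    CnvType,
    GeneModel,
    GeneSetCollection,
    SampleRecord,
    Sex,
    Status,
)


def _call(sample, chrom, start, end, cnv_type, probes):
    return CnvCall(
        sample_id=sample, cohort="TOY", chrom=chrom, start=start, end=end,
        cnv_type=cnv_type, n_probes=probes,
    )


@pytest.fixture()
def hand_genes() -> list[GeneModel]:
    spans = [
        ("G_A", "chr1", 1_000_000), ("G_B", "chr1", 2_000_000),
        ("G_C", "chr1", 3_000_000), ("G_D", "chr2", 1_000_000),
        ("G_E", "chr2", 2_000_000), ("G_F", "chr2", 3_000_000),
    ]
    return [GeneModel(g, c, s, s + 50_000) for g, c, s in spans]


@pytest.fixture()
def hand_sets() -> GeneSetCollection:
    coll = GeneSetCollection()
    coll.add("lipid", {"G_A", "G_B", "G_C", "G_D"}, "toy lipid")
    coll.add("small_intestine", {"G_B", "G_C", "G_D", "G_E"}, "toy tissue")
    coll.add("random", {"G_F"}, "toy random")
    return coll


@pytest.fixture()
def hand_samples() -> list[SampleRecord]:
    rows = [
        ("S1", Status.CASE, Sex.MALE), ("S2", Status.CASE, Sex.FEMALE),
        ("S3", Status.CASE, Sex.FEMALE), ("S4", Status.CONTROL, Sex.MALE),
        ("S5", Status.CONTROL, Sex.FEMALE), ("S6", Status.CONTROL, Sex.FEMALE),
    ]
    return [
        SampleRecord(sid, "TOY", st, sx, age=50.0, bmi=27.0)
        for sid, st, sx in rows
    ]


@pytest.fixture()
def hand_calls() -> list[CnvCall]:
    G, L = CnvType.GAIN, CnvType.LOSS
    return [
        _call("S1", "chr1", 1_990_000, 2_140_000, L, 60),   # c1
        _call("S2", "chr1", 3_000_000, 3_200_000, G, 55),   # c2
        _call("S4", "chr1", 3_010_000, 3_220_000, G, 70),   # c3
        _call("S3", "chr2", 990_000, 1_140_000, L, 52),     # c4
        _call("S5", "chr2", 990_000, 1_140_000, L, 52),     # c5
        _call("S6", "chr2", 2_000_000, 2_150_000, G, 80),   # c6
        _call("S1", "chr1", 500_000, 590_000, G, 60),       # c7 size-fail
        _call("S2", "chr1", 700_000, 800_000, L, 60),       # c8 size boundary
        _call("S3", "chr2", 5_000_000, 5_200_000, L, 49),   # c9 probe-fail
        _call("S4", "chr1", 8_950_000, 9_100_000, G, 60),   # c10 blacklist
        _call("S1", "chr2", 6_000_000, 6_200_000, G, 60),   # c11 common
        _call("S2", "chr2", 6_000_000, 6_200_000, G, 60),   # c12 common
        _call("S5", "chr2", 6_000_000, 6_200_000, G, 60),   # c13 common
    ]


@pytest.fixture()
def hand_blacklist() -> list[GeneModel]:
    return [GeneModel("BL0", "chr1", 9_000_000, 9_010_000)]


@pytest.fixture()
def hand_qc_config(hand_blacklist) -> QcConfig:
    return QcConfig(max_frequency=0.40, blacklist=hand_blacklist)


@pytest.fixture()
def hand_qc_result(hand_calls, hand_samples, hand_qc_config):
    """(kept_calls, kept_samples, report) after the full QC chain."""
    return run_qc(hand_calls, hand_samples, hand_qc_config)


@pytest.fixture()
def hand_annotated(hand_qc_result, hand_genes, hand_sets):
    kept, kept_samples, _ = hand_qc_result
    index = build_gene_index(hand_genes)
    return annotate_calls(kept, index, hand_sets), kept_samples
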