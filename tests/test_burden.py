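"""Exact 2×2 inference, carrier counting and the burden grid."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from oracles import oracle_fisher_or_ci, oracle_fisher_p
from cnvburden.burden import (
    BurdenResult,
    ContingencyTable,
    bonferroni_alpha,
    burden_frame,
    conditional_mle_or,
    count_carriers,
    exact_or_ci,
    fisher_exact_2x2,
    fisher_exact_batch,
    fisher_p_two_sided,
    format_alpha,
    run_burden,
)
from cnvburden.overlap_annot import annotate_calls, build_gene_index
from cnvburden.types import (
    ANY_SET,
    CnvCall,
    CnvType,
    SampleRecord,
    Sex,
    Status,
    TypeStratum,
)


def _close(x, y, tol=1e-12):
    if math.isnan(x) and math.isnan(y):
        return True
    if math.isinf(x) or math.isinf(y):
        return x == y
    return abs(x - y) <= tol * max(1.0, abs(x), abs(y))


# ---------------------------------------------------------------------------
# exact inference on single tables
# ---------------------------------------------------------------------------

def test_balanced_table_is_null():
    t = ContingencyTable(5, 5, 5, 5)
    p, orr, (lo, hi) = fisher_exact_2x2(t)
    assert p == 1.0
    assert _close(orr, 1.0, 1e-10)
    assert lo < 1.0 < hi


def test_example_table_against_oracle_and_scipy():
    t = ContingencyTable(10, 90, 5, 95)
    p, orr, (lo, hi) = fisher_exact_2x2(t)
    assert _close(p, oracle_fisher_p(10, 90, 5, 95))
    o_or, o_lo, o_hi = oracle_fisher_or_ci(10, 90, 5, 95)
    assert _close(orr, o_or) and _close(lo, o_lo) and _close(hi, o_hi)
    # independent library route
    assert p == pytest.approx(scipy_fisher([[10, 90], [5, 95]]).pvalue, rel=1e-10)
    sp = scipy_odds_ratio([[10, 90], [5, 95]])
    ci = sp.confidence_interval(0.95)
    assert orr == pytest.approx(sp.statistic, rel=1e-9)
    assert lo == pytest.approx(ci.low, rel=1e-9)
    assert hi == pytest.approx(ci.high, rel=1e-9)


def test_zero_cell_conventions():
    # a at the bottom of its support: OR 0, CI low 0
    p, orr, (lo, hi) = fisher_exact_2x2(ContingencyTable(0, 10, 5, 5))
    assert orr == 0.0 and lo == 0.0 and 0 < hi < math.inf
    # a at the top of its support: OR inf, CI high inf
    p2, orr2, (lo2, hi2) = fisher_exact_2x2(ContingencyTable(5, 5, 0, 10))
    assert orr2 == math.inf and hi2 == math.inf and 0 < lo2
    # degenerate support (no controls-carriers possible variation)
    p3, orr3, (lo3, hi3) = fisher_exact_2x2(ContingencyTable(0, 10, 0, 10))
    assert p3 == 1.0 and math.isnan(orr3) and (lo3, hi3) == (0.0, math.inf)


def test_transpose_and_row_swap_invariances():
    rng = np.random.default_rng(23)
    for _ in range(50):
        a, b, c, d = (int(v) for v in rng.integers(0, 25, 4))
        t = ContingencyTable(a, b, c, d)
        p = fisher_p_two_sided(t)
        # transposing the table leaves p and OR unchanged
        tt = ContingencyTable(a, c, b, d)
        assert _close(p, fisher_p_two_sided(tt), 1e-9)
        assert _close(conditional_mle_or(t), conditional_mle_or(tt), 1e-9)
        # swapping rows inverts the OR and mirrors the CI
        sw = ContingencyTable(c, d, a, b)
        o1, o2 = conditional_mle_or(t), conditional_mle_or(sw)
        if 0 < o1 < math.inf:
            assert _close(o2, 1 / o1, 1e-9)
            lo1, hi1 = exact_or_ci(t)
            lo2, hi2 = exact_or_ci(sw)
            assert _close(lo2, 1 / hi1, 1e-8) and _close(hi2, 1 / lo1, 1e-8)


def test_scipy_cross_check_random_tables():
    rng = np.random.default_rng(29)
    for _ in range(100):
        a, b, c, d = (int(v) for v in rng.integers(0, 40, 4))
        p, orr, (lo, hi) = fisher_exact_2x2(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(
            scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-9, abs=1e-12
        )
        sp = scipy_odds_ratio([[a, b], [c, d]])
        if 0 < orr < math.inf:
            assert orr == pytest.approx(sp.statistic, rel=1e-6)


def test_batch_matches_scalar_to_machine_precision():
    rng = np.random.default_rng(31)
    tables = np.vstack([
        rng.integers(0, 4, size=(150, 4)),     # boundary-heavy
        rng.integers(0, 60, size=(150, 4)),    # general
    ])
    res = fisher_exact_batch(tables)
    for i, (a, b, c, d) in enumerate(tables):
        p, orr, (lo, hi) = fisher_exact_2x2(
            ContingencyTable(int(a), int(b), int(c), int(d))
        )
        assert _close(p, res["p"][i])
        assert _close(orr, res["oddsratio"][i])
        assert _close(lo, res["ci_low"][i])
        assert _close(hi, res["ci_high"][i])


def test_negative_cell_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 0, 0, 0)


def test_crude_or():
    assert ContingencyTable(10, 90, 5, 95).crude_or() == pytest.approx(
        (10 * 95) / (90 * 5)
    )
    assert ContingencyTable(1, 0, 1, 1).crude_or() == math.inf
    assert math.isnan(ContingencyTable(0, 0, 1, 1).crude_or())


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def test_bonferroni_values_and_display():
    assert bonferroni_alpha(0.05, 9) == pytest.approx(0.05 / 9)
    assert bonferroni_alpha(0.05, 15) == pytest.approx(0.05 / 15)
    # display truncates, it does not round: 0.005555... -> 0.0055
    assert format_alpha(bonferroni_alpha(0.05, 9)) == "0.0055"
    assert format_alpha(bonferroni_alpha(0.05, 15)) == "0.0033"
    with pytest.raises(ValueError):
        bonferroni_alpha(0.0, 9)
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


# ---------------------------------------------------------------------------
# carrier counting
# ---------------------------------------------------------------------------

def test_count_carriers_hand_tables(hand_annotated, hand_sets):
    annotated, samples = hand_annotated
    assert count_carriers(annotated, samples, ANY_SET) == ContingencyTable(3, 0, 3, 0)
    assert count_carriers(
        annotated, samples, ANY_SET, TypeStratum.GAIN
    ) == ContingencyTable(1, 2, 2, 1)
    assert count_carriers(
        annotated, samples, ANY_SET, TypeStratum.LOSS
    ) == ContingencyTable(2, 1, 1, 2)
    assert count_carriers(
        annotated, samples, "lipid", collection=hand_sets
    ) == ContingencyTable(3, 0, 2, 1)
    assert count_carriers(
        annotated, samples, "small_intestine", collection=hand_sets
    ) == ContingencyTable(3, 0, 3, 0)
    assert count_carriers(
        annotated, samples, "random", collection=hand_sets
    ) == ContingencyTable(0, 3, 0, 3)
    assert count_carriers(
        annotated, samples, "lipid", TypeStratum.GAIN, hand_sets
    ) == ContingencyTable(1, 2, 1, 2)
    assert count_carriers(
        annotated, samples, "lipid", TypeStratum.LOSS, hand_sets
    ) == ContingencyTable(2, 1, 1, 2)


def test_count_carriers_counts_each_sample_once(hand_sets, hand_genes):
    """A sample with three qualifying calls is one carrier."""
    idx = build_gene_index(hand_genes)
    calls = [
        CnvCall("S1", "TOY", "chr1", 1_000_000 + k, 1_200_000 + k,
                CnvType.GAIN, 60)
        for k in range(3)
    ]
    samples = [
        SampleRecord("S1", "TOY", Status.CASE, Sex.MALE, 50, 25),
        SampleRecord("S2", "TOY", Status.CONTROL, Sex.MALE, 50, 25),
    ]
    annotated = annotate_calls(calls, idx, hand_sets)
    assert count_carriers(annotated, samples, "lipid", collection=hand_sets) == \
        ContingencyTable(1, 0, 0, 1)


def test_count_carriers_errors(hand_annotated, hand_sets):
    annotated, samples = hand_annotated
    with pytest.raises(ValueError, match="unknown gene set"):
        count_carriers(annotated, samples, "nope", collection=hand_sets)
    with pytest.raises(ValueError, match="empty stratum"):
        count_carriers(annotated, [], "lipid", collection=hand_sets)


# ---------------------------------------------------------------------------
# burden grid
# ---------------------------------------------------------------------------

def test_run_burden_grid_shape_and_alphas(hand_annotated, hand_sets):
    annotated, samples = hand_annotated
    results = run_burden(annotated, samples, hand_sets)
    # 1 cohort x ("any" + 3 sets) x 3 strata
    assert len(results) == 12
    adj = 0.05 / 4
    for r in results:
        if r.type_stratum is TypeStratum.ANY:
            assert r.alpha_adjusted == pytest.approx(adj)
        else:
            assert r.alpha_adjusted == 0.05
        assert r.significant == (r.p_two_sided < r.alpha_adjusted)


def test_run_burden_matches_count_carriers(hand_annotated, hand_sets):
    annotated, samples = hand_annotated
    results = run_burden(annotated, samples, hand_sets)
    by_key = {(r.set_name, r.type_stratum): r for r in results}
    t = by_key[("lipid", TypeStratum.ANY)].table
    assert (t.a, t.b, t.c, t.d) == (3, 0, 2, 1)
    r = by_key[("lipid", TypeStratum.ANY)]
    p, orr, ci = fisher_exact_2x2(t)
    assert r.p_two_sided == p and r.or_estimate == orr and r.ci95 == ci


def test_run_burden_requires_cases_and_controls(hand_annotated):
    annotated, samples = hand_annotated
    cases_only = [s for s in samples if s.status is Status.CASE]
    from cnvburden.types import GeneSetCollection
    coll = GeneSetCollection()
    coll.add("lipid", {"G_B"}, "")
    with pytest.raises(ValueError, match="cases and controls"):
        run_burden(annotated, cases_only, coll)


def test_identical_profiles_give_null_or():
    """Cases and controls with identical carrier structure: OR at 1, p = 1."""
    samples = [
        SampleRecord(f"S{i}", "A", Status.CASE if i < 10 else Status.CONTROL,
                     Sex.FEMALE, 50, 25)
        for i in range(20)
    ]
    # first 5 of each group are carriers of a gene-free call
    calls = [
        CnvCall(f"S{i}", "A", "chr1", 0, 200_000, CnvType.GAIN, 60)
        for i in list(range(5)) + list(range(10, 15))
    ]
    idx = build_gene_index([])
    from cnvburden.types import GeneSetCollection
    coll = GeneSetCollection()
    coll.add("lipid", {"G_X"}, "")
    annotated = annotate_calls(calls, idx, coll)
    t = count_carriers(annotated, samples, ANY_SET)
    assert (t.a, t.c) == (5, 5)
    p, orr, _ = fisher_exact_2x2(t)
    assert p == 1.0 and _close(orr, 1.0, 1e-9)


def test_burden_frame_columns(hand_annotated, hand_sets):
    annotated, samples = hand_annotated
    frame = burden_frame(run_burden(annotated, samples, hand_sets))
    assert len(frame) == 12
    assert {"cohort", "set", "stratum", "p", "or", "ci_low", "ci_high",
            "significant"} <= set(frame.columns)
    assert set(frame["stratum"]) == {"ANY", "GAIN", "LOSS"}
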