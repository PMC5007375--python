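"""Paired framework: tests, consistency, FDR, enrichment, expression."""

import math

import numpy as np
import pandas as pd
import pytest

from convrates.compare import (
    PairedRateModel,
    bh_fdr,
    classify_consistency,
    enrichment_2x2,
    expression_contrast,
    paired_tests,
    reverse_foreground_filter,
)
from convrates.simulate import simulate_expression_matrix


def _table(design, n=100, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(0.05, 0.01, size=n)
    data = {}
    for m, g in design.pairs:
        data[m] = base + rng.normal(shift, 0.005, size=n)
        data[g] = base + rng.normal(0.0, 0.005, size=n)
    return pd.DataFrame(data)


def test_shifted_pairs_all_significant(design):
    res = paired_tests(_table(design, shift=0.02), design)
    assert (res["fraction_mutualist_greater"] > 0.95).all()
    assert (res["t_p"] < 0.01).all()
    assert (res["t_stat"] > 0).all()


def test_single_unit_errors(design):
    with pytest.raises(ValueError, match="fewer than 2"):
        paired_tests(_table(design, n=1), design)


def test_missing_species_named(design):
    t = _table(design).drop(columns=["pallidus"])
    with pytest.raises(ValueError, match="pallidus"):
        paired_tests(t, design)


def test_invariant_to_unit_level_constants(design):
    t = _table(design, shift=0.01, seed=3)
    res1 = paired_tests(t, design)
    res2 = paired_tests(t.add(np.arange(len(t)) * 0.5, axis=0), design)
    for col in ("t_stat", "t_p", "n_mutualist_greater"):
        assert np.allclose(res1[col], res2[col])


def test_classification_rules(design):
    cols = design.ingroup
    rows = pd.DataFrame(
        [
            dict(zip(cols, [2.0, 1.0, 2.0, 1.0, 2.0, 1.0])),  # all pairs +
            dict(zip(cols, [1.0, 2.0, 1.0, 2.0, 1.0, 2.0])),  # all pairs -
            dict(zip(cols, [2.0, 1.0, 2.0, 1.0, 1.0, 1.0])),  # tie in pair 3
            dict(zip(cols, [2.0, 1.0, 1.0, 2.0, 2.0, 1.0])),  # mixed signs
            dict(zip(cols, [2.0, np.nan, 2.0, 1.0, 2.0, 1.0])),  # incomplete
        ]
    )
    calls, counts = classify_consistency(rows, design)
    assert list(calls["class"]) == [
        "mutualist-faster", "generalist-faster", "inconsistent", "inconsistent",
    ]
    assert counts["n_skipped"] == 1
    assert (counts["mutualist-faster"] + counts["generalist-faster"]
            + counts["inconsistent"]) == counts["n_units"] == 4


def test_bh_fdr_worked_example():
    # step-up thresholds i*q/m = 0.0125, 0.025, 0.0375, 0.05
    adjusted, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert reject.all()
    assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])
    _, none = bh_fdr([1.0, 1.0, 1.0])
    assert not none.any()


def test_bh_fdr_monotone_and_validated(rng):
    p = rng.random(50)
    adjusted, _ = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(adjusted[order]) >= -1e-12).all()
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_reverse_foreground_filter():
    retained, discarded = reverse_foreground_filter({"a", "b", "c"}, {"b", "d"})
    assert retained == {"a", "c"}
    assert discarded == {"b"}
    assert reverse_foreground_filter(set(), {"x"}) == (set(), set())


def test_enrichment_null_and_signal():
    null = enrichment_2x2(10, 20, 100, 200)  # 10/100 vs 10/100
    assert null["odds_ratio"] == pytest.approx(1.0)
    assert null["p"] == pytest.approx(1.0)
    sig = enrichment_2x2(30, 40, 50, 150)  # 30/50 vs 10/100
    assert sig["p"] < 0.001


def test_enrichment_matches_hypergeometric_enumeration():
    """Independent oracle: two-sided Fisher p as the sum of hypergeometric
    point probabilities no larger than the observed table's."""
    a, hits, list_size, universe = 7, 12, 20, 60

    def pmf(x):
        return (math.comb(list_size, x)
                * math.comb(universe - list_size, hits - x)
                / math.comb(universe, hits))

    obs = pmf(a)
    expected = sum(pmf(x) for x in range(max(0, hits - (universe - list_size)),
                                         min(list_size, hits) + 1)
                   if pmf(x) <= obs * (1 + 1e-9))
    got = enrichment_2x2(a, hits, list_size, universe)
    assert got["p"] == pytest.approx(expected)


def test_enrichment_validation_and_continuity():
    with pytest.raises(ValueError):
        enrichment_2x2(30, 20, 25, 100)  # hits in list exceed total hits
    res = enrichment_2x2(0, 5, 10, 100)
    assert res["continuity_corrected"]


def test_expression_rows_standardised_and_signal_detected():
    expr = simulate_expression_matrix(400, fast_gene_ids=list(range(40)),
                                      head_shift=5.0, seed=9)
    fast = list(expr.index[:40])
    out, n_zero = expression_contrast(expr, fast)
    assert n_zero == 0
    head = out[out["tissue"] == "head"].iloc[0]
    assert head["significant"] and head["mean_difference"] > 0


def test_expression_zero_rows_excluded():
    expr = simulate_expression_matrix(50, seed=4)
    expr.iloc[0] = 0.0
    fast = list(expr.index[1:8])
    out, n_zero = expression_contrast(expr, fast)
    assert n_zero == 1
    with pytest.raises(ValueError):
        expression_contrast(expr - 5.0, fast)


def test_model_results_summary(design):
    res = PairedRateModel(_table(design, shift=0.02), design, statistic="dS").fit()
    text = res.summary()
    assert "dS" in text and "consistency classes" in text
    assert res.significant_pairs == 3
    long = pd.DataFrame(
        {
            "gene": ["g1"] * 6,
            "species": design.ingroup,
            "dS": [2.0, 1.0, 2.0, 1.0, 2.0, 1.0],
        }
    )
    model = PairedRateModel.from_long(long, design, "dS")
    assert model.table.loc["g1", "concolor"] == 2.0
    with pytest.raises(ValueError):
        PairedRateModel.from_long(long, design, "nope")
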