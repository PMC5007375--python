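"""The paired mutualist/generalist statistical framework.

Every unit (a gene or a genomic window) contributes one value per species;
each (mutualist, generalist) sister pair is contrasted within units, which
cancels shared history.  Three views are computed per pair: a paired t-test,
a Wilcoxon signed-rank test, and the sign count (fraction of units where
the mutualist value exceeds the generalist's, ties excluded).  A unit is
classified mutualist-faster only when *all* pairs agree in sign (strict
inequalities; any tie breaks consistency), generalist-faster symmetrically,
otherwise inconsistent — under an exchangeable null each directional class
therefore holds (1/2)^n_pairs of the units.

`PairedRateModel` wraps the framework statsmodels-style: build it from a
unit-by-species table and a design, call :meth:`fit`, and read the per-pair
tests, class counts and ``summary()`` off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import PairDesign

__all__ = [
    "paired_tests",
    "classify_consistency",
    "bh_fdr",
    "reverse_foreground_filter",
    "enrichment_2x2",
    "expression_contrast",
    "PairedRateModel",
    "PairedRateResults",
]


def paired_tests(table: pd.DataFrame, design: PairDesign) -> pd.DataFrame:
    """Per-pair paired t, Wilcoxon signed-rank, and sign-count statistics.

    ``table`` has one row per unit and one column per species.  Units
    missing either member of a pair are dropped for that pair; sign counts
    exclude ties.  Raises when fewer than two usable units remain.
    """
    missing = [s for s in design.ingroup if s not in table.columns]
    if missing:
        raise ValueError(f"design species absent from table: {missing}")
    rows = []
    for m, g in design.pairs:
        sub = table[[m, g]].dropna()
        if len(sub) < 2:
            raise ValueError(f"fewer than 2 usable units for pair ({m},{g})")
        x, y = sub[m].to_numpy(float), sub[g].to_numpy(float)
        t_stat, t_p = stats.ttest_rel(x, y)
        d = x - y
        nz = d[d != 0]
        if nz.size:
            w_stat, w_p = stats.wilcoxon(nz, zero_method="wilcox")
        else:
            w_stat, w_p = 0.0, 1.0
        n_pos = int((d > 0).sum())
        n_neg = int((d < 0).sum())
        rows.append(
            {
                "mutualist": m, "generalist": g, "n_units": len(sub),
                "t_stat": float(t_stat), "t_p": float(t_p),
                "wilcoxon_stat": float(w_stat), "wilcoxon_p": float(w_p),
                "n_mutualist_greater": n_pos, "n_generalist_greater": n_neg,
                "fraction_mutualist_greater":
                    n_pos / (n_pos + n_neg) if n_pos + n_neg else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def classify_consistency(
    table: pd.DataFrame, design: PairDesign
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify each unit by the direction of all per-pair differences.

    Units with any missing ingroup value are skipped.  Returns (calls,
    class_counts); calls has per-pair signed differences and the class in
    {mutualist-faster, generalist-faster, inconsistent}.
    """
    missing = [s for s in design.ingroup if s not in table.columns]
    if missing:
        raise ValueError(f"design species absent from table: {missing}")
    complete = table[design.ingroup].dropna()
    diffs = pd.DataFrame(
        {f"{m}-{g}": complete[m] - complete[g] for m, g in design.pairs}
    )
    all_pos = (diffs > 0).all(axis=1)
    all_neg = (diffs < 0).all(axis=1)
    cls = np.where(all_pos, "mutualist-faster",
                   np.where(all_neg, "generalist-faster", "inconsistent"))
    calls = diffs.copy()
    calls["class"] = cls
    counts = {
        "mutualist-faster": int(all_pos.sum()),
        "generalist-faster": int(all_neg.sum()),
        "inconsistent": int(len(calls) - all_pos.sum() - all_neg.sum()),
        "n_units": int(len(calls)),
        "n_skipped": int(len(table) - len(complete)),
    }
    return calls, counts


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p, np.zeros(0, dtype=bool)
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def reverse_foreground_filter(
    forward_significant: set[str], reverse_significant: set[str]
) -> tuple[set[str], set[str]]:
    """Drop hits that are also significant with the foreground reversed.

    Units significant under both foreground choices reflect overall high
    rates rather than foreground-specific selection.  Returns
    (retained, discarded).
    """
    forward = set(forward_significant)
    discarded = forward & set(reverse_significant)
    return forward - discarded, discarded


def enrichment_2x2(
    hits_in_list: int, hits_total: int, list_size: int, universe_size: int
) -> dict[str, float]:
    """Fisher's exact test for over-representation of a gene list.

    2x2 margins: (in list, not in list) x (hit, not hit).  The odds ratio
    falls back to a 0.5 continuity correction when any cell is zero
    (flagged in the result).
    """
    a = hits_in_list
    b = list_size - a
    c = hits_total - a
    d = (universe_size - list_size) - c
    if min(a, b, c, d) < 0 or hits_total > universe_size:
        raise ValueError(f"inconsistent 2x2 margins: {(a, b, c, d)}")
    table = np.array([[a, b], [c, d]])
    _or, p = stats.fisher_exact(table, alternative="two-sided")
    corrected = False
    if (table == 0).any():
        corrected = True
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        odds = (a2 * d2) / (b2 * c2)
    else:
        odds = (a * d) / (b * c)
    return {"odds_ratio": float(odds), "p": float(p),
            "continuity_corrected": corrected}


def expression_contrast(
    expression: pd.DataFrame,
    fast_ids: list[str],
    comparison_ids: list[str] | None = None,
    q: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Per-tissue contrast of a fast-evolving gene set against the rest.

    Each gene row is first standardised to sum one across tissues, so the
    tests compare the *allocation* of expression rather than its level.
    Within each tissue the fast set is compared with the comparison set
    (default: all other genes) by Welch's t-test; p-values are BH-corrected
    across tissues.  All-zero rows cannot be standardised and are excluded
    (their count is the second return value).
    """
    if (expression < 0).any().any():
        raise ValueError("expression matrix must be non-negative")
    totals = expression.sum(axis=1)
    zero = totals == 0
    n_zero = int(zero.sum())
    std = expression.loc[~zero].div(totals[~zero], axis=0)
    fast = [g for g in fast_ids if g in std.index]
    comp = (
        [g for g in comparison_ids if g in std.index]
        if comparison_ids is not None
        else [g for g in std.index if g not in set(fast)]
    )
    rows = []
    for tissue in std.columns:
        x = std.loc[fast, tissue].to_numpy(float)
        y = std.loc[comp, tissue].to_numpy(float)
        t_stat, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {"tissue": tissue, "mean_difference": float(x.mean() - y.mean()),
             "t_stat": float(t_stat), "p": float(p)}
        )
    out = pd.DataFrame(rows)
    adjusted, reject = bh_fdr(out["p"].to_numpy(), q=q)
    out["p_adjusted"] = adjusted
    out["significant"] = reject
    return out, n_zero


# ---------------------------------------------------------------------------
# model/results wrapper


class PairedRateModel:
    """Paired-lineage rate comparison over a unit-by-species value table.

    Parameters
    ----------
    table : DataFrame
        One row per unit (gene or window), one column per species; the
        statistic being compared (dN, dS, dN/dS or genetic distance).
    design : PairDesign
    statistic : str
        Name of the statistic, echoed in results.
    """

    def __init__(self, table: pd.DataFrame, design: PairDesign,
                 statistic: str = "distance"):
        missing = [s for s in design.ingroup if s not in table.columns]
        if missing:
            raise ValueError(f"design species absent from table: {missing}")
        self.table = table
        self.design = design
        self.statistic = statistic

    @classmethod
    def from_long(cls, frame: pd.DataFrame, design: PairDesign,
                  statistic: str, unit_col: str = "gene",
                  species_col: str = "species") -> "PairedRateModel":
        """Build from a long-format table (unit, species, value columns)."""
        if statistic not in frame.columns:
            raise ValueError(f"unknown statistic {statistic!r}")
        wide = frame.pivot_table(index=unit_col, columns=species_col,
                                 values=statistic, aggfunc="first")
        return cls(wide, design, statistic=statistic)

    def fit(self) -> "PairedRateResults":
        tests = paired_tests(self.table, self.design)
        calls, counts = classify_consistency(self.table, self.design)
        return PairedRateResults(model=self, pair_tests=tests,
                                 consistency_calls=calls, class_counts=counts)


@dataclass
class PairedRateResults:
    """Fitted paired-comparison results (tests, classes, summary table)."""

    model: PairedRateModel
    pair_tests: pd.DataFrame
    consistency_calls: pd.DataFrame
    class_counts: dict[str, int]

    @property
    def significant_pairs(self) -> int:
        """Pairs with paired-t p < 0.01 and the mutualist faster on average."""
        t = self.pair_tests
        return int(((t["t_p"] < 0.01) & (t["t_stat"] > 0)).sum())

    def summary(self) -> str:
        lines = [
            f"Paired lineage comparison — statistic: {self.model.statistic}",
            f"units: {self.class_counts['n_units']} "
            f"(skipped incomplete: {self.class_counts['n_skipped']})",
            "",
            self.pair_tests.to_string(
                index=False,
                float_format=lambda v: f"{v:.3g}",
                columns=[
                    "mutualist", "generalist", "n_units", "t_stat", "t_p",
                    "wilcoxon_p", "fraction_mutualist_greater",
                ],
            ),
            "",
            "consistency classes: "
            + ", ".join(
                f"{k}={self.class_counts[k]}"
                for k in ("mutualist-faster", "generalist-faster", "inconsistent")
            ),
        ]
        return "\n".join(lines)
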