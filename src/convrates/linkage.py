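"""Mapping-population marker QC, phase doubling, and linkage grouping.

The mapping family is a heterozygous diploid queen crossed to a haploid
father, genotyped through diploid worker offspring: each informative marker
reduces to which of the queen's two alleles an offspring inherited (0/1
codes, NaN missing).  Because parental phase is unknown, every marker is
duplicated with its phase mirrored before grouping; mirrored linkage groups
(identical underlying locus sets) are collapsed afterwards, keeping the
lexicographically first copy.

Grouping itself is a deliberately simple single-linkage closure on pairwise
recombination fractions — a transparent stand-in for a full ordering
algorithm, sufficient to recover chromosome membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerMatrix",
    "marker_qc",
    "phase_double",
    "dedup_groups",
    "recombination_fraction",
    "linkage_groups",
]


@dataclass
class MarkerMatrix:
    """Offspring genotypes per marker, coded by inherited maternal allele.

    ``genotypes``: markers x offspring DataFrame over {0, 1, NaN}.
    ``queen_het``: marker -> whether the queen was called heterozygous.
    ``n_alleles``: marker -> allele count observed at the locus.
    """

    genotypes: pd.DataFrame
    queen_het: dict[str, bool] = field(default_factory=dict)
    n_alleles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotypes.shape[1] == 0:
            raise ValueError("zero offspring")
        vals = self.genotypes.to_numpy(float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("genotypes must be 0, 1 or missing")
        for m in self.genotypes.index:
            self.queen_het.setdefault(m, True)
            self.n_alleles.setdefault(m, 2)

    @property
    def markers(self) -> list[str]:
        return list(self.genotypes.index)


def marker_qc(
    m: MarkerMatrix, min_genotyped: float = 0.75, alpha: float = 0.05
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Apply the marker-retention rules in order; log the first rule hit.

    1. queen must be heterozygous;
    2. at least ``min_genotyped`` of offspring genotyped, and no more than
       two alleles;
    3. the two maternal alleles must not deviate from the expected 1:1
       ratio (exact two-sided binomial test at ``alpha``).
    Idempotent: retained markers pass all rules.
    """
    log_rows = []
    keep = []
    n_off = m.genotypes.shape[1]
    for marker in m.markers:
        row = m.genotypes.loc[marker]
        if not m.queen_het.get(marker, True):
            log_rows.append({"marker": marker, "rule": "queen-homozygous"})
            continue
        n_typed = int(row.notna().sum())
        if n_typed / n_off < min_genotyped:
            log_rows.append({"marker": marker, "rule": "missing-data"})
            continue
        if m.n_alleles.get(marker, 2) > 2:
            log_rows.append({"marker": marker, "rule": "multiallelic"})
            continue
        n_one = int((row == 1).sum())
        p = stats.binomtest(n_one, n_typed, 0.5, alternative="two-sided").pvalue
        if p < alpha:
            log_rows.append({"marker": marker, "rule": "allele-ratio"})
            continue
        keep.append(marker)
    retained = MarkerMatrix(
        genotypes=m.genotypes.loc[keep].copy(),
        queen_het={k: m.queen_het[k] for k in keep},
        n_alleles={k: m.n_alleles[k] for k in keep},
    )
    return retained, pd.DataFrame(log_rows, columns=["marker", "rule"])


PHASE_SUFFIXES = ("/p0", "/p1")


def phase_double(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Duplicate every marker with its phase mirrored.

    Marker ids gain ``/p0`` (original coding) and ``/p1`` (0/1 flipped)
    suffixes; exactly 2k rows result from k.  Applying the flip twice
    recovers the original encoding.
    """
    a = genotypes.copy()
    a.index = [f"{i}{PHASE_SUFFIXES[0]}" for i in genotypes.index]
    b = (1 - genotypes).copy()
    b.index = [f"{i}{PHASE_SUFFIXES[1]}" for i in genotypes.index]
    return pd.concat([a, b])


def strip_phase(marker_id: str) -> str:
    for suf in PHASE_SUFFIXES:
        if marker_id.endswith(suf):
            return marker_id[: -len(suf)]
    return marker_id


def dedup_groups(groups: list[list[str]]) -> list[list[str]]:
    """Collapse mirrored linkage groups (identical underlying locus sets),
    keeping the lexicographically first copy of each."""
    seen: dict[frozenset, list[str]] = {}
    for grp in groups:
        key = frozenset(strip_phase(g) for g in grp)
        cand = sorted(grp)
        if key not in seen or cand < sorted(seen[key]):
            seen[key] = grp
    return [seen[k] for k in sorted(seen, key=lambda s: sorted(s))]


def recombination_fraction(x: pd.Series, y: pd.Series) -> float:
    """Recombinant fraction among offspring informative for both markers;
    NaN when none are."""
    both = x.notna() & y.notna()
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float((x[both] != y[both]).mean())


def linkage_groups(
    genotypes: pd.DataFrame, rf_max: float = 0.2, min_loci: int = 3
) -> tuple[list[list[str]], list[list[str]], pd.DataFrame]:
    """Single-linkage grouping of markers at recombination fraction < rf_max.

    Returns (groups, small_groups, rf_matrix): groups meeting ``min_loci``,
    the under-sized remainder, and the pairwise rf matrix.  Pairs with no
    informative offspring have undefined rf and are never linked.
    """
    markers = list(genotypes.index)
    n = len(markers)
    vals = genotypes.to_numpy(float)
    rf = np.full((n, n), np.nan)
    np.fill_diagonal(rf, 0.0)
    present = ~np.isnan(vals)
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            cnt = int(both.sum())
            if cnt:
                rf[i, j] = rf[j, i] = float(
                    (vals[i, both] != vals[j, both]).mean()
                )
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(rf[i, j]) and rf[i, j] < rf_max:
                parent[find(i)] = find(j)
    clusters: dict[int, list[str]] = {}
    for i, mk in enumerate(markers):
        clusters.setdefault(find(i), []).append(mk)
    groups = [sorted(g) for g in clusters.values()]
    big = sorted([g for g in groups if len(g) >= min_loci])
    small = sorted([g for g in groups if len(g) < min_loci])
    rf_df = pd.DataFrame(rf, index=markers, columns=markers)
    return big, small, rf_df
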