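"""Counting-method substitution rates and codon-usage statistics.

The headline estimator here is the Nei–Gojobori (1986) counting method:
fractional synonymous/nonsynonymous site counts per codon, pathway-averaged
difference counts between codon pairs (pathways through stop codons
excluded), and a Jukes–Cantor correction d = -(3/4)·ln(1 - (4/3)p).  It is a
deliberately transparent stand-in for maximum-likelihood codon-model fits:
every number it produces can be checked against exhaustive enumeration.

Codon-usage bias is summarised with Wright's effective number of codons
(Nc, 20 = one codon per amino acid, 61 = uniform synonymous usage) and GC3
(fraction of third positions that are G or C).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import codons
from .design import PairDesign

__all__ = [
    "SiteCounts",
    "RateRecord",
    "ng86_site_counts",
    "ng86_pair",
    "species_rate_table",
    "aggregate_rates",
    "enc",
    "codon_usage_counts",
    "composition",
    "rate_usage_correlation",
]


@dataclass
class SiteCounts:
    """Fractional synonymous (S) and nonsynonymous (N) site counts."""

    S: float
    N: float
    n_codons: int
    n_skipped: int


@dataclass
class RateRecord:
    """NG86 estimates for one sequence pair (typically species vs outgroup)."""

    gene: str
    species: str
    dN: float
    dS: float
    ratio: float  # NaN when undefined
    Sd: float
    Nd: float
    S: float
    N: float
    n_codons: int
    n_skipped: int
    flags: list[str] = field(default_factory=list)


def ng86_site_counts(seq: str) -> SiteCounts:
    """Nei–Gojobori fractional site counts of one codon sequence.

    Codons containing N/gaps or coding for stops are skipped and counted.
    """
    idx = codons.encode_codons(seq)
    ok = codons.sense_mask(idx)
    s64, _, _ = codons.ng86_tables()
    s = float(s64[idx[ok]].sum())
    n = 3.0 * int(ok.sum()) - s
    return SiteCounts(S=s, N=n, n_codons=int(ok.sum()), n_skipped=int((~ok).sum()))


def _jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction; NaN outside the log domain."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p)


def ng86_pair(seq1: str, seq2: str, gene: str = "", species: str = "") -> RateRecord:
    """NG86 dN/dS between two equal-length codon-aligned sequences.

    Codons with ambiguity in either sequence are skipped; S and N are the
    averages of the two sequences' site counts over comparable codons.
    Flags: ``dS=0`` (ratio undefined), ``JC-undefined`` (pS or pN >= 3/4).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be codon-aligned to equal length")
    i1 = codons.encode_codons(seq1)
    i2 = codons.encode_codons(seq2)
    s64, sd64, nd64 = codons.ng86_tables()
    ok = codons.sense_mask(i1) & codons.sense_mask(i2)
    sd_all = sd64[i1[ok], i2[ok]]
    # codons whose every mutational pathway is blocked by stops are skipped
    blocked = np.isnan(sd_all)
    usable = np.where(ok)[0][~blocked]
    n_skipped = len(i1) - len(usable)
    if len(usable) == 0:
        raise ValueError("no comparable codons between sequences")
    c1, c2 = i1[usable], i2[usable]
    Sd = float(sd64[c1, c2].sum())
    Nd = float(nd64[c1, c2].sum())
    S = float((s64[c1].sum() + s64[c2].sum()) / 2.0)
    N = 3.0 * len(usable) - S
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    dS = _jc_correct(pS) if np.isfinite(pS) else float("nan")
    dN = _jc_correct(pN) if np.isfinite(pN) else float("nan")
    flags = []
    if (np.isfinite(pS) and pS >= 0.75) or (np.isfinite(pN) and pN >= 0.75):
        flags.append("JC-undefined")
    if dS == 0.0 or not np.isfinite(dS):
        flags.append("dS=0" if dS == 0.0 else "dS-undefined")
        ratio = float("nan")
    else:
        ratio = dN / dS
    return RateRecord(
        gene=gene, species=species, dN=dN, dS=dS, ratio=ratio,
        Sd=Sd, Nd=Nd, S=S, N=N, n_codons=len(usable), n_skipped=n_skipped,
        flags=flags,
    )


def species_rate_table(
    gene_alignments: dict[str, dict[str, str]],
    design: PairDesign,
    max_ratio: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-species NG86 rates against the outgroup, plus aggregates.

    Parameters
    ----------
    gene_alignments : dict
        gene id -> {species -> codon-aligned sequence}; must include the
        design's outgroup and ingroup species.
    design : PairDesign
    max_ratio : float
        Genes with dN/dS >= max_ratio are excluded from ratio statistics
        (large values flag assembly/annotation artefacts), but their dN and
        dS still enter the sums and means.

    Returns
    -------
    (records, aggregates)
        records: one row per gene x ingroup species.
        aggregates: per species mean dN, mean dS, mean ratio over usable
        genes, and the outlier-robust sum-based ratio sum(dN)/sum(dS).
    """
    if not gene_alignments:
        raise ValueError("empty gene set")
    rows = []
    for gene, seqs in gene_alignments.items():
        design.validate_against(list(seqs))
        ref = seqs[design.outgroup]
        for sp in design.ingroup:
            rec = ng86_pair(ref, seqs[sp], gene=gene, species=sp)
            rows.append(
                {
                    "gene": rec.gene, "species": rec.species, "dN": rec.dN,
                    "dS": rec.dS, "ratio": rec.ratio,
                    "flags": ";".join(rec.flags),
                }
            )
    records = pd.DataFrame(rows)
    return records, aggregate_rates(records, max_ratio=max_ratio)


def aggregate_rates(records: pd.DataFrame, max_ratio: float = 10.0) -> pd.DataFrame:
    """Per-species aggregates of a per-gene rate table.

    The mean ratio is taken over genes with a defined ratio below
    ``max_ratio``; the sum-based ratio sum(dN)/sum(dS) uses all genes
    (including dS=0 ones), which damps the influence of outlying loci.
    """
    aggs = []
    for sp, grp in records.groupby("species", sort=False):
        usable = grp[np.isfinite(grp["ratio"]) & (grp["ratio"] < max_ratio)]
        ds_sum = float(np.nansum(grp["dS"]))
        aggs.append(
            {
                "species": sp,
                "mean_dN": float(np.nanmean(grp["dN"])),
                "mean_dS": float(np.nanmean(grp["dS"])),
                "mean_ratio": float(usable["ratio"].mean()) if len(usable) else float("nan"),
                "sum_ratio": float(np.nansum(grp["dN"]) / ds_sum) if ds_sum > 0 else float("nan"),
                "n_genes": int(len(grp)),
                "n_ratio_used": int(len(usable)),
            }
        )
    return pd.DataFrame(aggs)


# ---------------------------------------------------------------------------
# codon usage

# synonymous-family degeneracy classes of the standard code: Met and Trp are
# the two non-degenerate amino acids (the "+2" of Wright's formula), Ile is
# the single 3-fold family, and Leu/Ser/Arg are 6-fold.
def _families() -> dict[str, list[str]]:
    fam: dict[str, list[str]] = {}
    for codon, aa in codons.AMINO_ACID.items():
        fam.setdefault(aa, []).append(codon)
    return fam


_FAMILIES = _families()
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}


def enc(counts: dict[str, int] | Counter) -> float:
    """Wright's effective number of codons (Nc) from raw codon counts.

    For each synonymous family with total count n >= 2 the homozygosity
    F-hat = (n * sum(p^2) - 1) / (n - 1); Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6
    with class means of F-hat.  Degeneracy classes with no usable family are
    imputed with the mean of the observed class means.  Capped at 61.
    """
    counts = {c: int(v) for c, v in counts.items() if v}
    if not counts:
        raise ValueError("empty codon counts")
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in _FAMILIES.items():
        k = len(fam)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        ssq = sum((counts.get(c, 0) / n) ** 2 for c in fam)
        f_hat = (n * ssq - 1.0) / (n - 1.0)
        if f_hat > 0:
            class_f[k].append(f_hat)
    means = {k: float(np.mean(v)) for k, v in class_f.items() if v}
    if not means:
        return 61.0
    impute = float(np.mean(list(means.values())))
    nc = 2.0
    for k, size in _CLASS_SIZES.items():
        nc += size / means.get(k, impute)
    return min(nc, 61.0)


def codon_usage_counts(seq: str) -> Counter:
    """Counts of sense codons in a nucleotide sequence (others ignored)."""
    idx = codons.encode_codons(seq)
    ok = codons.sense_mask(idx)
    inv = {v: k for k, v in codons.CODON_INDEX.items()}
    return Counter(inv[i] for i in idx[ok])


def gc3(seq: str) -> float:
    """Fraction of third codon positions (of sense codons) that are G or C."""
    idx = codons.encode_codons(seq)
    ok = codons.sense_mask(idx)
    if not ok.any():
        raise ValueError("no sense codons")
    third = idx[ok] % 4  # A=0 C=1 G=2 T=3
    return float(np.isin(third, [1, 2]).mean())


def composition(sequences: dict[str, str]) -> pd.DataFrame:
    """Per-species codon usage summary: 61 sense-codon proportions, GC3, Nc.

    Returns a DataFrame indexed by species with one column per sense codon
    plus ``GC3`` and ``Nc``.
    """
    rows = {}
    for sp, seq in sequences.items():
        counts = codon_usage_counts(seq)
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"no sense codons for species {sp}")
        row = {c: counts.get(c, 0) / total for c in codons.SENSE_CODONS}
        row["GC3"] = gc3(seq)
        row["Nc"] = enc(counts)
        rows[sp] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def rate_usage_correlation(
    per_gene_nc: pd.Series, records: pd.DataFrame, species: str
) -> pd.DataFrame:
    """Spearman rank correlation of per-gene Nc with dN and with dS.

    ``records`` is the per-gene rate table from :func:`species_rate_table`.
    """
    sub = records[records["species"] == species].set_index("gene")
    out = []
    for stat in ("dN", "dS"):
        joined = pd.concat([per_gene_nc, sub[stat]], axis=1, join="inner").dropna()
        if len(joined) < 3:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
        out.append({"species": species, "statistic": stat, "rho": rho, "p": p,
                    "n": len(joined)})
    return pd.DataFrame(out)
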