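"""Scan protein alignments for convergent amino-acid substitutions.

A column is convergent for a foreground subset F' (at least two foreground
lineages) when every member of F' carries the same residue and no species
outside F' carries it (``shared-exclusive``); the ``strict-background-
uniform`` mode additionally requires all remaining species to agree on a
single different residue — the pattern every worked example of this kind
shows (e.g. two plant-ant lineages converging on aspartic acid while all
other species keep asparagine).  Columns containing any gap, stop or
unknown residue are excluded from the examined-sites denominator.

Positions are reported 1-based within the translated gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .utils import percent

__all__ = ["ConvergenceRecord", "ScanTotals", "scan_convergent_sites", "gene_summary"]

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ConvergenceRecord:
    gene: str
    position: int  # 1-based amino-acid position within the gene
    foreground_subset: tuple[str, ...]
    residue: str
    background: str  # residues outside the subset, joined by '/'
    mode: str


@dataclass
class ScanTotals:
    sites_examined: int
    sites_excluded: int
    n_subset_convergent: int  # |F'| >= 2
    n_fully_convergent: int  # |F'| == |foreground|

    @property
    def subset_percent(self) -> float:
        return percent(self.n_subset_convergent, self.sites_examined, 3)

    @property
    def fully_percent(self) -> float:
        return percent(self.n_fully_convergent, self.sites_examined, 4)


def scan_convergent_sites(
    protein_alignments: dict[str, dict[str, str]],
    foreground: set[str] | list[str],
    mode: str = "shared-exclusive",
) -> tuple[list[ConvergenceRecord], ScanTotals]:
    """Scan translated gene alignments for convergent columns.

    Parameters
    ----------
    protein_alignments : dict
        gene id -> {species -> amino-acid sequence}, equal lengths per gene.
    foreground : set of str
        The lineages tested for convergence (|foreground| >= 2); must be a
        strict subset of the alignment species.
    mode : {"shared-exclusive", "strict-background-uniform"}
    """
    if mode not in ("shared-exclusive", "strict-background-uniform"):
        raise ValueError(f"unknown mode {mode!r}")
    fg = sorted(foreground)
    if len(fg) < 2:
        raise ValueError("foreground must contain at least two lineages")
    records: list[ConvergenceRecord] = []
    examined = excluded = fully = 0
    for gene, seqs in protein_alignments.items():
        species = sorted(seqs)
        missing_fg = set(fg) - set(species)
        if missing_fg:
            raise ValueError(f"foreground not in alignment {gene}: {sorted(missing_fg)}")
        mat = np.array([list(seqs[sp]) for sp in species])
        is_fg = np.array([sp in set(fg) for sp in species])
        ncols = mat.shape[1]
        ok_col = np.ones(ncols, dtype=bool)
        for aa_row in mat:
            ok_col &= np.isin(aa_row, list(_AA20))
        examined += int(ok_col.sum())
        excluded += int(ncols - ok_col.sum())
        for col in np.nonzero(ok_col)[0]:
            column = mat[:, col]
            for residue in np.unique(column[is_fg]):
                carriers_fg = [sp for sp, aa, f in zip(species, column, is_fg) if f and aa == residue]
                if len(carriers_fg) < 2:
                    continue
                outside = [
                    (sp, aa)
                    for sp, aa in zip(species, column)
                    if sp not in carriers_fg
                ]
                if any(aa == residue for _sp, aa in outside):
                    continue  # not exclusive to the subset
                bg_res = sorted({aa for _sp, aa in outside})
                if mode == "strict-background-uniform" and len(bg_res) != 1:
                    continue
                records.append(
                    ConvergenceRecord(
                        gene=gene, position=int(col) + 1,
                        foreground_subset=tuple(carriers_fg), residue=str(residue),
                        background="/".join(bg_res), mode=mode,
                    )
                )
                if len(carriers_fg) == len(fg):
                    fully += 1
    totals = ScanTotals(
        sites_examined=examined, sites_excluded=excluded,
        n_subset_convergent=len(records), n_fully_convergent=fully,
    )
    return records, totals


def gene_summary(
    records: list[ConvergenceRecord],
    full_foreground_size: int,
    min_fully: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene convergent-site counts and the multi-hit gene list.

    Returns (summary, notable) where summary has per-gene counts of
    subset-level and fully convergent sites (grand totals equal the column
    sums), and notable lists genes with at least ``min_fully`` fully
    convergent sites.
    """
    per_gene: dict[str, dict[str, int]] = {}
    for r in records:
        d = per_gene.setdefault(r.gene, {"n_subset": 0, "n_fully": 0})
        d["n_subset"] += 1
        if len(r.foreground_subset) == full_foreground_size:
            d["n_fully"] += 1
    summary = pd.DataFrame(
        [{"gene": g, **d} for g, d in sorted(per_gene.items())],
        columns=["gene", "n_subset", "n_fully"],
    )
    notable = sorted(summary[summary["n_fully"] >= min_fully]["gene"]) if len(summary) else []
    return summary, notable


def records_frame(records: list[ConvergenceRecord]) -> pd.DataFrame:
    """Tabular view of scan records (for TSV export)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "position": r.position,
                "subset": ",".join(r.foreground_subset), "residue": r.residue,
                "background": r.background, "mode": r.mode,
            }
            for r in records
        ],
        columns=["gene", "position", "subset", "residue", "background", "mode"],
    )
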