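"""End-to-end orchestration: simulate (or load) data, run every analysis
stage in order, and emit a structured report bundle.

Stage order mirrors the analysis narrative: window distances -> paired
window tests -> gene rates (NG86) -> paired gene tests -> consistency
classification -> convergence scan -> depth/copy-number screen ->
expression contrast.  Everything is deterministic given the seed; the
summary JSON carries per-pair test results, class counts, convergence
totals and flagged regions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import convergence as conv
from . import compare, rates, screens, windows
from .alignment import gene_qc, extract_gene
from .codons import translate_codon_indices, encode_codons
from .design import DEFAULT_DESIGN, DEFAULT_NEWICK, PairDesign
from .simulate import (
    SimParams,
    SimTree,
    simulate_codon_alignment,
    simulate_expression_matrix,
    simulate_noncoding_alignment,
    simulate_read_depth,
)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a synthetic end-to-end run."""

    seed: int
    outdir: str = "convrates_run"
    design: PairDesign = field(default_factory=PairDesign)
    newick: str = DEFAULT_NEWICK
    mutualist_rho: float = 1.5
    omega: float = 0.2
    kappa: float = 2.0
    n_genes: int = 150
    gene_length: int = 400
    n_scaffolds: int = 4
    scaffold_length: int = 300_000
    window_size: int = 25_000
    window_step: int = 5_000
    min_known: float = 0.5
    min_codons: int = 300
    max_missing: float = 0.20
    n_convergent_sites: int = 20
    mean_depth: float = 30.0
    n_dup_regions: int = 3
    head_shift: float = 3.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "design" in raw:
            d = raw["design"]
            raw["design"] = PairDesign(
                outgroup=d["outgroup"],
                pairs=tuple(tuple(p) for p in d["pairs"]),
            )
        return cls(**raw)

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("a seed is mandatory for synthetic runs")
        if not (0 < self.min_known <= 1 and 0 <= self.max_missing <= 1):
            raise ValueError("thresholds out of range")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic pipeline; write tables + JSON summary + log."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("convrates")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    try:
        summary = _run(config, outdir)
    finally:
        root.removeHandler(fh)
        fh.close()
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _run(config: RunConfig, outdir: Path) -> dict:
    design = config.design
    tree = SimTree(
        newick=config.newick, default_omega=config.omega
    ).with_terminal_rho(design.mutualists, config.mutualist_rho)
    design.validate_against(tree.leaf_labels)

    # --- noncoding windows -------------------------------------------------
    nc_params = SimParams(
        seed=config.seed,
        scaffold_lengths=tuple([config.scaffold_length] * config.n_scaffolds),
        kappa_nuc=1.0,
    )
    nc_aln, _ = simulate_noncoding_alignment(tree, nc_params)
    wins = windows.make_windows(
        nc_aln, size=config.window_size, step=config.window_step,
        min_known=config.min_known,
    )
    wtable = windows.window_table(nc_aln, wins, reference=design.outgroup)
    wtable.to_csv(outdir / "window_table.tsv", sep="\t", index=False)
    wide_windows = (
        wtable[wtable["valid"]]
        .assign(unit=lambda d: d["scaffold"] + ":" + d["start"].astype(str))
        .pivot_table(index="unit", columns="species", values="distance")
    )
    log.info("windows: %d made, %d valid units", len(wins), len(wide_windows))
    dist_results = compare.PairedRateModel(
        wide_windows, design, statistic="distance"
    ).fit()
    dist_results.pair_tests.to_csv(outdir / "paired_tests_distance.tsv", sep="\t", index=False)

    # --- coding genes ------------------------------------------------------
    cd_params = SimParams(
        seed=config.seed + 1,
        kappa=config.kappa,
        n_genes=config.n_genes,
        gene_length=config.gene_length,
        n_convergent_sites=config.n_convergent_sites,
    )
    cd_aln, gene_models, truth = simulate_codon_alignment(tree, cd_params, design)
    gene_alns = {}
    n_fail = 0
    for gm in gene_models:
        ga = extract_gene(cd_aln, gm)
        qc = gene_qc(
            ga, species_count_required=len(design.all_species),
            min_codons=min(config.min_codons, config.gene_length),
            max_missing=config.max_missing,
        )
        if qc.passed:
            gene_alns[gm.gene_id] = qc.alignment.seqs
        else:
            n_fail += 1
            log.info("gene %s failed QC: %s", gm.gene_id, qc.reasons)
    log.info("gene QC: %d retained + %d removed = %d input",
             len(gene_alns), n_fail, len(gene_models))

    records, aggregates = rates.species_rate_table(gene_alns, design)
    records.to_csv(outdir / "rate_table.tsv", sep="\t", index=False)
    aggregates.to_csv(outdir / "rate_aggregates.tsv", sep="\t", index=False)

    ds_results = compare.PairedRateModel.from_long(
        records, design, statistic="dS"
    ).fit()
    ds_results.pair_tests.to_csv(outdir / "paired_tests_ds.tsv", sep="\t", index=False)
    calls, class_counts = ds_results.consistency_calls, ds_results.class_counts
    calls.to_csv(outdir / "consistency_calls.tsv", sep="\t")

    # --- convergence -------------------------------------------------------
    proteins = {
        g: {sp: translate_codon_indices(encode_codons(s)) for sp, s in seqs.items()}
        for g, seqs in gene_alns.items()
    }
    records_c, totals = conv.scan_convergent_sites(
        proteins, foreground=design.mutualists
    )
    conv.records_frame(records_c).to_csv(outdir / "convergence.tsv", sep="\t", index=False)
    planted = truth.convergent_sites
    planted_in_passed = planted[planted["gene"].isin(gene_alns)]
    found = {
        (r.gene, r.position)
        for r in records_c
        if len(r.foreground_subset) == len(design.mutualists)
    }
    recovered = sum(
        (row.gene, row.codon_column) in found
        for row in planted_in_passed.itertuples()
    )
    recall = recovered / len(planted_in_passed) if len(planted_in_passed) else float("nan")

    # --- depth / copy number ----------------------------------------------
    scaffold_lengths = {"cnv_scaffold": 200_000}
    region_len = 10_000
    dup_regions = [
        ("cnv_scaffold", 20_000 + i * 50_000, 20_000 + i * 50_000 + region_len)
        for i in range(config.n_dup_regions)
    ]
    cn_rows = {}
    for si, sp in enumerate(design.ingroup):
        is_mut = sp in design.mutualists
        spec = [
            (scaf, s, e, 4.0 if is_mut else 2.0) for scaf, s, e in dup_regions
        ]
        track, _ = simulate_read_depth(
            spec, config.mean_depth, seed=config.seed + 100 + si,
            scaffold_lengths=scaffold_lengths,
        )
        est = screens.cn_estimate(track, dup_regions)
        cn_rows[sp] = est["cn"].to_numpy()
    cn_table = pd.DataFrame(cn_rows, index=[f"{s}:{a}-{b}" for s, a, b in dup_regions])
    flagged, n_skip = screens.duplication_consistency(cn_table, design)
    flagged.to_csv(outdir / "cn_regions.tsv", sep="\t")
    n_mut_amp = int((flagged["class"] == "mutualist-amplified").sum())

    # --- expression --------------------------------------------------------
    fast_genes = sorted(calls.index[calls["class"] == "mutualist-faster"])
    gene_ids = sorted(gene_alns)
    expr = simulate_expression_matrix(
        n_genes=len(gene_ids),
        fast_gene_ids=[gene_ids.index(g) for g in fast_genes],
        head_shift=config.head_shift,
        seed=config.seed + 7,
    )
    expr.index = gene_ids
    contrast, n_zero = compare.expression_contrast(expr, fast_genes)
    contrast.to_csv(outdir / "expression_contrast.tsv", sep="\t", index=False)

    def pair_rows(df: pd.DataFrame) -> list[dict]:
        return df[["mutualist", "generalist", "t_stat", "t_p",
                   "wilcoxon_p", "fraction_mutualist_greater"]].to_dict("records")

    return {
        "schema_version": SCHEMA_VERSION,
        "seed": int(config.seed),
        "n_windows": len(wins),
        "n_window_units": int(len(wide_windows)),
        "paired_tests": {
            "distance": pair_rows(dist_results.pair_tests),
            "dS": pair_rows(ds_results.pair_tests),
        },
        "gene_qc": {"retained": len(gene_alns), "removed": n_fail},
        "consistency_classes": class_counts,
        "convergence": {
            "sites_examined": totals.sites_examined,
            "subset_convergent": totals.n_subset_convergent,
            "fully_convergent": totals.n_fully_convergent,
            "planted_recall": recall,
        },
        "copy_number": {
            "regions": len(cn_table),
            "mutualist_amplified": n_mut_amp,
            "skipped": n_skip,
        },
        "expression": {
            "head_significant": bool(
                contrast.loc[contrast["tissue"] == "head", "significant"].iloc[0]
            ),
            "n_zero_rows": n_zero,
        },
    }
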