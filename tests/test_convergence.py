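"""Convergence scanner: worked columns, planted recall, symmetry."""

import numpy as np
import pytest
from scipy import stats

from convrates.codons import encode_codons, translate_codon_indices
from convrates.convergence import gene_summary, scan_convergent_sites
from convrates.simulate import SimParams, SimTree, simulate_codon_alignment

SPECIES = ["den", "fla", "con", "pal", "elo", "psw", "gra"]
FOREGROUND = ["den", "fla", "con"]


def _column_alignment(columns):
    """Build a one-gene alignment from a list of per-species residue dicts."""
    seqs = {sp: "".join(col[sp] for col in columns) for sp in SPECIES}
    return {"g1": seqs}


def test_two_lineage_convergent_column_detected_in_both_modes():
    # two foreground lineages share D, all others carry N
    col = {"den": "D", "fla": "D", "con": "N", "pal": "N", "elo": "N",
           "psw": "N", "gra": "N"}
    for mode in ("shared-exclusive", "strict-background-uniform"):
        records, totals = scan_convergent_sites(
            _column_alignment([col]), FOREGROUND, mode=mode
        )
        assert len(records) == 1
        assert records[0].foreground_subset == ("den", "fla")
        assert records[0].residue == "D"
        assert records[0].position == 1
        assert totals.sites_examined == 1


def test_uniform_column_not_convergent():
    col = {sp: "A" for sp in SPECIES}
    records, _ = scan_convergent_sites(_column_alignment([col]), FOREGROUND)
    assert records == []


def test_background_carrier_breaks_exclusivity():
    col = {"den": "D", "fla": "D", "con": "N", "pal": "D", "elo": "N",
           "psw": "N", "gra": "N"}
    records, _ = scan_convergent_sites(_column_alignment([col]), FOREGROUND)
    assert records == []


def test_strict_mode_requires_uniform_background():
    col = {"den": "D", "fla": "D", "con": "N", "pal": "S", "elo": "N",
           "psw": "N", "gra": "N"}
    shared, _ = scan_convergent_sites(_column_alignment([col]), FOREGROUND)
    strict, _ = scan_convergent_sites(
        _column_alignment([col]), FOREGROUND, mode="strict-background-uniform"
    )
    assert len(shared) == 1 and strict == []


def test_missing_data_columns_excluded():
    good = {"den": "D", "fla": "D", "con": "N", "pal": "N", "elo": "N",
            "psw": "N", "gra": "N"}
    gap = dict(good, gra="-")
    unknown = dict(good, pal="X")
    records, totals = scan_convergent_sites(
        _column_alignment([good, gap, unknown]), FOREGROUND
    )
    assert totals.sites_examined == 1
    assert totals.sites_excluded == 2
    assert [r.position for r in records] == [1]


def test_foreground_validation():
    aln = _column_alignment([{sp: "A" for sp in SPECIES}])
    with pytest.raises(ValueError):
        scan_convergent_sites(aln, ["den"])
    with pytest.raises(ValueError):
        scan_convergent_sites(aln, ["den", "nosuch"])


def test_planted_sites_fully_recovered(small_codon_sim, design):
    aln, _genes, truth = small_codon_sim
    proteins = {
        g: {sp: translate_codon_indices(encode_codons(s)) for sp, s in rows.items()}
        for g, rows in aln.sequences.items()
    }
    records, totals = scan_convergent_sites(proteins, design.mutualists)
    found = {
        (r.gene, r.position)
        for r in records
        if len(r.foreground_subset) == 3
    }
    for row in truth.convergent_sites.itertuples():
        assert (row.gene, row.codon_column) in found
    assert totals.n_fully_convergent >= len(truth.convergent_sites)


def test_strict_counts_never_exceed_shared(small_codon_sim, design):
    aln, _genes, _truth = small_codon_sim
    proteins = {
        g: {sp: translate_codon_indices(encode_codons(s)) for sp, s in rows.items()}
        for g, rows in aln.sequences.items()
    }
    _, shared = scan_convergent_sites(proteins, design.mutualists)
    _, strict = scan_convergent_sites(
        proteins, design.mutualists, mode="strict-background-uniform"
    )
    assert strict.n_subset_convergent <= shared.n_subset_convergent


def test_foreground_background_symmetry_on_exchangeable_data(design):
    """With no rate shift the mutualist and generalist labels are
    exchangeable, so convergent-site counts from either foreground should
    be statistically indistinguishable.  A deeper tree provides enough
    background convergence to test against; counts are pooled over seeds
    and compared with a two-sided binomial test."""
    deep = (
        "(gracilis:0.3,(concolor:0.24,((dendroicus:0.084,elongatus:0.084):0.096,"
        "(pallidus:0.12,(flavicornis:0.06,PSW54:0.06):0.06):0.06):0.06):0.06);"
    )
    tree = SimTree(newick=deep, default_omega=1.0)
    m_total = g_total = 0
    for seed in (11, 22, 33, 44, 55):
        aln, _, _ = simulate_codon_alignment(
            tree, SimParams(seed=seed, n_genes=8, gene_length=400)
        )
        proteins = {
            g: {sp: translate_codon_indices(encode_codons(s)) for sp, s in rows.items()}
            for g, rows in aln.sequences.items()
        }
        _, tm = scan_convergent_sites(proteins, design.mutualists)
        _, tg = scan_convergent_sites(proteins, design.generalists)
        m_total += tm.n_subset_convergent
        g_total += tg.n_subset_convergent
    assert m_total + g_total > 20  # enough signal for the comparison
    p = stats.binomtest(m_total, m_total + g_total, 0.5).pvalue
    assert p > 0.01


def test_gene_summary_conservation():
    good = {"den": "D", "fla": "D", "con": "D", "pal": "N", "elo": "N",
            "psw": "N", "gra": "N"}
    partial = {"den": "D", "fla": "D", "con": "A", "pal": "N", "elo": "N",
               "psw": "N", "gra": "N"}
    records, totals = scan_convergent_sites(
        _column_alignment([good, good, good, partial]), FOREGROUND
    )
    summary, notable = gene_summary(records, full_foreground_size=3, min_fully=3)
    assert summary["n_subset"].sum() == len(records)
    assert summary["n_fully"].sum() == totals.n_fully_convergent == 3
    assert notable == ["g1"]
    empty, empty_notable = gene_summary([], 3)
    assert len(empty) == 0 and empty_notable == []
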