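"""Simulator correctness: determinism, closed forms, planted truths."""

import numpy as np
import pytest

from convrates import codons
from convrates.design import DEFAULT_DESIGN
from convrates.simulate import (
    SimParams,
    SimTree,
    haldane_rf,
    read_bedgraph,
    simulate_codon_alignment,
    simulate_expression_matrix,
    simulate_mapping_population,
    simulate_noncoding_alignment,
    simulate_read_depth,
    write_bedgraph,
)
from convrates.windows import p_distance


def test_validation():
    with pytest.raises(ValueError):
        SimTree(rho={"concolor": 0.0})
    with pytest.raises(ValueError):
        SimTree(omega={"concolor": -1.0})
    with pytest.raises(ValueError):
        SimParams(seed=1, pi=np.ones(61))  # does not sum to 1
    with pytest.raises(ValueError):
        SimParams(seed=1, scaffold_lengths=(0,))
    with pytest.raises(ValueError):
        SimParams(seed="x")  # type: ignore[arg-type]


def test_codon_sim_deterministic_and_stop_free(default_tree, design):
    params = SimParams(seed=42, n_genes=3, gene_length=120, n_convergent_sites=2)
    a1, g1, t1 = simulate_codon_alignment(default_tree, params, design)
    a2, _, _ = simulate_codon_alignment(default_tree, params, design)
    assert a1.sequences == a2.sequences
    for rows in a1.sequences.values():
        lengths = {len(s) for s in rows.values()}
        assert lengths == {360}
        for s in rows.values():
            idx = codons.encode_codons(s)
            assert codons.sense_mask(idx).all()  # no stops, no ambiguity


def test_zero_branch_lengths_give_identical_leaves():
    tree = SimTree(newick="(a:0,(b:0,(c:0,d:0):0):0);")
    aln, _, _ = simulate_codon_alignment(tree, SimParams(seed=7, gene_length=80))
    assert len(set(aln.sequences["gene0001"].values())) == 1


def test_planted_convergent_sites_present_in_sequences(small_codon_sim, design):
    aln, _genes, truth = small_codon_sim
    assert len(truth.convergent_sites) == 6
    for row in truth.convergent_sites.itertuples():
        col = row.codon_column - 1
        for sp in design.mutualists:
            codon = aln.sequences[row.gene][sp][3 * col : 3 * col + 3]
            assert codons.AMINO_ACID[codon] == row.residue


def test_noncoding_jc_closed_form():
    """Under Jukes–Cantor, expected p-distance is 0.75*(1 - exp(-4t/3))."""
    t = 0.08
    tree = SimTree(newick=f"(a:{t},b:0.0);")
    aln, _ = simulate_noncoding_alignment(
        tree, SimParams(seed=9, scaffold_lengths=(400_000,))
    )
    seqs = aln.sequences["scaffold001"]
    expected = 0.75 * (1 - np.exp(-4 * t / 3))
    assert p_distance(seqs["a"], seqs["b"]) == pytest.approx(expected, abs=0.003)


def test_rho_doubles_terminal_divergence():
    """rho=2 on one of two equal sister terminals doubles its expected
    distance contribution beyond the shared path."""
    nwk = "(out:0.05,(m:0.02,g:0.02):0.03);"
    fast = SimTree(newick=nwk, rho={"m": 2.0})
    aln, _ = simulate_noncoding_alignment(
        fast, SimParams(seed=13, scaffold_lengths=(400_000,))
    )
    seqs = aln.sequences["scaffold001"]
    d_m = p_distance(seqs["out"], seqs["m"])
    d_g = p_distance(seqs["out"], seqs["g"])
    # expected excess of m over g ~= extra terminal length 0.02 (minus
    # multiple hits); with rho=1 the difference would centre on zero
    assert d_m - d_g == pytest.approx(0.02, abs=0.004)


def test_rho_one_is_symmetric(default_tree, design):
    aln, _ = simulate_noncoding_alignment(
        default_tree, SimParams(seed=17, scaffold_lengths=(300_000,))
    )
    seqs = aln.sequences["scaffold001"]
    diffs = [
        p_distance(seqs[design.outgroup], seqs[m])
        - p_distance(seqs[design.outgroup], seqs[g])
        for m, g in design.pairs
    ]
    assert np.abs(diffs).max() < 0.004  # centred on zero


def test_unknown_runs_planted():
    aln, _ = simulate_noncoding_alignment(
        SimTree(), SimParams(seed=3, scaffold_lengths=(20_000,), unknown_runs=2,
                             unknown_run_length=1_000)
    )
    total_n = sum(s.count("N") for s in aln.sequences["scaffold001"].values())
    assert total_n == 2_000


# --- read depth -------------------------------------------------------------


def test_read_depth_poisson_means(tmp_path):
    regions = [("s1", 50_000, 60_000, 4.0)]
    track, truth = simulate_read_depth(
        regions, mean_depth=30.0, seed=5, scaffold_lengths={"s1": 100_000}
    )
    d = track["s1"]
    assert np.median(d[:50_000]) == pytest.approx(30, abs=1)
    assert d[50_000:60_000].mean() == pytest.approx(60, rel=0.03)
    path = tmp_path / "depth.bedgraph"
    write_bedgraph(track, path)
    again = read_bedgraph(path)
    assert np.array_equal(again["s1"], d)


def test_read_depth_rejects_bad_regions():
    with pytest.raises(ValueError, match="zero-length"):
        simulate_read_depth([("s1", 10, 10, 4.0)], 30.0, seed=1,
                            scaffold_lengths={"s1": 100})
    with pytest.raises(ValueError):
        simulate_read_depth([], 0.0, seed=1, scaffold_lengths={"s1": 100})


# --- mapping population -----------------------------------------------------


def test_mapping_population_recombination():
    geno, truth = simulate_mapping_population(
        500, {"chr1": [0.0, 10.0], "chr2": [0.0]}, seed=21
    )
    rf_adj = float((geno.loc["chr1_m01"] != geno.loc["chr1_m02"]).mean())
    assert rf_adj == pytest.approx(haldane_rf(10.0), abs=0.03)
    rf_cross = float((geno.loc["chr1_m01"] != geno.loc["chr2_m01"]).mean())
    assert rf_cross == pytest.approx(0.5, abs=0.06)
    assert truth.marker_chromosomes["chr2_m01"] == "chr2"


def test_mapping_population_validation():
    with pytest.raises(ValueError):
        simulate_mapping_population(1, {"chr1": [0.0]}, seed=1)
    with pytest.raises(ValueError):
        simulate_mapping_population(10, {"chr1": []}, seed=1)


# --- expression -------------------------------------------------------------


def test_expression_defaults_and_shift():
    em = simulate_expression_matrix(50, seed=3)
    assert em.shape == (50, 29)
    assert (em >= 0).all().all()
    shifted = simulate_expression_matrix(50, fast_gene_ids=[0], head_shift=4.0, seed=3)
    assert shifted.iloc[0, 0] == pytest.approx(5 * em.iloc[0, 0])
    with pytest.raises(ValueError):
        simulate_expression_matrix(10, fast_gene_ids=[10], seed=1)
    with pytest.raises(ValueError):
        simulate_expression_matrix(10, head_shift=-1.0, seed=1)
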