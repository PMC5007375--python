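"""Unit and oracle tests for the counting estimator and codon-usage stats."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from convrates import codons, rates


# --- independent enumeration oracle ---------------------------------------


def _oracle_site_counts(codon: str) -> float:
    """Synonymous sites by direct mutant enumeration (per-position fractions,
    stop targets removed from the denominator)."""
    aa = codons.AMINO_ACID[codon]
    total = 0.0
    for pos in range(3):
        outcomes = []
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in codons.STOP_CODONS:
                continue
            outcomes.append(codons.AMINO_ACID[mut] == aa)
        if outcomes:
            total += sum(outcomes) / len(outcomes)
    return total


def _oracle_pathways(c1: str, c2: str):
    """All stop-free single-step paths from c1 to c2 via recursive DFS,
    returning pathway-averaged (syn, nonsyn) or None."""
    results = []

    def walk(cur, remaining, syn, non):
        if not remaining:
            results.append((syn, non))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in codons.STOP_CODONS:
                continue
            step_syn = codons.AMINO_ACID[cur] == codons.AMINO_ACID[nxt]
            walk(nxt, [p for p in remaining if p != pos],
                 syn + step_syn, non + (not step_syn))

    walk(c1, [i for i in range(3) if c1[i] != c2[i]], 0, 0)
    if not results:
        return None
    arr = np.array(results, dtype=float)
    return arr[:, 0].mean(), arr[:, 1].mean()


def test_site_count_worked_examples():
    sc = rates.ng86_site_counts("TTT")
    assert sc.S == pytest.approx(1 / 3)
    assert sc.N == pytest.approx(8 / 3)
    sc = rates.ng86_site_counts("ATG")
    assert sc.S == 0.0 and sc.N == 3.0


def test_site_counts_conserve_three_per_codon():
    for codon in codons.SENSE_CODONS:
        sc = rates.ng86_site_counts(codon)
        assert sc.S + sc.N == pytest.approx(3.0)
        assert sc.S == pytest.approx(_oracle_site_counts(codon))


def test_pathway_counts_match_exhaustive_enumeration(rng):
    """Pathway-averaged (Sd, Nd) equals independent DFS enumeration for
    1,000 random sense-codon pairs."""
    _, sd64, nd64 = codons.ng86_tables()
    sense = list(codons.SENSE_CODONS)
    for _ in range(1000):
        c1, c2 = (sense[i] for i in rng.integers(0, 61, size=2))
        got = (sd64[codons.CODON_INDEX[c1], codons.CODON_INDEX[c2]],
               nd64[codons.CODON_INDEX[c1], codons.CODON_INDEX[c2]])
        want = _oracle_pathways(c1, c2)
        if want is None:
            assert np.isnan(got[0])
        else:
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])


def test_two_step_pathway_worked_example():
    r = rates.ng86_pair("CCT", "CAG")
    assert r.Sd == pytest.approx(0.5)
    assert r.Nd == pytest.approx(1.5)


def test_pair_is_symmetric_and_zero_on_identity(rng):
    sense = list(codons.SENSE_CODONS)
    seq1 = "".join(sense[i] for i in rng.integers(0, 61, size=60))
    seq2 = "".join(sense[i] for i in rng.integers(0, 61, size=60))
    a = rates.ng86_pair(seq1, seq2)
    b = rates.ng86_pair(seq2, seq1)
    assert a.dN == pytest.approx(b.dN, nan_ok=True)
    assert a.dS == pytest.approx(b.dS, nan_ok=True)
    same = rates.ng86_pair(seq1, seq1)
    assert same.dN == 0.0 and same.dS == 0.0


def test_pair_cross_checked_against_biopython(rng):
    """Dual route: our NG86 against Biopython's independent implementation."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    sense = list(codons.SENSE_CODONS)
    base = [sense[i] for i in rng.integers(0, 61, size=200)]
    # mutate ~10% of codons into other sense codons
    other = list(base)
    for i in rng.integers(0, len(base), size=25):
        other[i] = sense[int(rng.integers(0, 61))]
    r = rates.ng86_pair("".join(base), "".join(other))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dn, ds = cal_dn_ds(CodonSeq("".join(base)), CodonSeq("".join(other)),
                           method="NG86")
    # conventions differ slightly in how mutations to stop codons enter the
    # site-count denominators, so agreement is close but not bit-exact
    assert r.dN == pytest.approx(dn, rel=0.05)
    assert r.dS == pytest.approx(ds, rel=0.05)


def test_jc_undefined_flagged():
    # GGG vs GGA: one synonymous difference over exactly one synonymous
    # site per codon -> pS = 1 >= 3/4, outside the correction's domain
    r = rates.ng86_pair("GGG", "GGA")
    assert np.isnan(r.dS)
    assert "JC-undefined" in r.flags


def test_pair_input_validation():
    with pytest.raises(ValueError):
        rates.ng86_pair("ATG", "ATGATG")
    with pytest.raises(ValueError):
        rates.ng86_pair("NNN", "NNN")


# --- aggregation ------------------------------------------------------------


def _records(rows):
    return pd.DataFrame(rows, columns=["gene", "species", "dN", "dS", "ratio", "flags"])


def test_aggregate_sum_vs_mean_worked_example():
    rec = _records([
        ("g1", "sp", 1.0, 4.0, 0.25, ""),
        ("g2", "sp", 3.0, 2.0, 1.5, ""),
    ])
    agg = rates.aggregate_rates(rec).iloc[0]
    assert agg["sum_ratio"] == pytest.approx(4 / 6)
    assert agg["mean_ratio"] == pytest.approx(0.875)


def test_aggregate_filters_large_ratios_and_keeps_sums():
    rec = _records([
        ("g1", "sp", 1.0, 4.0, 0.25, ""),
        ("g2", "sp", 12.0, 1.0, 12.0, ""),       # ratio >= 10: out of means
        ("g3", "sp", 0.5, 0.0, np.nan, "dS=0"),  # undefined ratio, in sums
    ])
    agg = rates.aggregate_rates(rec).iloc[0]
    assert agg["n_ratio_used"] == 1
    assert agg["mean_ratio"] == pytest.approx(0.25)
    assert agg["sum_ratio"] == pytest.approx((1.0 + 12.0 + 0.5) / 5.0)


def test_sum_and_mean_agree_on_single_gene():
    rec = _records([("g1", "sp", 0.02, 0.08, 0.25, "")])
    agg = rates.aggregate_rates(rec).iloc[0]
    assert agg["sum_ratio"] == pytest.approx(agg["mean_ratio"])


def test_species_rate_table_requires_genes(design):
    with pytest.raises(ValueError):
        rates.species_rate_table({}, design)


# --- codon usage ------------------------------------------------------------


def test_enc_closed_forms():
    uniform = Counter({c: 500 for c in codons.SENSE_CODONS})
    assert rates.enc(uniform) == pytest.approx(61.0)
    one_per_aa = Counter()
    seen = set()
    for c in codons.SENSE_CODONS:
        aa = codons.AMINO_ACID[c]
        if aa not in seen:
            seen.add(aa)
            one_per_aa[c] = 500
    assert rates.enc(one_per_aa) == pytest.approx(20.0)


@given(st.lists(st.integers(0, 200), min_size=61, max_size=61).filter(lambda v: sum(v) > 1))
def test_enc_range(counts):
    nc = rates.enc(dict(zip(codons.SENSE_CODONS, counts)))
    assert 20.0 <= nc <= 61.0 or np.isnan(nc)


def test_enc_rejects_empty():
    with pytest.raises(ValueError):
        rates.enc({})


def test_gc3_and_proportions():
    assert rates.gc3("GGGGGG") == 1.0
    assert rates.gc3("GGAGGT") == 0.0
    comp = rates.composition({"x": "ATGGCCAAA" * 30})
    assert comp.loc["x", list(codons.SENSE_CODONS)].sum() == pytest.approx(1.0)


def test_rate_usage_correlation_shapes():
    nc = pd.Series({"g1": 45.0, "g2": 50.0, "g3": 55.0, "g4": 60.0})
    rec = _records([
        ("g1", "sp", 0.01, 0.05, 0.2, ""),
        ("g2", "sp", 0.02, 0.04, 0.5, ""),
        ("g3", "sp", 0.03, 0.03, 1.0, ""),
        ("g4", "sp", 0.04, 0.02, 2.0, ""),
    ])
    out = rates.rate_usage_correlation(nc, rec, "sp")
    assert set(out["statistic"]) == {"dN", "dS"}
    dn_rho = out.loc[out["statistic"] == "dN", "rho"].iloc[0]
    assert dn_rho == pytest.approx(1.0)  # monotone by construction


def test_omega_ordering_recovered_across_replicates():
    """Simulations at omega=0.2 vs omega=1 yield correctly ordered NG86
    ratio estimates in at least 95% of seeded replicates."""
    from convrates.simulate import SimParams, SimTree, simulate_codon_alignment

    nwk = "(out:0.05,sp:0.0);"
    correct = 0
    n_rep = 20
    for seed in range(700, 700 + n_rep):
        ratios = {}
        for omega in (0.2, 1.0):
            tree = SimTree(newick=nwk, default_omega=omega)
            aln, _, _ = simulate_codon_alignment(
                tree, SimParams(seed=seed, gene_length=500)
            )
            seqs = aln.sequences["gene0001"]
            ratios[omega] = rates.ng86_pair(seqs["out"], seqs["sp"]).ratio
        if ratios[0.2] < ratios[1.0]:
            correct += 1
    assert correct >= 0.95 * n_rep


def test_gc_biased_frequencies_shift_gc3():
    """Asymmetric codon frequencies move third-position GC content in the
    expected direction in simulated sequences."""
    import numpy as np

    from convrates.simulate import SimParams, SimTree, simulate_codon_alignment

    tree = SimTree(newick="(out:0.02,sp:0.02);")
    gc3_by_bias = {}
    for name, favoured_weight in (("gc", 9.0), ("at", 1 / 9.0)):
        weights = np.array(
            [favoured_weight if c[2] in "GC" else 1.0 for c in codons.SENSE_CODONS]
        )
        params = SimParams(seed=55, gene_length=2_000, pi=weights / weights.sum())
        aln, _, _ = simulate_codon_alignment(tree, params)
        gc3_by_bias[name] = rates.gc3(aln.sequences["gene0001"]["sp"])
    assert gc3_by_bias["gc"] > 0.6 > 0.4 > gc3_by_bias["at"]
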