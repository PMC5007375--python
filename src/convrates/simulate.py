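"""Sequence-evolution and study-design simulators.

These generators produce inputs with the statistical structure the analysis
pipeline assumes, together with truth tables for parameter-recovery tests:

* codon alignments under a Goldman–Yang-style Markov process (61 sense-codon
  states, transition/transversion ratio kappa, dN/dS omega, target codon
  frequencies pi) evolved site-independently along a fixed tree;
* noncoding nucleotide alignments (Jukes–Cantor by default, HKY when kappa
  or unequal base frequencies are supplied);
* per-base read-depth tracks with planted copy-number gains;
* a single-family mapping population (heterozygous queen, haploid father,
  Haldane recombination);
* a tissue-by-gene expression matrix with an optional head-tissue shift for
  a designated fast-evolving gene set.

Every branch carries a rate multiplier rho (the dial used to plant
lineage-specific accelerations) and its own omega; branch lengths are in
expected substitutions per site, so rho scales realised divergence directly.
All randomness flows from a single integer seed: identical seed and
parameters give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import codons
from .alignment import AlignmentSet, GeneModel
from .design import DEFAULT_NEWICK, PairDesign

__all__ = [
    "SimTree",
    "SimParams",
    "TruthTable",
    "simulate_codon_alignment",
    "simulate_noncoding_alignment",
    "simulate_read_depth",
    "simulate_mapping_population",
    "simulate_expression_matrix",
    "haldane_rf",
]


# ---------------------------------------------------------------------------
# tree & parameters


@dataclass
class SimTree:
    """Fixed topology with branch lengths plus per-branch rho and omega.

    ``rho`` and ``omega`` map node labels (leaf taxon labels for terminal
    branches, internal node labels for internal branches) to values; the
    per-branch defaults are rho=1 and ``default_omega``.
    """

    newick: str = DEFAULT_NEWICK
    rho: dict[str, float] = field(default_factory=dict)
    omega: dict[str, float] = field(default_factory=dict)
    default_omega: float = 0.2

    def __post_init__(self) -> None:
        for k, v in self.rho.items():
            if not v > 0:
                raise ValueError(f"rho must be > 0 (branch {k!r}: {v})")
        for k, v in self.omega.items():
            if v < 0:
                raise ValueError(f"omega must be >= 0 (branch {k!r}: {v})")
        if self.default_omega < 0:
            raise ValueError("default omega must be >= 0")
        t = self._parse()
        labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for edge in t.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("branch lengths must be >= 0")

    def _parse(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick, schema="newick", preserve_underscores=True
        )

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._parse().leaf_node_iter()]

    def with_terminal_rho(self, species: list[str], rho: float) -> "SimTree":
        """Copy of the tree with ``rho`` applied to the named terminal branches."""
        new = dict(self.rho)
        new.update({sp: rho for sp in species})
        return replace(self, rho=new)

    def edges(self):
        """Preorder (node_key, parent_key, length, rho, omega); root key ''."""
        t = self._parse()
        keys: dict[int, str] = {}
        out = []
        counter = [0]
        for node in t.preorder_node_iter():
            if node.taxon is not None:
                key = node.taxon.label
            elif node.label:
                key = node.label
            elif node.parent_node is None:
                key = ""
            else:
                counter[0] += 1
                key = f"_node{counter[0]}"
            keys[id(node)] = key
            if node.parent_node is None:
                continue
            out.append(
                (
                    key,
                    keys[id(node.parent_node)],
                    float(node.edge.length or 0.0),
                    float(self.rho.get(key, 1.0)),
                    float(self.omega.get(key, self.default_omega)),
                )
            )
        return out


@dataclass
class SimParams:
    """Shared simulation parameters.

    pi is the 61-vector of target sense-codon frequencies (uniform when
    None); pi_nuc the 4-vector of base frequencies for noncoding runs.
    Gene lengths are in codons, scaffold lengths in bases.
    """

    seed: int
    kappa: float = 2.0
    pi: np.ndarray | None = None
    n_genes: int = 1
    gene_length: int = 400
    scaffold_lengths: tuple[int, ...] = (100_000,)
    kappa_nuc: float = 1.0
    pi_nuc: np.ndarray | None = None
    n_convergent_sites: int = 0
    unknown_runs: int = 0
    unknown_run_length: int = 500

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)
            if self.pi.shape != (61,):
                raise ValueError("pi must be a 61-vector over sense codons")
            if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-8:
                raise ValueError("pi must be non-negative and sum to 1")
        if self.pi_nuc is not None:
            self.pi_nuc = np.asarray(self.pi_nuc, dtype=float)
            if self.pi_nuc.shape != (4,) or (self.pi_nuc < 0).any() or abs(self.pi_nuc.sum() - 1) > 1e-8:
                raise ValueError("pi_nuc must be a non-negative 4-vector summing to 1")
        if self.n_genes < 0 or self.gene_length <= 0:
            raise ValueError("gene count must be >= 0 and lengths positive")
        if any(l <= 0 for l in self.scaffold_lengths):
            raise ValueError("scaffold lengths must be positive")


@dataclass
class TruthTable:
    """Ground truth recorded by the simulators."""

    branch_changes: dict[str, int] = field(default_factory=dict)
    convergent_sites: pd.DataFrame | None = None
    cn_regions: pd.DataFrame | None = None
    marker_chromosomes: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Markov machinery


def codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray | None) -> np.ndarray:
    """61x61 instantaneous rate matrix: off-diagonal rates proportional to
    the target frequency, times kappa for transitions and omega for
    nonsynonymous single-base changes; zero for multi-base changes; scaled
    so the mean rate at stationarity is 1."""
    if pi is None:
        pi = np.full(61, 1.0 / 61.0)
    q = np.zeros((61, 61))
    sense = codons.SENSE_CODONS
    for i, c1 in enumerate(sense):
        for pos, b, c2 in codons.codon_neighbors(c1):
            if c2 in codons.STOP_CODONS:
                continue
            j = codons.SENSE_INDEX[c2]
            rate = pi[j]
            if codons.is_transition(c1[pos], b):
                rate *= kappa
            if codons.AMINO_ACID[c1] != codons.AMINO_ACID[c2]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(q))
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix (omega and kappa both zero?)")
    return q / mean_rate


def nucleotide_rate_matrix(kappa: float, pi: np.ndarray | None) -> np.ndarray:
    """4x4 HKY rate matrix (Jukes–Cantor when kappa=1, uniform pi), mean rate 1."""
    if pi is None:
        pi = np.full(4, 0.25)
    bases = codons.BASES
    q = np.zeros((4, 4))
    for i, b1 in enumerate(bases):
        for j, b2 in enumerate(bases):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if codons.is_transition(b1, b2) else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q / -float(pi @ np.diag(q))


def _sample_markov(parent: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw child states given parent states and a transition matrix.

    Exploits the low per-branch substitution probability of the study
    regime: one uniform per site decides stay/move against the diagonal of
    P, and only the (few) moving sites resolve their target state from the
    renormalised off-diagonal row.  Exact, not approximate.
    """
    k = P.shape[0]
    diag = np.ascontiguousarray(np.diag(P))
    u = rng.random(parent.size)
    p_stay = diag[parent]
    child = parent.copy()
    movers = np.nonzero(u >= p_stay)[0]
    if movers.size == 0:
        return child
    # conditional uniform given a move: (u - p_stay) / (1 - p_stay)
    v = (u[movers] - p_stay[movers]) / (1.0 - p_stay[movers])
    mp = parent[movers]
    counts = np.bincount(mp, minlength=k)
    other = np.arange(k)
    for s in np.nonzero(counts)[0]:
        sel = np.nonzero(mp == s)[0]
        row = np.delete(P[s], s)
        targets = np.delete(other, s)
        cum = np.cumsum(row)
        cum /= cum[-1]
        pick = np.searchsorted(cum, v[sel], side="right")
        child[movers[sel]] = targets[np.minimum(pick, k - 2)].astype(
            child.dtype, copy=False
        )
    return child


def _evolve(
    tree: SimTree,
    n_sites: int,
    root_freqs: np.ndarray,
    q_of_omega,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Evolve site-independent states down the tree.

    ``q_of_omega`` maps a branch omega to its (already scaled) rate matrix.
    Returns leaf state arrays and per-branch differing-site counts.
    """
    cum = np.cumsum(root_freqs)
    cum[-1] = 1.0
    dtype = np.uint8 if len(root_freqs) <= 256 else np.int64
    states: dict[str, np.ndarray] = {
        "": np.searchsorted(cum, rng.random(n_sites), side="right").astype(dtype)
    }
    changes: dict[str, int] = {}
    p_cache: dict[tuple[float, float], np.ndarray] = {}
    leaf_set = set(tree.leaf_labels)
    leaves: dict[str, np.ndarray] = {}
    for key, parent, length, rho, omega in tree.edges():
        t_eff = length * rho
        ck = (round(t_eff, 12), round(omega, 12))
        if ck not in p_cache:
            p_cache[ck] = expm(q_of_omega(omega) * t_eff)
        parent_states = states[parent]
        if t_eff == 0.0:
            child = parent_states.copy()
        else:
            child = _sample_markov(parent_states, p_cache[ck], rng)
        changes[key] = int((child != parent_states).sum())
        states[key] = child
        if key in leaf_set:
            leaves[key] = child
    return leaves, changes


# ---------------------------------------------------------------------------
# codon alignments


def simulate_codon_alignment(
    tree: SimTree,
    params: SimParams,
    design: PairDesign | None = None,
) -> tuple[AlignmentSet, list[GeneModel], TruthTable]:
    """Simulate codon-aligned coding genes along ``tree``.

    Each gene is placed on its own scaffold (plus strand, frame 0).  When
    ``params.n_convergent_sites`` > 0 a :class:`PairDesign` is required:
    the chosen columns are overwritten in every mutualist leaf with a codon
    for an amino acid absent from all species at that column, giving a
    known-positive set for the convergence scanner.  Simulated sequences
    contain no stop codons by construction.
    """
    if params.n_genes == 0:
        raise ValueError("zero genes requested")
    rng = np.random.default_rng(params.seed)
    pi = params.pi if params.pi is not None else np.full(61, 1.0 / 61.0)
    q_cache: dict[float, np.ndarray] = {}

    def q_of(omega: float) -> np.ndarray:
        if omega not in q_cache:
            q_cache[omega] = codon_rate_matrix(params.kappa, omega, pi)
        return q_cache[omega]

    n_codons_total = params.n_genes * params.gene_length
    leaves, changes = _evolve(tree, n_codons_total, pi, q_of, rng)

    # planted convergent amino-acid sites, overwritten post hoc on mutualist leaves
    planted = []
    if params.n_convergent_sites:
        if design is None:
            raise ValueError("a PairDesign is required to plant convergent sites")
        aa_by_codon = [codons.AMINO_ACID[c] for c in codons.SENSE_CODONS]
        codons_of_aa: dict[str, list[int]] = {}
        for si, aa in enumerate(aa_by_codon):
            codons_of_aa.setdefault(aa, []).append(si)
        cols = rng.choice(n_codons_total, size=params.n_convergent_sites, replace=False)
        for col in sorted(int(c) for c in cols):
            present = {aa_by_codon[leaves[sp][col]] for sp in leaves}
            absent = sorted(set(codons_of_aa) - present)
            if not absent:  # all 20 residues in use at this column; vanishingly rare
                continue
            aa = absent[int(rng.integers(len(absent)))]
            codon_state = codons_of_aa[aa][int(rng.integers(len(codons_of_aa[aa])))]
            for sp in design.mutualists:
                leaves[sp][col] = codon_state
            gene_i = col // params.gene_length
            planted.append(
                {
                    "gene": f"gene{gene_i + 1:04d}",
                    "codon_column": col % params.gene_length + 1,  # 1-based
                    "residue": aa,
                }
            )

    sense = np.array(codons.SENSE_CODONS)
    sequences: dict[str, dict[str, str]] = {}
    genes: list[GeneModel] = []
    for gi in range(params.n_genes):
        gid = f"gene{gi + 1:04d}"
        lo, hi = gi * params.gene_length, (gi + 1) * params.gene_length
        sequences[gid] = {
            sp: "".join(sense[states[lo:hi]]) for sp, states in leaves.items()
        }
        genes.append(
            GeneModel(gene_id=gid, scaffold=gid,
                      intervals=[(0, 3 * params.gene_length)], strand="+")
        )
    truth = TruthTable(
        branch_changes=changes,
        convergent_sites=pd.DataFrame(
            planted, columns=["gene", "codon_column", "residue"]
        ),
    )
    return AlignmentSet(sequences), genes, truth


# ---------------------------------------------------------------------------
# noncoding alignments


def simulate_noncoding_alignment(
    tree: SimTree, params: SimParams
) -> tuple[AlignmentSet, TruthTable]:
    """Simulate per-scaffold noncoding alignments (4-state model).

    ``params.unknown_runs`` random runs of N per scaffold (in one random
    species each) exercise the window-validity rules downstream.
    """
    rng = np.random.default_rng(params.seed)
    pi = params.pi_nuc if params.pi_nuc is not None else np.full(4, 0.25)
    q = nucleotide_rate_matrix(params.kappa_nuc, pi)
    leaf_labels = tree.leaf_labels
    ascii_bases = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    sequences: dict[str, dict[str, str]] = {}
    changes: dict[str, int] = {}
    for si, length in enumerate(params.scaffold_lengths):
        leaves, ch = _evolve(tree, length, pi, lambda _o: q, rng)
        for k, v in ch.items():
            changes[k] = changes.get(k, 0) + v
        rows = {}
        for sp in leaf_labels:
            arr = ascii_bases[leaves[sp]]
            rows[sp] = arr.tobytes().decode()
        for _ in range(params.unknown_runs):
            sp = leaf_labels[int(rng.integers(len(leaf_labels)))]
            run = min(params.unknown_run_length, length)
            start = int(rng.integers(0, length - run + 1))
            s = rows[sp]
            rows[sp] = s[:start] + "N" * run + s[start + run:]
        sequences[f"scaffold{si + 1:03d}"] = rows
    return AlignmentSet(sequences), TruthTable(branch_changes=changes)


# ---------------------------------------------------------------------------
# read depth


def simulate_read_depth(
    regions: list[tuple[str, int, int, float]],
    mean_depth: float,
    seed: int,
    scaffold_lengths: dict[str, int] | None = None,
) -> tuple[dict[str, np.ndarray], TruthTable]:
    """Per-base Poisson depth with planted copy-number regions.

    ``regions`` lists (scaffold, start, end, copy_number); the diploid
    baseline is CN=2, so per-base counts have mean ``mean_depth * CN / 2``.
    """
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    if scaffold_lengths is None:
        scaffold_lengths = {}
        for scaf, _s, e, _cn in regions:
            scaffold_lengths[scaf] = max(scaffold_lengths.get(scaf, 0), e)
    rng = np.random.default_rng(seed)
    track: dict[str, np.ndarray] = {}
    for scaf, length in scaffold_lengths.items():
        cn = np.full(length, 2.0)
        for rscaf, s, e, rcn in regions:
            if rscaf != scaf:
                continue
            if e <= s:
                raise ValueError(f"zero-length region [{s},{e}) on {scaf}")
            cn[s:e] = rcn
        track[scaf] = rng.poisson(mean_depth * cn / 2.0)
    truth = TruthTable(
        cn_regions=pd.DataFrame(regions, columns=["scaffold", "start", "end", "cn"])
    )
    return track, truth


def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Write a depth track as bedGraph (runs of equal depth merged)."""
    with open(path, "w") as fh:
        for scaf in sorted(track):
            d = track[scaf]
            if d.size == 0:
                continue
            breaks = np.nonzero(np.diff(d))[0] + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [d.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{scaf}\t{s}\t{e}\t{d[s]}\n")


def read_bedgraph(path) -> dict[str, np.ndarray]:
    """Read a bedGraph depth track into per-base arrays."""
    rows: dict[str, list[tuple[int, int, float]]] = {}
    for line in open(path):
        if not line.strip() or line.startswith(("track", "#")):
            continue
        scaf, s, e, v = line.split()[:4]
        rows.setdefault(scaf, []).append((int(s), int(e), float(v)))
    out = {}
    for scaf, ivs in rows.items():
        length = max(e for _s, e, _v in ivs)
        arr = np.zeros(length)
        for s, e, v in ivs:
            arr[s:e] = v
        out[scaf] = arr
    return out


# ---------------------------------------------------------------------------
# mapping population


def haldane_rf(d_cm: float) -> float:
    """Recombinant fraction for a map distance in cM (Haldane map function)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def simulate_mapping_population(
    n_offspring: int,
    chromosomes: dict[str, list[float]],
    seed: int,
) -> tuple[pd.DataFrame, TruthTable]:
    """Single-family mapping population: heterozygous queen, haploid father.

    ``chromosomes`` maps chromosome name to marker positions in cM.  The
    queen is heterozygous at every marker by construction; each diploid
    offspring inherits one maternal allele per marker, with recombination
    between adjacent markers per the Haldane map function.  Offspring are
    coded 0/1 by which maternal allele they carry (0 = the phase matching
    the paternal allele, observationally a homozygous genotype).

    Returns (markers x offspring DataFrame of 0/1 codes, truth with the
    chromosome of each marker).
    """
    if n_offspring < 2:
        raise ValueError("need at least 2 offspring")
    rng = np.random.default_rng(seed)
    rows = {}
    chrom_of = {}
    for chrom, positions in chromosomes.items():
        if len(positions) == 0:
            raise ValueError(f"chromosome {chrom} has no markers")
        positions = sorted(positions)
        gam = rng.integers(0, 2, size=n_offspring)
        for mi, pos in enumerate(positions):
            if mi > 0:
                r = haldane_rf(pos - positions[mi - 1])
                flip = rng.random(n_offspring) < r
                gam = np.where(flip, 1 - gam, gam)
            mid = f"{chrom}_m{mi + 1:02d}"
            rows[mid] = gam.copy()
            chrom_of[mid] = chrom
    matrix = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=[f"w{i + 1:02d}" for i in range(n_offspring)])
    return matrix, TruthTable(marker_chromosomes=chrom_of)


# ---------------------------------------------------------------------------
# expression


def simulate_expression_matrix(
    n_genes: int,
    n_tissues: int = 29,
    fast_gene_ids: list[int] | None = None,
    head_shift: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x tissue expression matrix with an optional head-tissue shift.

    Baseline expression is Gamma(2, 1) i.i.d.; the first tissue is "head"
    and designated fast genes have their head expression multiplied by
    (1 + head_shift), so head_shift=0 is an exact null.
    """
    if head_shift < 0:
        raise ValueError("head_shift must be >= 0")
    fast = list(fast_gene_ids or [])
    if any(i < 0 or i >= n_genes for i in fast):
        raise ValueError("fast_gene_ids outside gene range")
    rng = np.random.default_rng(seed)
    x = rng.gamma(shape=2.0, scale=1.0, size=(n_genes, n_tissues))
    if fast:
        x[fast, 0] *= 1.0 + head_shift
    tissues = ["head", "ovary"] + [f"tissue{i:02d}" for i in range(3, n_tissues + 1)]
    return pd.DataFrame(
        x, index=[f"g{i + 1:05d}" for i in range(n_genes)], columns=tissues[:n_tissues]
    )
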