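"""Sliding-window genetic distances, window trees, and neutral-locus sampling.

Distances are p-distances — the proportion of pairwise-comparable (both
sequences known) sites that differ — computed against the reference species,
matching the "proportion of segregating sites from the outgroup" framing of
the genome-wide window analysis.  IUPAC ambiguity codes count as known; two
sites differ iff their allele sets are disjoint, so a heterozygote sharing
an allele with the reference is not a difference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentSet, GeneModel

__all__ = [
    "Window",
    "make_windows",
    "p_distance",
    "window_table",
    "nj_tree",
    "TopologyCensus",
    "topology_census",
    "sample_neutral_loci",
]

# 4-bit allele masks: N, gaps and anything else are 0 (unknown)
_MASK_LUT = np.zeros(256, dtype=np.uint8)
_ALLELES = {"A": 1, "C": 2, "G": 4, "T": 8}
from Bio.Data.IUPACData import ambiguous_dna_values as _amb

for _code, _bases in _amb.items():
    if _code == "X" or len(_bases) == 4:
        continue
    _MASK_LUT[ord(_code)] = np.bitwise_or.reduce([_ALLELES[b] for b in _bases])
for _b, _v in _ALLELES.items():
    _MASK_LUT[ord(_b)] = _v


def _allele_masks(seq: str) -> np.ndarray:
    return _MASK_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class Window:
    scaffold: str
    start: int
    end: int
    known_fraction: dict[str, float] = field(default_factory=dict)
    valid: bool = True


def make_windows(
    aln: AlignmentSet, size: int = 25_000, step: int = 5_000, min_known: float = 0.5
) -> list[Window]:
    """Tile each scaffold with fixed-size windows at the given step.

    Windows start at 0, step, 2*step, ... with start+size <= scaffold
    length (no shorter trailing window).  A window is valid only when every
    species has known sequence over at least ``min_known`` of its length.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    out: list[Window] = []
    for scaf in aln.scaffolds:
        L = aln.scaffold_length(scaf)
        if L < size:
            continue
        known_cum = {
            sp: np.concatenate([[0], np.cumsum(_allele_masks(s) > 0)])
            for sp, s in aln.sequences[scaf].items()
        }
        for start in range(0, L - size + 1, step):
            kf = {
                sp: float((c[start + size] - c[start]) / size)
                for sp, c in known_cum.items()
            }
            out.append(
                Window(scaffold=scaf, start=start, end=start + size,
                       known_fraction=kf,
                       valid=all(v >= min_known for v in kf.values()))
            )
    return out


def p_distance(seq1: str, seq2: str) -> float:
    """Proportion of both-known sites that differ; NaN when none comparable."""
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    m1, m2 = _allele_masks(seq1), _allele_masks(seq2)
    comparable = (m1 > 0) & (m2 > 0)
    denom = int(comparable.sum())
    if denom == 0:
        return float("nan")
    diff = int((comparable & ((m1 & m2) == 0)).sum())
    return diff / denom


def window_table(
    aln: AlignmentSet, windows: list[Window], reference: str
) -> pd.DataFrame:
    """Per-window, per-species p-distance to the reference species.

    Rows: (scaffold, start, end, species, distance, valid).  A row is
    invalid when the window itself failed the known-fraction rule or when no
    site is comparable (distance NaN).
    """
    if not windows:
        return pd.DataFrame(
            columns=["scaffold", "start", "end", "species", "distance", "valid"]
        )
    rows = []
    for scaf in {w.scaffold for w in windows}:
        seqs = aln.sequences[scaf]
        if reference not in seqs:
            raise ValueError(f"reference species {reference!r} absent from {scaf}")
        mref = _allele_masks(seqs[reference])
        for sp, s in seqs.items():
            if sp == reference:
                continue
            msp = _allele_masks(s)
            comparable = (mref > 0) & (msp > 0)
            diff = comparable & ((mref & msp) == 0)
            ccum = np.concatenate([[0], np.cumsum(comparable)])
            dcum = np.concatenate([[0], np.cumsum(diff)])
            for w in windows:
                if w.scaffold != scaf:
                    continue
                denom = int(ccum[w.end] - ccum[w.start])
                dist = (dcum[w.end] - dcum[w.start]) / denom if denom else float("nan")
                rows.append(
                    {
                        "scaffold": scaf, "start": w.start, "end": w.end,
                        "species": sp, "distance": dist,
                        "valid": bool(w.valid and denom > 0),
                    }
                )
    return pd.DataFrame(rows)


def all_pairs_distance_matrix(
    aln: AlignmentSet, scaffold: str, start: int | None = None, end: int | None = None
) -> pd.DataFrame:
    """Symmetric p-distance matrix over all species for one window/scaffold."""
    seqs = aln.sequences[scaffold]
    sl = slice(start, end)
    species = sorted(seqs)
    n = len(species)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(seqs[species[i]][sl], seqs[species[j]][sl])
            m[i, j] = m[j, i] = d
    return pd.DataFrame(m, index=species, columns=species)


def nj_tree(dm: pd.DataFrame) -> str:
    """Neighbor-joining tree (newick) from a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero.  NJ is consistent
    on additive distances, so the generating topology (and, for additive
    input, the exact branch lengths) are recovered.
    """
    mat = np.asarray(dm, dtype=float)
    if np.isnan(mat).any():
        raise ValueError("distance matrix contains NaN")
    if mat.shape[0] != mat.shape[1] or mat.shape[0] < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(mat, ids=list(dm.index)), neg_as_zero=True)
    return tree.__str__().strip()


# ---------------------------------------------------------------------------
# topology census


def _canonical_splits(newick: str) -> tuple[frozenset, frozenset[frozenset]]:
    """(leaf set, canonical non-trivial splits) of one newick string.

    Each split is represented by its side not containing the alphabetically
    first leaf, which makes the encoding invariant to rooting and child
    order; branch lengths are ignored.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(leaves)
    n = len(leaves)
    splits = set()
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if anchor not in below else leaves - below
        if 1 < len(side) < n - 1:
            splits.add(side)
    return leaves, frozenset(splits)


def _split_key(splits: frozenset[frozenset]) -> str:
    parts = sorted(",".join(sorted(s)) for s in splits)
    return ";".join(parts)


@dataclass
class TopologyCensus:
    counts: Counter
    total: int
    clade_present_count: int
    reference_count: int

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    @property
    def most_common(self) -> tuple[str, int]:
        return self.counts.most_common(1)[0]


def topology_census(
    newicks: list[str],
    reference_topology: str | None = None,
    focal_clade: set[str] | None = None,
) -> TopologyCensus:
    """Census of unrooted topologies over a set of newick trees.

    Counts canonical topologies (branch lengths and rooting ignored), how
    many trees match ``reference_topology``, and how many contain the
    ``focal_clade`` as an unrooted split (e.g. all mutualists together,
    no generalists).
    """
    counts: Counter = Counter()
    clade_n = 0
    leafset = None
    keys = []
    for nwk in newicks:
        leaves, splits = _canonical_splits(nwk)
        if leafset is None:
            leafset = leaves
        elif leaves != leafset:
            raise ValueError("trees have differing leaf sets")
        key = _split_key(splits)
        counts[key] += 1
        keys.append((splits, leaves))
    if focal_clade is not None and leafset is not None:
        focal = frozenset(focal_clade)
        anchor = min(leafset)
        focal_side = focal if anchor not in focal else leafset - focal
        for splits, leaves in keys:
            if focal_side in splits:
                clade_n += 1
    ref_n = 0
    if reference_topology is not None:
        _, ref_splits = _canonical_splits(reference_topology)
        ref_key = _split_key(ref_splits)
        ref_n = counts.get(ref_key, 0)
    return TopologyCensus(
        counts=counts, total=len(newicks),
        clade_present_count=clade_n, reference_count=ref_n,
    )


# ---------------------------------------------------------------------------
# neutral-locus sampling


def sample_neutral_loci(
    aln: AlignmentSet,
    genes: list[GeneModel],
    repeat_mask: dict[str, list[tuple[int, int]]] | None = None,
    locus_len: int = 500,
    min_gap: int = 15_000,
    cds_flank: int = 5_000,
    min_species: int = 4,
    max_missing: float = 0.20,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Greedy left-to-right sampling of putatively neutral loci.

    Candidate loci of ``locus_len`` bases must avoid repeat-masked bases and
    coding sequence with its ``cds_flank`` buffer entirely, lie at least
    ``min_gap`` bases from the previously accepted locus, and have at least
    ``min_species`` species present (a species is present iff its unknown +
    gap fraction is <= ``max_missing``).
    """
    repeat_mask = repeat_mask or {}
    species = species or aln.species
    rows = []
    for scaf in aln.scaffolds:
        L = aln.scaffold_length(scaf)
        forbidden = np.zeros(L, dtype=bool)
        for s, e in repeat_mask.get(scaf, []):
            forbidden[max(0, s) : min(L, e)] = True
        for g in genes:
            if g.scaffold != scaf:
                continue
            for s, e in g.intervals:
                forbidden[max(0, s - cds_flank) : min(L, e + cds_flank)] = True
        forb_idx = np.nonzero(forbidden)[0]
        kcums = {
            sp: np.concatenate([[0], np.cumsum(_allele_masks(aln.sequences[scaf][sp]) > 0)])
            for sp in species
        }
        pos = 0
        while pos + locus_len <= L:
            # jump past the last forbidden base overlapping the candidate
            j = np.searchsorted(forb_idx, pos + locus_len, side="left")
            i = np.searchsorted(forb_idx, pos, side="left")
            if j > i:
                pos = int(forb_idx[j - 1]) + 1
                continue
            present = sum(
                1
                for sp in species
                if 1 - (kcums[sp][pos + locus_len] - kcums[sp][pos]) / locus_len
                <= max_missing
            )
            if present >= min_species:
                rows.append(
                    {"scaffold": scaf, "start": pos, "end": pos + locus_len,
                     "n_present": present}
                )
                pos += locus_len + min_gap
            else:
                pos += 1
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_present"])
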