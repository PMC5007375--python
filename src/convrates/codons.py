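"""Genetic-code tables and codon-level machinery shared across the package.

Codons are indexed 0..63 as ``16*A + 4*C + G`` over the base order A,C,G,T.
All tables are built once at import from Biopython's standard nuclear code
(table 1); stop codons (TAA/TAG/TGA) are excluded from the sense state space.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
AMINO_ACID: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(ALL_CODONS)}
SENSE_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: transitions are A<->G and C<->T
_PURINES = {"A", "G"}


def is_transition(b1: str, b2: str) -> bool:
    return b1 != b2 and ((b1 in _PURINES) == (b2 in _PURINES))


def codon_neighbors(codon: str):
    """Yield (position, new_base, new_codon) for the 9 single-base mutants."""
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                yield pos, b, codon[:pos] + b + codon[pos + 1 :]


def _site_counts_one(codon: str) -> float:
    """Synonymous site count of one sense codon.

    Per position, the synonymous fraction of the three single-base changes,
    with changes into stop codons removed from the denominator; nonsynonymous
    sites are the complement so S + N = 3 per codon.
    """
    s = 0.0
    aa = AMINO_ACID[codon]
    for pos in range(3):
        syn = 0
        usable = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            usable += 1
            if AMINO_ACID[mut] == aa:
                syn += 1
        if usable:
            s += syn / usable
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are discarded, the rest weighted equally.  Returns
    None when every pathway is blocked.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot = 0.0
    non_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AMINO_ACID[cur] == AMINO_ACID[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_tot += syn
            non_tot += non
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_tot / n_paths, non_tot / n_paths


@lru_cache(maxsize=1)
def ng86_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(S64, SD64, ND64): per-codon synonymous sites and pairwise pathway
    counts over the 64-codon index space; NaN marks stops/blocked pairs."""
    s64 = np.full(64, np.nan)
    for c in SENSE_CODONS:
        s64[CODON_INDEX[c]] = _site_counts_one(c)
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for c1 in SENSE_CODONS:
        i = CODON_INDEX[c1]
        for c2 in SENSE_CODONS:
            j = CODON_INDEX[c2]
            res = _pathway_counts(c1, c2)
            if res is not None:
                sd[i, j], nd[i, j] = res
    return s64, sd, nd


def encode_codons(seq: str) -> np.ndarray:
    """Codon index array for a nucleotide string; -1 for codons containing
    anything outside A/C/G/T.  Length must be a multiple of 3."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    b = lut[arr].reshape(-1, 3)
    idx = 16 * b[:, 0] + 4 * b[:, 1] + b[:, 2]
    idx[(b < 0).any(axis=1)] = -1
    return idx


STOP_INDICES = frozenset(CODON_INDEX[c] for c in STOP_CODONS)
_SENSE_MASK64 = np.zeros(64, dtype=bool)
for _c in SENSE_CODONS:
    _SENSE_MASK64[CODON_INDEX[_c]] = True


def sense_mask(idx: np.ndarray) -> np.ndarray:
    """Boolean mask of codon indices that are valid sense codons."""
    ok = idx >= 0
    out = np.zeros(idx.shape, dtype=bool)
    out[ok] = _SENSE_MASK64[idx[ok]]
    return out


def translate_codon_indices(idx: np.ndarray) -> str:
    """Amino-acid string; 'X' for invalid codons, '*' for stops."""
    aas = np.full(64, "X", dtype="<U1")
    for c in SENSE_CODONS:
        aas[CODON_INDEX[c]] = AMINO_ACID[c]
    for c in STOP_CODONS:
        aas[CODON_INDEX[c]] = "*"
    out = np.full(idx.shape, "X", dtype="<U1")
    ok = idx >= 0
    out[ok] = aas[idx[ok]]
    return "".join(out)
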