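"""Genome-scale rule engines: NuMt counting, copy number, TE filtering.

These operate on externally produced tables (homology hits in BLAST
outfmt-6-like form, per-base depth tracks) and apply fixed published-style
thresholds; the value here is that each rule is explicit, logged and
testable on toy tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PairDesign

__all__ = [
    "numt_count",
    "cn_estimate",
    "duplication_consistency",
    "te_filter",
    "read_blast_tab",
]

#: standard outfmt-6 column names
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path) -> pd.DataFrame:
    """Read a BLAST tabular (outfmt 6) file."""
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")


def numt_count(
    hits: pd.DataFrame,
    seed_lengths: dict[str, int],
    e_max: float = 1e-20,
    min_cov: float = 0.35,
) -> dict:
    """Count nuclear copies of mitochondrial genes from homology hits.

    A hit counts as an introgression of its query gene iff its e-value is
    below ``e_max`` and its alignment span covers at least ``min_cov`` of
    the seed sequence length.  Returns per-gene counts, the genome total,
    and the number of genes with at least one copy.  Malformed rows
    (missing fields, negative values, unknown seeds) are skipped and
    counted.
    """
    per_gene: dict[str, int] = {}
    skipped = 0
    for _, row in hits.iterrows():
        try:
            q = str(row["qseqid"])
            e = float(row["evalue"])
            span = float(row["length"])
            seed_len = seed_lengths[q]
        except (KeyError, TypeError, ValueError):
            skipped += 1
            continue
        if not np.isfinite(e) or e < 0 or span <= 0 or seed_len <= 0:
            skipped += 1
            continue
        if e < e_max and span / seed_len >= min_cov:
            per_gene[q] = per_gene.get(q, 0) + 1
    return {
        "per_gene": per_gene,
        "total": sum(per_gene.values()),
        "genes_with_copy": len(per_gene),
        "n_skipped": skipped,
    }


def cn_estimate(
    depth: dict[str, np.ndarray],
    regions: list[tuple[str, int, int]],
    mask: dict[str, list[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Depth-based copy number per region on the diploid scale.

    CN = 2 * (region mean depth) / (genome-wide median depth), both over
    unmasked positions.  Fully masked regions get CN NaN with
    ``defined=False``.
    """
    mask = mask or {}
    unmasked_all = []
    masked_bool: dict[str, np.ndarray] = {}
    for scaf, d in depth.items():
        m = np.zeros(d.size, dtype=bool)
        for s, e in mask.get(scaf, []):
            m[max(0, s) : min(d.size, e)] = True
        masked_bool[scaf] = m
        unmasked_all.append(d[~m])
    genome_median = float(np.median(np.concatenate(unmasked_all)))
    if genome_median <= 0:
        raise ValueError("genome-wide median depth is zero")
    rows = []
    for scaf, s, e in regions:
        d = depth[scaf][s:e]
        m = masked_bool[scaf][s:e]
        usable = d[~m]
        if usable.size == 0:
            rows.append({"scaffold": scaf, "start": s, "end": e,
                         "cn": float("nan"), "defined": False})
        else:
            rows.append(
                {"scaffold": scaf, "start": s, "end": e,
                 "cn": 2.0 * float(usable.mean()) / genome_median,
                 "defined": True}
            )
    return pd.DataFrame(rows)


def duplication_consistency(
    cn: pd.DataFrame,
    design: PairDesign,
    cn_min: float = 1.5,
    fold: float = 1.5,
) -> tuple[pd.DataFrame, int]:
    """Flag regions consistently amplified in one life-history class.

    ``cn`` has one row per region with one copy-number column per ingroup
    species.  A region is mutualist-amplified iff every mutualist CN is at
    least ``cn_min`` AND at least ``fold`` times every generalist CN;
    symmetrically for generalists (the classes are mutually exclusive).
    Regions with any missing species are skipped and counted.
    """
    design.validate_against(list(cn.columns) + [design.outgroup])
    muts, gens = design.mutualists, design.generalists
    complete = cn[muts + gens].dropna()
    n_skipped = len(cn) - len(complete)
    m = complete[muts].to_numpy(float)
    g = complete[gens].to_numpy(float)
    m_min, m_max = m.min(axis=1), m.max(axis=1)
    g_min, g_max = g.min(axis=1), g.max(axis=1)
    mut_amp = (m_min >= cn_min) & (m_min >= fold * g_max)
    gen_amp = (g_min >= cn_min) & (g_min >= fold * m_max)
    out = complete.copy()
    out["class"] = np.where(mut_amp, "mutualist-amplified",
                            np.where(gen_amp, "generalist-amplified", "none"))
    return out, n_skipped


@dataclass
class TEFilterResult:
    retained: list[str]
    removal_log: pd.DataFrame  # columns: candidate, rule


def te_filter(
    lengths: dict[str, int],
    protein_hits: pd.DataFrame | None = None,
    identity_pairs: pd.DataFrame | None = None,
    min_length: int = 80,
    bit_max: float = 100.0,
    sim_threshold: float = 0.50,
    cov_threshold: float = 0.50,
    cluster_identity: float = 0.80,
    cluster_coverage: float = 0.80,
) -> TEFilterResult:
    """Filter transposable-element candidate sequences.

    Rules applied in order, each removal logged with the first rule hit:

    1. redundancy: candidates at least ``cluster_identity`` similar over
       ``cluster_coverage`` of their length (from ``identity_pairs`` with
       columns query, subject, identity, coverage) are clustered and each
       cluster represented by its single longest member;
    2. length: candidates shorter than ``min_length`` bases removed;
    3. protein similarity: candidates whose best hit (``protein_hits`` with
       columns candidate, bitscore, similarity, coverage) has bit score >=
       ``bit_max`` or similarity >= ``sim_threshold`` over >=
       ``cov_threshold`` of the sequence are removed as false positives.
    """
    log_rows = []
    alive = set(lengths)

    # 1. dedupe via union-find over qualifying pairs
    parent = {c: c for c in alive}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    if identity_pairs is not None and len(identity_pairs):
        for _, row in identity_pairs.iterrows():
            a, b = str(row["query"]), str(row["subject"])
            if a == b or a not in alive or b not in alive:
                continue
            if float(row["identity"]) >= cluster_identity and float(row["coverage"]) >= cluster_coverage:
                parent[find(a)] = find(b)
        clusters: dict[str, list[str]] = {}
        for c in alive:
            clusters.setdefault(find(c), []).append(c)
        for members in clusters.values():
            if len(members) == 1:
                continue
            keep = max(members, key=lambda c: (lengths[c], c))
            for c in members:
                if c != keep:
                    alive.discard(c)
                    log_rows.append({"candidate": c, "rule": "redundant"})

    # 2. length cutoff
    for c in sorted(alive):
        if lengths[c] < min_length:
            alive.discard(c)
            log_rows.append({"candidate": c, "rule": "length"})

    # 3. protein similarity
    if protein_hits is not None and len(protein_hits):
        for _, row in protein_hits.iterrows():
            c = str(row["candidate"])
            if c not in alive:
                continue
            if float(row["bitscore"]) >= bit_max or (
                float(row["similarity"]) >= sim_threshold
                and float(row["coverage"]) >= cov_threshold
            ):
                alive.discard(c)
                log_rows.append({"candidate": c, "rule": "protein"})

    return TEFilterResult(
        retained=sorted(alive),
        removal_log=pd.DataFrame(log_rows, columns=["candidate", "rule"]),
    )
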