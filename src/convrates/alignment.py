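"""Species-alignment container, gene extraction, and the consensus/QC rules.

The whole-genome alignment is stored in reference coordinates: one scaffold
maps to one equal-length row per species over the alphabet A,C,G,T,N,`-`
plus IUPAC ambiguity codes (heterozygous consensus sites).  Coordinates are
0-based half-open throughout; GFF3's 1-based inclusive convention is
converted at the file boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

KNOWN_BASES = set("ACGT")
AMBIGUITY_CODES = {c for c, v in ambiguous_dna_values.items() if 1 < len(v) < 4}
ALLOWED = KNOWN_BASES | AMBIGUITY_CODES | {"N", "-"}
#: heterozygous base pair -> IUPAC code
IUPAC_OF_PAIR = {
    frozenset(v): c for c, v in ambiguous_dna_values.items() if len(v) == 2
}


@dataclass
class AlignmentSet:
    """scaffold id -> (species label -> aligned sequence)."""

    sequences: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        species = None
        for scaf, rows in self.sequences.items():
            lens = {len(s) for s in rows.values()}
            if len(lens) > 1:
                raise ValueError(f"unequal row lengths on scaffold {scaf}: {lens}")
            sp = frozenset(rows)
            if species is None:
                species = sp
            elif sp != species:
                raise ValueError(f"species set differs on scaffold {scaf}")

    @property
    def species(self) -> list[str]:
        first = next(iter(self.sequences.values()))
        return sorted(first)

    @property
    def scaffolds(self) -> list[str]:
        return list(self.sequences)

    def scaffold_length(self, scaffold: str) -> int:
        return len(next(iter(self.sequences[scaffold].values())))


def _clean(seq: str) -> tuple[str, int]:
    """Uppercase and map disallowed symbols to N; return (seq, n_mapped)."""
    seq = seq.upper()
    bad = set(seq) - ALLOWED
    if not bad:
        return seq, 0
    n = sum(seq.count(b) for b in bad)
    table = str.maketrans({b: "N" for b in bad})
    return seq.translate(table), n


def load_alignment(
    fasta_paths: list[str | Path], species_map: dict[str, str] | None = None
) -> AlignmentSet:
    """Load one FASTA per scaffold (record ids are species labels).

    Scaffold ids are the file stems.  Symbols outside the allowed alphabet
    are mapped to N with a warning.  ``species_map`` optionally renames
    record ids.
    """
    sequences: dict[str, dict[str, str]] = {}
    total_mapped = 0
    for path in fasta_paths:
        path = Path(path)
        rows: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            name = (species_map or {}).get(rec.id, rec.id)
            seq, n = _clean(str(rec.seq))
            total_mapped += n
            rows[name] = seq
        if not rows:
            raise ValueError(f"no records in {path}")
        sequences[path.stem] = rows
    if total_mapped:
        warnings.warn(f"{total_mapped} unknown symbols mapped to N", stacklevel=2)
    return AlignmentSet(sequences)


def write_alignment(aln: AlignmentSet, outdir: str | Path) -> list[Path]:
    """Write one FASTA per scaffold under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for scaf, rows in aln.sequences.items():
        path = outdir / f"{scaf}.fa"
        recs = [SeqRecord(Seq(s), id=sp, description="") for sp, s in sorted(rows.items())]
        SeqIO.write(recs, str(path), "fasta")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """CDS layout of one gene in reference coordinates (0-based half-open)."""

    gene_id: str
    scaffold: str
    intervals: list[tuple[int, int]]
    strand: str = "+"
    frame: int = 0

    def __post_init__(self) -> None:
        iv = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        self.intervals = iv
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (CDS features grouped by Parent/ID) or
    from 6-column BED with an optional 7th frame column."""
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed6"}:
        return _load_bed(path)
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    for cds in db.features_of_type("CDS"):
        parent = (cds.attributes.get("Parent") or cds.attributes.get("ID") or ["?"])[0]
        frame = int(cds.frame) if cds.frame not in (None, ".") else 0
        g = genes.get(parent)
        if g is None:
            genes[parent] = GeneModel(
                gene_id=parent, scaffold=cds.seqid,
                intervals=[(cds.start - 1, cds.end)], strand=cds.strand,
                frame=frame,
            )
        else:
            g.intervals.append((cds.start - 1, cds.end))
            g.__post_init__()
    return list(genes.values())


def _load_bed(path: Path) -> list[GeneModel]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        frame = int(f[6]) if len(f) > 6 else 0
        out.append(
            GeneModel(gene_id=f[3], scaffold=f[0],
                      intervals=[(int(f[1]), int(f[2]))], strand=f[5], frame=frame)
        )
    return out


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (one gene + CDS features per model)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = min(s for s, _ in g.intervals) + 1
            end = max(e for _, e in g.intervals)
            fh.write(
                f"{g.scaffold}\tconvrates\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for s, e in g.intervals:
                fh.write(
                    f"{g.scaffold}\tconvrates\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{g.frame}\tParent={g.gene_id}\n"
                )


@dataclass
class GeneAlignment:
    """Codon-aligned per-species sequences of one gene."""

    gene_id: str
    seqs: dict[str, str]
    missing_fraction: dict[str, float] = field(default_factory=dict)
    masked_codons: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.seqs.values()}
        if len(lens) > 1:
            raise ValueError(f"unequal sequence lengths in gene {self.gene_id}")
        self.length = lens.pop() if lens else 0
        if self.length % 3:
            raise ValueError(f"gene {self.gene_id} length {self.length} not codon-sized")
        if not self.missing_fraction:
            self.missing_fraction = {
                sp: _missing_fraction(s) for sp, s in self.seqs.items()
            }

    @property
    def n_codons(self) -> int:
        return self.length // 3


def _missing_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    known = sum(seq.count(b) for b in KNOWN_BASES)
    return 1.0 - known / len(seq)


def extract_gene(aln: AlignmentSet, gene: GeneModel) -> GeneAlignment:
    """Pull a gene's spliced CDS from the alignment; minus-strand genes are
    reverse-complemented (N and IUPAC codes complement correctly)."""
    L = aln.scaffold_length(gene.scaffold)
    for s, e in gene.intervals:
        if s < 0 or e > L:
            raise ValueError(
                f"{gene.gene_id}: interval [{s},{e}) outside scaffold "
                f"{gene.scaffold} of length {L}"
            )
    seqs = {}
    for sp, row in aln.sequences[gene.scaffold].items():
        cds = "".join(row[s:e] for s, e in gene.intervals)
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        if gene.frame:
            cds = cds[gene.frame:]
        if len(cds) % 3:
            raise ValueError(f"{gene.gene_id}: CDS length {len(cds)} not a multiple of 3")
        seqs[sp] = cds
    return GeneAlignment(gene_id=gene.gene_id, seqs=seqs)


# ---------------------------------------------------------------------------
# consensus calling


def consensus_call(
    genotype: str | None,
    n_alleles: int,
    depth: int,
    ref: str,
    het_policy: str = "iupac",
) -> str:
    """Consensus base for one site of a reference-mapped assembly.

    Rules: sites with more than three alleles are unknown; a diploid
    genotype call is emitted directly (heterozygous biallelic sites become
    IUPAC ambiguity codes, or N under ``het_policy='mask'``); without a call
    the reference base is emitted only at depth >= 5, otherwise N.
    """
    if depth < 0:
        raise ValueError("negative depth")
    if het_policy not in ("iupac", "mask"):
        raise ValueError(f"unknown het policy {het_policy!r}")
    if n_alleles > 3:
        return "N"
    if genotype:
        alleles = sorted(set(genotype.upper()))
        if len(alleles) == 1:
            return alleles[0]
        if len(alleles) == 2:
            if het_policy == "mask":
                return "N"
            return IUPAC_OF_PAIR[frozenset(alleles)]
        return "N"
    return ref.upper() if depth >= 5 else "N"


# ---------------------------------------------------------------------------
# gene-level QC


@dataclass
class QCResult:
    gene_id: str
    passed: bool
    reasons: list[str]
    n_masked_columns: int
    alignment: GeneAlignment


def gene_qc(
    g: GeneAlignment,
    species_count_required: int = 7,
    min_codons: int = 300,
    max_missing: float = 0.20,
) -> QCResult:
    """Apply the gene-level quality rules and mask premature-stop columns.

    A gene passes if it has the required species count, at least
    ``min_codons`` codons, and every sequence has under ``max_missing``
    missing data.  Any codon column containing an in-frame stop in any
    species is masked to NNN across all species (misalignment artefacts);
    masking alone never fails a gene.  Idempotent.
    """
    reasons = []
    if len(g.seqs) != species_count_required:
        reasons.append("species")
    if g.n_codons < min_codons:
        reasons.append("length")
    if any(f >= max_missing for f in g.missing_fraction.values()):
        reasons.append("missing")

    from . import codons as _codons

    stop_cols: set[int] = set()
    idx = {sp: _codons.encode_codons(s) for sp, s in g.seqs.items()}
    for sp, arr in idx.items():
        for col in np.where(np.isin(arr, list(_codons.STOP_INDICES)))[0]:
            stop_cols.add(int(col))
    if stop_cols:
        new_seqs = {}
        for sp, s in g.seqs.items():
            chars = list(s)
            for col in stop_cols:
                chars[3 * col : 3 * col + 3] = "NNN"
            new_seqs[sp] = "".join(chars)
        masked = GeneAlignment(gene_id=g.gene_id, seqs=new_seqs,
                               masked_codons=sorted(stop_cols))
    else:
        masked = g
    return QCResult(
        gene_id=g.gene_id, passed=not reasons, reasons=reasons,
        n_masked_columns=len(stop_cols), alignment=masked,
    )


def mask_columns(g: GeneAlignment, policy: str = "drop-gap-columns") -> GeneAlignment:
    """Column masking for unconserved/gapped regions (codon-wise).

    ``drop-gap-columns`` removes every codon column containing a gap in any
    species (a deliberately simple proxy for alignment-block filtering);
    ``none`` is the identity.
    """
    if policy == "none":
        return g
    if policy != "drop-gap-columns":
        raise ValueError(f"unknown mask policy {policy!r}")
    n = g.n_codons
    drop = set()
    for s in g.seqs.values():
        for col in range(n):
            if "-" in s[3 * col : 3 * col + 3]:
                drop.add(col)
    if not drop:
        return g
    keep = [c for c in range(n) if c not in drop]
    new_seqs = {
        sp: "".join(s[3 * c : 3 * c + 3] for c in keep) for sp, s in g.seqs.items()
    }
    return GeneAlignment(gene_id=g.gene_id, seqs=new_seqs,
                         masked_codons=sorted(drop))
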