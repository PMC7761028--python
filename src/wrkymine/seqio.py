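"""Sequence and annotation I/O: FASTA, GFF3, Newick, catalog TSV, promoter extraction.

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted at the parsing boundary.  Promoter offsets reported
to users are negative integers with -1 denoting the base immediately upstream
of the A of the start codon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

DNA_CHARS = set("ACGTUNRYSWKMBDHV")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named residue sequence with a declared alphabet ('dna' or 'protein')."""

    id: str
    residues: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self, strict: bool = False) -> None:
        allowed = DNA_CHARS if self.alphabet == "dna" else PROTEIN_CHARS
        if strict and self.alphabet == "dna":
            allowed = set("ACGT")
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal {self.alphabet} character(s) "
                f"{sorted(bad)}")


@dataclass
class GeneModel:
    """One transcript: strand-aware exon and CDS intervals on a contig.

    Intervals are 0-based half-open, sorted ascending, non-overlapping.
    """

    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParseError(
                f"transcript {self.transcript_id!r}: unknown strand {self.strand!r}")
        if not self.exons:
            raise ParseError(f"transcript {self.transcript_id!r}: no exons")
        for ivs in (self.exons, self.cds):
            for (s, e) in ivs:
                if not (0 <= s < e):
                    raise ParseError(
                        f"transcript {self.transcript_id!r}: bad interval {(s, e)}")
            for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ParseError(
                        f"transcript {self.transcript_id!r}: overlapping/unsorted "
                        f"intervals")

    @property
    def cds_span(self) -> tuple[int, int]:
        if not self.cds:
            raise ValueError(f"transcript {self.transcript_id!r} has no CDS")
        return self.cds[0][0], self.cds[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GenomeBundle:
    """Contigs + gene models + proteome, as one unit of analysis."""

    contigs: dict[str, SequenceRecord]
    genes: list[GeneModel]
    proteome: dict[str, SequenceRecord]

    def validate(self) -> None:
        for g in self.genes:
            if g.seq_id not in self.contigs:
                raise ValueError(f"gene {g.gene_id}: contig {g.seq_id!r} missing")
            if g.cds and g.protein_id is not None and g.protein_id not in self.proteome:
                raise ValueError(
                    f"gene {g.gene_id}: protein {g.protein_id!r} not in proteome")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a (possibly multi-record) FASTA file.

    Record ids are the first whitespace-delimited token of the header; the
    rest of the header becomes the description.  Characters outside the
    declared alphabet raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}:{lineno}: expected FASTA header")
                break
    records: list[SequenceRecord] = []
    with open(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                records.append(SequenceRecord(
                    id=rec.id, residues=str(rec.seq),
                    alphabet=alphabet, description=rec.description))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    for r in records:
        try:
            r.validate()
        except ParseError:
            raise ParseError(
                f"{path}:{_locate_bad_line(path, r)}: illegal character in "
                f"record {r.id!r}") from None
    return records


def _locate_bad_line(path: Path, record: SequenceRecord) -> int:
    allowed = DNA_CHARS if record.alphabet == "dna" else PROTEIN_CHARS
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_record = line[1:].split()[:1] == [record.id]
            elif in_record and set(line.strip().upper()) - allowed:
                return lineno
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, sequence wrapped at `width` columns."""
    with open(path, "w") as fh:
        for r in records:
            header = r.id
            if r.description and r.description != r.id:
                desc = r.description
                if desc.startswith(r.id):
                    desc = desc[len(r.id):].strip()
                if desc:
                    header = f"{r.id} {desc}"
            fh.write(f">{header}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    One GeneModel per mRNA; parentage resolved through ID/Parent attributes.
    File coordinates (1-based inclusive) are converted to 0-based half-open.
    """
    import gffutils

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                                keep_order=True)

    models: list[GeneModel] = []
    mrna_ids = set()
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        mrna_ids.add(mrna.id)
        if mrna.strand not in "+-":
            raise ParseError(
                f"{path}: mRNA {mrna.id!r}: unknown strand {mrna.strand!r}")
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons, cds = [], []
        protein_id = None
        for child in db.children(mrna.id, order_by="start"):
            iv = (child.start - 1, child.end)  # 1-based inclusive -> half-open
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
                pid = child.attributes.get("protein_id", [None])[0]
                protein_id = pid or protein_id
        if not exons and cds:
            exons = list(cds)
        models.append(GeneModel(
            gene_id=gene_id, transcript_id=mrna.id, seq_id=mrna.seqid,
            strand=mrna.strand, exons=sorted(exons), cds=sorted(cds),
            protein_id=protein_id))

    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            raise ParseError(f"{path}: CDS at {feat.start} has no mRNA parent")
    return models


# ---------------------------------------------------------------------------
# Promoter extraction

def extract_promoter(gene: GeneModel, bundle: GenomeBundle,
                     length: int = 3000) -> SequenceRecord:
    """Return up to `length` bases immediately 5' of the first CDS base.

    The sequence is reported on the coding strand (reverse-complemented for
    '-' genes), so its last character sits at offset -1 relative to the A of
    the start codon.  Promoters truncated at a contig edge are returned
    shorter, with a logged warning.
    """
    if not gene.cds:
        raise ValueError(f"transcript {gene.transcript_id!r} has no CDS")
    contig = bundle.contigs[gene.seq_id].residues
    lo, hi = gene.cds_span
    if gene.strand == "+":
        start = max(0, lo - length)
        region = contig[start:lo]
    else:
        end = min(len(contig), hi + length)
        region = reverse_complement(contig[hi:end])
    if len(region) < length:
        log.warning("promoter of %s truncated to %d bp at contig edge",
                    gene.transcript_id, len(region))
    return SequenceRecord(id=gene.transcript_id, residues=region, alphabet="dna",
                          description=f"promoter len={len(region)}")


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree, path: str | Path | None = None) -> str:
    """Serialize a phylogeny.Tree as Newick with branch lengths and integer
    bootstrap supports as internal node labels."""
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path):
    """Parse Newick text (or a file path) back into a phylogeny.Tree."""
    from .phylogeny import Tree

    text = source
    p = Path(str(source))
    if ("(" not in str(source)) and p.exists():
        text = p.read_text()
    return Tree.from_newick(str(text))


# ---------------------------------------------------------------------------
# Catalog TSV

CATALOG_COLUMNS = ["protein_id", "gene_id", "contig", "strand", "start", "end",
                   "n_domains", "zf_class", "group", "subgroup", "flags"]


def write_catalog_tsv(entries: Sequence, path: str | Path) -> None:
    """Write family-catalog rows in the fixed documented column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for e in entries:
            contig, strand, (start, end) = e.locus
            fh.write("\t".join(str(x) for x in (
                e.protein_id, e.gene_id, contig, strand, start, end,
                e.n_domains, e.zf_class, e.group, e.subgroup,
                ",".join(sorted(e.flags)) or ".")) + "\n")
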