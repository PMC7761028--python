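"""Promoter cis-regulatory element scanning with IUPAC patterns.

The scanner works on promoter sequences whose 3' end abuts the translational
start, so hit offsets are reported as negative ATG-relative positions (-1 is
the base immediately upstream of the A of ATG).  The built-in element set
covers the W-box (the (C/T)TGAC(C/T) WRKY binding site), the jasmonate
CGTCA motif, the GCC- and G-boxes, the ethylene-responsive element, and the
salicylic-acid TCA-element, plus the bipartite "double W-box" — two adjacent
W-boxes whose TGAC cores are separated by exactly two nucleotides
(TTGACTTTGACT/C).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seqio import SequenceRecord, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Table-1 column order
MOTIF_ORDER = ("W-box", "G-box", "GCC-box", "TCA-element", "MeJa-RE", "ERE")


@dataclass(frozen=True)
class MotifDef:
    """A named cis-element: one or more IUPAC DNA patterns, OR-ed."""

    name: str
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"motif {self.name!r}: no patterns")
        for p in self.patterns:
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(
                    f"motif {self.name!r}: non-IUPAC characters {sorted(bad)}")

    def regexes(self) -> list[re.Pattern]:
        return [re.compile("(?=(" + "".join(
            c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in p
        ) + "))") for p in self.patterns]


@dataclass(frozen=True)
class MotifHit:
    """One element occurrence at an ATG-relative (negative) offset."""

    motif: str
    strand: str
    offset: int  # ATG-relative start of the match on the forward sequence
    matched: str

    def __post_init__(self) -> None:
        assert self.offset + len(self.matched) <= 0
        assert self.strand in "+-"


@dataclass
class PromoterReport:
    """Table-1-shaped per-gene element counts with a totals row."""

    motifs: tuple[str, ...]
    rows: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def totals(self) -> dict[str, int]:
        return {m: sum(r[m] for r in self.rows.values()) for m in self.motifs}

    def to_tsv(self) -> str:
        lines = ["seq\t" + "\t".join(self.motifs)]
        for gene, counts in self.rows.items():
            lines.append(gene + "\t" + "\t".join(
                str(counts[m]) for m in self.motifs))
        tot = self.totals
        lines.append("total\t" + "\t".join(str(tot[m]) for m in self.motifs))
        return "\n".join(lines) + "\n"


def builtin_motifs() -> list[MotifDef]:
    """The six built-in element classes, in Table-1 column order."""
    return [
        MotifDef("W-box", ("YTGACY",)),
        MotifDef("G-box", ("CACGTG",)),
        MotifDef("GCC-box", ("GCCGCC",)),
        MotifDef("TCA-element", ("CCATCTTTTT", "TCAGAAGAGG")),
        MotifDef("MeJa-RE", ("CGTCA",)),
        MotifDef("ERE", ("ATTTCAAA", "ATTTCATA")),
    ]


def _require_dna(seq: SequenceRecord | str) -> str:
    if isinstance(seq, SequenceRecord):
        if seq.alphabet != "dna":
            raise ValueError(f"record {seq.id!r}: expected DNA, got "
                             f"{seq.alphabet!r}")
        return seq.residues.upper()
    return seq.upper()


def scan_promoter(seq: SequenceRecord | str, motifs: list[MotifDef],
                  strand_mode: str = "forward") -> list[MotifHit]:
    """All (including overlapping) element matches in a promoter.

    ``strand_mode``: 'forward' scans the given strand only; 'both' also scans
    the reverse complement, reporting minus-strand hits at the forward-strand
    interval they occupy.  A palindromic pattern matching both strands over
    the same interval is counted once (as a '+' hit).
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    s = _require_dna(seq)
    n = len(s)
    hits: list[MotifHit] = []
    for motif in motifs:
        seen: set[tuple[int, int]] = set()
        for rx in motif.regexes():
            for m in rx.finditer(s):
                start = m.start()
                text = m.group(1)
                seen.add((start, start + len(text)))
                hits.append(MotifHit(motif.name, "+", start - n, text))
        if strand_mode == "both":
            rc = reverse_complement(s)
            for rx in motif.regexes():
                for m in rx.finditer(rc):
                    text = m.group(1)
                    # interval on the forward strand
                    start = n - (m.start() + len(text))
                    if (start, start + len(text)) in seen:
                        continue  # palindromic twin already counted
                    hits.append(MotifHit(motif.name, "-", start - n,
                                         reverse_complement(text)))
    hits.sort(key=lambda h: (h.offset, h.motif, h.strand))
    return hits


def find_bipartite_wbox(seq: SequenceRecord | str) -> list[MotifHit]:
    """Occurrences of the double W-box: two adjacent full W-boxes whose TGAC
    cores are exactly two nucleotides apart (YTGACYYTGACY).

    The reported offset is the ATG-relative start of the first W-box.
    """
    s = _require_dna(seq)
    n = len(s)
    rx = re.compile("(?=([CT]TGAC[CT][CT]TGAC[CT]))")
    return [MotifHit("double-W-box", "+", m.start() - n, m.group(1))
            for m in rx.finditer(s)]


def count_table(promoters: dict[str, SequenceRecord | str],
                motifs: list[MotifDef] | None = None,
                strand_mode: str = "forward") -> PromoterReport:
    """Per-gene element counts, one row per input gene in input order."""
    if not promoters:
        raise ValueError("no promoters given")
    motifs = motifs if motifs is not None else builtin_motifs()
    names = tuple(m.name for m in motifs)
    report = PromoterReport(motifs=names)
    for gene, seq in promoters.items():
        hits = scan_promoter(seq, motifs, strand_mode=strand_mode)
        counts = {name: 0 for name in names}
        for h in hits:
            counts[h.motif] += 1
        report.rows[gene] = counts
    return report


def hits_bed(gene: str, seq_len: int, hits: list[MotifHit]) -> str:
    """BED-like TSV export (0-based half-open promoter coordinates)."""
    lines = []
    for h in hits:
        start = seq_len + h.offset
        lines.append("\t".join(map(str, (
            gene, start, start + len(h.matched), h.motif, h.strand,
            h.matched, h.offset))))
    return "\n".join(lines) + ("\n" if lines else "")
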