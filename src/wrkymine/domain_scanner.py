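"""Detection of WRKY domains, zinc-finger chemistry, leucine zippers and NLS.

A WRKY domain is the conserved heptapeptide WRKYGQK (or a close variant)
followed, within a bounded gap, by a metal-coordinating zinc finger whose
four coordinating residues are Cys-Cys-His-His (C2H2; groups I/II) or
Cys-Cys-His-Cys (C2HC; group III) at characteristic spacings, e.g.
C-X5-C-X23-H-X1-H for the C2H2 type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seqio import SequenceRecord


@dataclass(frozen=True)
class DomainPattern:
    """Configurable search pattern for the composite WRKY domain.

    ``c2h2_spacing``/``c2hc_spacing`` are ``((x1_min, x1_max), (x2_min,
    x2_max), x3)`` residue counts between the coordinating residues of
    C-X(x1)-C-X(x2)-H-X(x3)-[H or C].
    """

    heptapeptide_variants: tuple[str, ...] = ("WRKYGQK", "WRKYGKK", "WRKYGEK")
    c2h2_spacing: tuple[tuple[int, int], tuple[int, int], int] = ((4, 7), (22, 23), 1)
    c2hc_spacing: tuple[tuple[int, int], tuple[int, int], int] = ((4, 8), (22, 28), 1)
    max_gap_hepta_to_zf: int = 40

    def __post_init__(self) -> None:
        for (a, b), (c, d), x3 in (self.c2h2_spacing, self.c2hc_spacing):
            if a > b or c > d or x3 < 0:
                raise ValueError("empty spacing range")
        if self.max_gap_hepta_to_zf < 0:
            raise ValueError("max_gap must be >= 0")
        if not self.heptapeptide_variants:
            raise ValueError("need at least one heptapeptide variant")

    @classmethod
    def strict(cls) -> "DomainPattern":
        """Canonical heptapeptide only (WRKYGQK)."""
        return cls(heptapeptide_variants=("WRKYGQK",))


@dataclass
class WrkyDomainHit:
    """One located heptapeptide with (optionally) its attached zinc finger."""

    hepta_start: int
    hepta_end: int
    hepta_seq: str
    zf_class: str = "none"  # C2H2 | C2HC | none
    zf_residue_positions: tuple[int, int, int, int] | None = None
    complete: bool = False

    def __post_init__(self) -> None:
        assert self.hepta_end - self.hepta_start == 7
        if self.zf_residue_positions is not None:
            p = self.zf_residue_positions
            assert all(a < b for a, b in zip(p, p[1:]))
            assert p[0] > self.hepta_end

    def shifted(self, k: int) -> "WrkyDomainHit":
        zf = None
        if self.zf_residue_positions is not None:
            zf = tuple(x + k for x in self.zf_residue_positions)
        return WrkyDomainHit(self.hepta_start + k, self.hepta_end + k,
                             self.hepta_seq, self.zf_class, zf, self.complete)


@dataclass
class ProteinAnnotation:
    protein_id: str
    hits: list[WrkyDomainHit] = field(default_factory=list)
    leucine_zipper: tuple[int, int] | None = None
    nls: list[tuple[int, int]] = field(default_factory=list)


def _require_protein(seq: SequenceRecord) -> str:
    if seq.alphabet != "protein":
        raise ValueError(f"record {seq.id!r}: expected protein alphabet, "
                         f"got {seq.alphabet!r}")
    return seq.residues.upper()


def _match_zinc_finger(residues: str, c1: int,
                       pattern: DomainPattern) -> tuple[str, tuple[int, ...]] | None:
    """Try to anchor a zinc finger whose first Cys is at `c1`.

    Spacings are scanned in ascending order (x1 then x2) for determinism; the
    fourth coordinating residue decides the class: His -> C2H2, Cys -> C2HC,
    each checked against its own spacing window.
    """
    if residues[c1] != "C":
        return None
    (h_x1, h_x2, h_x3) = pattern.c2h2_spacing
    (c_x1, c_x2, c_x3) = pattern.c2hc_spacing
    x1_lo = min(h_x1[0], c_x1[0])
    x1_hi = max(h_x1[1], c_x1[1])
    x2_lo = min(h_x2[0], c_x2[0])
    x2_hi = max(h_x2[1], c_x2[1])
    n = len(residues)
    for x1 in range(x1_lo, x1_hi + 1):
        c2 = c1 + x1 + 1
        if c2 >= n or residues[c2] != "C":
            continue
        for x2 in range(x2_lo, x2_hi + 1):
            h1 = c2 + x2 + 1
            if h1 >= n or residues[h1] != "H":
                continue
            for klass, (kx1, kx2, kx3) in (("C2H2", pattern.c2h2_spacing),
                                           ("C2HC", pattern.c2hc_spacing)):
                last = h1 + kx3 + 1
                if last >= n:
                    continue
                want = "H" if klass == "C2H2" else "C"
                if (residues[last] == want
                        and kx1[0] <= x1 <= kx1[1] and kx2[0] <= x2 <= kx2[1]):
                    return klass, (c1, c2, h1, last)
    return None


def find_wrky_domains(seq: SequenceRecord,
                      pattern: DomainPattern = DomainPattern()) -> list[WrkyDomainHit]:
    """Report every heptapeptide occurrence, each with the nearest downstream
    zinc finger starting within ``pattern.max_gap_hepta_to_zf`` residues."""
    residues = _require_protein(seq)
    hepta_re = re.compile("|".join(
        f"(?={re.escape(v)})" for v in pattern.heptapeptide_variants))
    hits: list[WrkyDomainHit] = []
    for m in hepta_re.finditer(residues):
        start = m.start()
        end = start + 7
        hit = WrkyDomainHit(start, end, residues[start:end])
        for c1 in range(end, min(end + pattern.max_gap_hepta_to_zf + 1,
                                 len(residues))):
            zf = _match_zinc_finger(residues, c1, pattern)
            if zf is not None:
                klass, positions = zf
                hit = WrkyDomainHit(start, end, residues[start:end],
                                    klass, positions, complete=True)
                break
        hits.append(hit)
    return hits


def find_leucine_zipper(seq: SequenceRecord) -> tuple[int, int] | None:
    """First window of >= 4 leucines at exact heptad period (L-X6-L-X6-L-X6-L).

    Returns the half-open interval covering the first four periodic leucines,
    or None.
    """
    residues = _require_protein(seq)
    for i, ch in enumerate(residues):
        if ch != "L":
            continue
        if all(i + 7 * k < len(residues) and residues[i + 7 * k] == "L"
               for k in range(4)):
            return (i, i + 7 * 3 + 1)
    return None


def find_nls(seq: SequenceRecord, window: int = 10,
             min_basic: int = 4) -> list[tuple[int, int]]:
    """Basic-residue-rich nuclear localization signal candidates.

    Windows of ``window`` residues containing >= ``min_basic`` Lys/Arg,
    merged when overlapping.  Detects e.g. the SSRKRKLESP signal.
    """
    residues = _require_protein(seq)
    n = len(residues)
    if n < window:
        return []
    hits = [i for i in range(n - window + 1)
            if sum(c in "KR" for c in residues[i:i + window]) >= min_basic]
    merged: list[list[int]] = []
    for i in hits:
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], i + window)
        else:
            merged.append([i, i + window])
    return [tuple(iv) for iv in merged]


def annotate_protein(seq: SequenceRecord,
                     pattern: DomainPattern = DomainPattern()) -> ProteinAnnotation:
    """Full annotation: WRKY domains, leucine zipper, NLS candidates."""
    return ProteinAnnotation(
        protein_id=seq.id,
        hits=find_wrky_domains(seq, pattern),
        leucine_zipper=find_leucine_zipper(seq),
        nls=find_nls(seq))


def annotation_tsv(annotations: list[ProteinAnnotation]) -> str:
    """TSV export: protein_id, feature, start, end, class."""
    lines = ["protein_id\tfeature\tstart\tend\tclass"]
    for ann in annotations:
        for h in ann.hits:
            lines.append(f"{ann.protein_id}\twrky_domain\t{h.hepta_start}\t"
                         f"{h.hepta_end}\t{h.zf_class}")
        if ann.leucine_zipper:
            s, e = ann.leucine_zipper
            lines.append(f"{ann.protein_id}\tleucine_zipper\t{s}\t{e}\t.")
        for s, e in ann.nls:
            lines.append(f"{ann.protein_id}\tnls\t{s}\t{e}\t.")
    return "\n".join(lines) + "\n"
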