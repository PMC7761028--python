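"""Theoretical protein properties: average molecular mass and isoelectric point.

The pI follows the Henderson–Hasselbalch charge balance with the Bjellqvist
pKa set (the values behind the common ExPASy-style calculators), solved by
bisection on the net charge over pH 0–14.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import SequenceRecord

# Average residue masses (Da): amino acid minus water, standard atomic weights.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


@dataclass(frozen=True)
class MassTable:
    residue_masses: dict = field(default_factory=lambda: dict(AVERAGE_RESIDUE_MASS))
    water: float = WATER_MASS


@dataclass(frozen=True)
class PkaTable:
    """Ionizable-group pKa values; defaults are the Bjellqvist set."""

    n_terminus: float = 7.5
    c_terminus: float = 3.55
    side_chains: tuple = (("D", 4.05), ("E", 4.45), ("C", 9.0), ("Y", 10.0),
                          ("H", 5.98), ("K", 10.0), ("R", 12.0))
    name: str = "Bjellqvist"

    def __post_init__(self) -> None:
        for v in (self.n_terminus, self.c_terminus,
                  *(p for _, p in self.side_chains)):
            if not 0 < v < 14:
                raise ValueError(f"pKa {v} outside (0, 14)")

    @property
    def acidic(self) -> dict:
        return {aa: p for aa, p in self.side_chains if aa in "DECY"}

    @property
    def basic(self) -> dict:
        return {aa: p for aa, p in self.side_chains if aa in "HKR"}


def _residues(seq: SequenceRecord | str) -> str:
    s = seq.residues if isinstance(seq, SequenceRecord) else seq
    return s.upper().rstrip("*")


def molecular_weight(seq: SequenceRecord | str,
                     masses: MassTable = MassTable(),
                     skip_unknown: bool = False) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    s = _residues(seq)
    if not s:
        raise ValueError("empty sequence")
    total = masses.water
    for c in s:
        if c not in masses.residue_masses:
            if skip_unknown:
                continue
            raise ValueError(f"non-standard residue {c!r} "
                             "(pass skip_unknown=True to ignore)")
        total += masses.residue_masses[c]
    return total


def net_charge(seq: SequenceRecord | str, pH: float,
               pka: PkaTable = PkaTable()) -> float:
    """Signed net charge at a given pH (termini included).

    Positive groups contribute 1/(1+10^(pH-pKa)); negative groups contribute
    -1/(1+10^(pKa-pH)).
    """
    if not 0 <= pH <= 14:
        raise ValueError(f"pH {pH} outside [0, 14]")
    s = _residues(seq)
    if not s:
        raise ValueError("empty sequence")

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - pH))

    charge = pos(pka.n_terminus) + neg(pka.c_terminus)
    acidic, basic = pka.acidic, pka.basic
    for c in s:
        if c in basic:
            charge += pos(basic[c])
        elif c in acidic:
            charge += neg(acidic[c])
    return charge


def isoelectric_point(seq: SequenceRecord | str,
                      pka: PkaTable = PkaTable(),
                      tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection over [0, 14]; reported to 2 dp.

    Net charge is strictly decreasing in pH, so the zero crossing is unique.
    """
    lo, hi = 0.0, 14.0
    c_lo = net_charge(seq, lo, pka)
    c_hi = net_charge(seq, hi, pka)
    if c_lo < 0 or c_hi > 0:  # monotone decreasing: sign change guaranteed
        raise ValueError("no zero crossing of net charge in [0, 14]")
    while hi - lo > 1e-9:
        mid = (lo + hi) / 2
        c = net_charge(seq, mid, pka)
        if abs(c) < tol:
            return round(mid, 2)
        if c > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2, 2)


def props_tsv(records: list[SequenceRecord]) -> str:
    """TSV report: id, length, MW (Da), pI."""
    lines = ["id\tlength\tmw_da\tpi"]
    for r in records:
        lines.append(f"{r.id}\t{len(_residues(r))}\t"
                     f"{molecular_weight(r):.2f}\t{isoelectric_point(r):.2f}")
    return "\n".join(lines) + "\n"
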