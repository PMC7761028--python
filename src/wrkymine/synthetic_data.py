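"""Synthetic genomes, proteomes, promoters and Ct tables with known truth.

Every generator is deterministic in its seed and returns a
:class:`TruthManifest` describing exactly what was planted, so each pipeline
stage can be tested closed-loop against ground truth.  Protein backgrounds
are drawn from a 19-letter alphabet without tryptophan, which makes planted
heptapeptides the only WRKY-domain anchors; promoter backgrounds are
fixed up to be free of every built-in cis-element before planting, so
planted counts are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .promoter_scanner import (MotifDef, builtin_motifs, count_table,
                               find_bipartite_wbox, scan_promoter)
from .seqio import GeneModel, GenomeBundle, SequenceRecord, reverse_complement

# background alphabet excludes W so planted heptapeptides are unique anchors
BG_AA = "ACDEFGHIKLMNPQRSTVY"
HEPTA = "WRKYGQK"


@dataclass
class TruthManifest:
    """Ground truth for one simulation.

    Keys (JSON on disk): ``proteins`` maps protein id to group, subgroup and
    the planted domain coordinates; ``loci`` maps locus id to member
    transcripts and the representative; ``promoters`` maps gene id to exact
    per-element counts, double W-box offsets, and the planted promoter
    string; ``folds`` maps (condition, timepoint) to the true fold change.
    """

    proteins: dict = field(default_factory=dict)
    loci: dict = field(default_factory=dict)
    promoters: dict = field(default_factory=dict)
    folds: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "proteins": self.proteins, "loci": self.loci,
            "promoters": self.promoters,
            "folds": {f"{c}@{t}": v for (c, t), v in self.folds.items()},
        }, indent=1, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "TruthManifest":
        raw = json.loads(Path(path).read_text())
        folds = {}
        for key, v in raw.get("folds", {}).items():
            c, _, t = key.partition("@")
            folds[(c, t)] = v
        return cls(proteins=raw.get("proteins", {}), loci=raw.get("loci", {}),
                   promoters=raw.get("promoters", {}), folds=folds)


# ---------------------------------------------------------------------------
# proteome


def _bg_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BG_AA))[rng.integers(0, len(BG_AA), n)])


def _domain_block(zf_class: str) -> str:
    """A complete WRKY domain: heptapeptide, linker, zinc finger.

    C2H2 uses the C-X5-C-X23-H-X1-H geometry; C2HC uses C-X5-C-X25-H-X1-C.
    Spacers are alanines so the planted coordinating residues are the only
    candidates the scanner can anchor.
    """
    if zf_class == "C2H2":
        zf = "C" + "A" * 5 + "C" + "A" * 23 + "H" + "A" + "H"
    elif zf_class == "C2HC":
        zf = "C" + "A" * 5 + "C" + "A" * 25 + "H" + "A" + "C"
    else:
        raise ValueError(f"unknown zinc-finger class {zf_class!r}")
    return HEPTA + "AAAA" + zf


def _plant(background: str, block: str, offset: int) -> str:
    return background[:offset] + block + background[offset + len(block):]


def simulate_wrky_proteome(n_group1: int = 10, n_group2_per_subgroup: int = 4,
                           n_group3: int = 5, n_decoys: int = 15,
                           length_range: tuple[int, int] = (180, 320),
                           seed: int = 0,
                           subgroup_mutation_rate: float = 0.05
                           ) -> tuple[list[SequenceRecord], TruthManifest]:
    """Proteome with planted WRKY domains of every group plus decoys.

    Group-I proteins carry two C2H2 domains, group-II one C2H2, group-III
    one C2HC; group-II sequences of each subgroup are point-mutated copies
    of a per-subgroup centroid (domains untouched), decoys have no
    heptapeptide at all.
    """
    from .family_catalog import SUBGROUPS

    rng = np.random.default_rng(seed)
    lo, hi = length_range
    block1 = _domain_block("C2H2")
    if lo < 2 * len(block1) + 30:
        raise ValueError(f"length_range too short to host domains "
                         f"(need >= {2 * len(block1) + 30})")
    records: list[SequenceRecord] = []
    manifest = TruthManifest()

    def add(pid: str, residues: str, group: str, subgroup: str,
            domains: list[tuple[int, str]]) -> None:
        records.append(SequenceRecord(pid, residues, "protein"))
        manifest.proteins[pid] = {
            "group": group, "subgroup": subgroup,
            "domains": [{"hepta_start": off, "zf_class": zc}
                        for off, zc in domains]}

    for i in range(n_group1):
        n = int(rng.integers(lo, hi + 1))
        bg = _bg_protein(rng, n)
        off1 = int(rng.integers(5, n // 2 - len(block1)))
        off2 = int(rng.integers(n // 2, n - len(block1) - 1))
        s = _plant(_plant(bg, block1, off1), block1, off2)
        add(f"G1_{i:03d}", s, "I", "none",
            [(off1, "C2H2"), (off2, "C2H2")])

    for sg in SUBGROUPS:
        n = int(rng.integers(lo, hi + 1))
        centroid_bg = _bg_protein(rng, n)
        off = int(rng.integers(5, n - len(block1) - 1))
        centroid = _plant(centroid_bg, block1, off)
        for i in range(n_group2_per_subgroup):
            s = list(centroid)
            n_mut = rng.binomial(n, subgroup_mutation_rate)
            positions = rng.choice(n, size=n_mut, replace=False)
            for p in positions:
                if off <= p < off + len(block1):
                    continue  # never mutate the planted domain
                s[p] = BG_AA[int(rng.integers(0, len(BG_AA)))]
            add(f"G2{sg}_{i:03d}", "".join(s), "II", sg, [(off, "C2H2")])

    block3 = _domain_block("C2HC")
    for i in range(n_group3):
        n = int(rng.integers(lo, hi + 1))
        bg = _bg_protein(rng, n)
        off = int(rng.integers(5, n - len(block3) - 1))
        add(f"G3_{i:03d}", _plant(bg, block3, off), "III", "none",
            [(off, "C2HC")])

    for i in range(n_decoys):
        n = int(rng.integers(lo, hi + 1))
        add(f"DEC_{i:03d}", _bg_protein(rng, n), "decoy", "none", [])

    return records, manifest


# ---------------------------------------------------------------------------
# promoters


def _bg_dna(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _scrub(seq: list[str], motifs: list[MotifDef],
           rng: np.random.Generator, max_rounds: int = 400) -> list[str]:
    """Mutate bases until the sequence has no forward-strand element match."""
    for _ in range(max_rounds):
        text = "".join(seq)
        hits = scan_promoter(text, motifs) + find_bipartite_wbox(text)
        if not hits:
            return seq
        h = hits[0]
        pos = len(seq) + h.offset + len(h.matched) // 2
        seq[pos] = "ACGT"[int(rng.integers(0, 4))]
    raise RuntimeError("could not scrub background free of elements")


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    from .promoter_scanner import IUPAC
    return "".join(c if len(IUPAC[c]) == 1
                   else IUPAC[c][int(rng.integers(0, len(IUPAC[c])))]
                   for c in pattern)


def simulate_promoters(planted_counts: dict[str, dict[str, int]],
                       double_wbox: dict[str, list[int]] | None = None,
                       length: int = 3000, gc: float = 0.35, seed: int = 0,
                       max_retries: int = 50
                       ) -> tuple[list[SequenceRecord], TruthManifest]:
    """Promoters with exact planted element counts and double W-boxes.

    ``planted_counts`` maps gene -> {motif name -> count}; ``double_wbox``
    maps gene -> ATG-relative offsets of planted TTGACTTTGAC(T/C) elements
    (each adds 2 to the effective W-box count).  Backgrounds are scrubbed
    free of all built-in elements before planting, and every emitted
    promoter is re-scanned to certify the manifest.
    """
    rng = np.random.default_rng(seed)
    motifs = builtin_motifs()
    by_name = {m.name: m for m in motifs}
    double_wbox = double_wbox or {}
    records: list[SequenceRecord] = []
    manifest = TruthManifest()

    for gene, wanted in planted_counts.items():
        unknown = set(wanted) - set(by_name)
        if unknown:
            raise ValueError(f"unknown motif(s) {sorted(unknown)}")
        doubles = sorted(double_wbox.get(gene, []))
        for attempt in range(max_retries):
            seq = _try_build(gene, wanted, doubles, length, gc, rng,
                             motifs, by_name)
            if seq is not None:
                break
        else:
            raise RuntimeError(f"infeasible packing for promoter {gene!r}")
        expected = {m.name: wanted.get(m.name, 0) for m in motifs}
        expected["W-box"] += 2 * len(doubles)
        records.append(SequenceRecord(gene, seq, "dna"))
        manifest.promoters[gene] = {
            "counts": expected, "double_wbox_offsets": doubles,
            "sequence": seq}

    # certify: manifest must match what the scanner reports
    report = count_table({r.id: r for r in records}, motifs)
    for r in records:
        truth = manifest.promoters[r.id]
        if report.rows[r.id] != truth["counts"]:
            raise RuntimeError(f"manifest/scan mismatch for {r.id!r}")
        found = [h.offset for h in find_bipartite_wbox(r)]
        if found != truth["double_wbox_offsets"]:
            raise RuntimeError(f"double W-box mismatch for {r.id!r}")
    return records, manifest


def _try_build(gene, wanted, doubles, length, gc, rng, motifs, by_name
               ) -> str | None:
    seq = _scrub(_bg_dna(rng, length, gc), motifs, rng)
    used: list[tuple[int, int]] = []

    def free(start: int, w: int) -> bool:
        # one spacer base so adjacent insertions cannot fuse into new motifs
        return (0 <= start and start + w <= length and
                all(start >= e + 1 or start + w + 1 <= s for s, e in used))

    for off in doubles:
        text = _instantiate("TTGACTTTGACY", rng)
        start = length + off
        if not free(start, len(text)):
            return None
        seq[start:start + len(text)] = list(text)
        used.append((start, start + len(text)))
    for name, count in wanted.items():
        for _ in range(count):
            pattern = by_name[name].patterns[
                int(rng.integers(0, len(by_name[name].patterns)))]
            text = _instantiate(pattern, rng)
            for _ in range(200):
                start = int(rng.integers(0, length - len(text) + 1))
                if free(start, len(text)):
                    break
            else:
                return None
            seq[start:start + len(text)] = list(text)
            used.append((start, start + len(text)))

    out = "".join(seq)
    # verify exact counts (junction artifacts force a retry)
    counts = {m.name: 0 for m in motifs}
    for h in scan_promoter(out, motifs):
        counts[h.motif] += 1
    expected = {m.name: wanted.get(m.name, 0) for m in motifs}
    expected["W-box"] += 2 * len(doubles)
    if counts != expected:
        return None
    if [h.offset for h in find_bipartite_wbox(out)] != doubles:
        return None
    return out


# ---------------------------------------------------------------------------
# genome bundles


def simulate_genome_with_loci(n_loci: int = 5,
                              isoforms_per_locus: list[int] | None = None,
                              groups: list[str] | None = None,
                              promoter_length: int = 3000,
                              seed: int = 0
                              ) -> tuple[GenomeBundle, TruthManifest]:
    """A single-contig genome with multi-isoform WRKY loci.

    Loci are spaced >= 5 kb apart, isoforms overlap their locus CDS on the
    same strand, and a scrubbed (element-free) promoter of
    ``promoter_length`` bp is placed immediately upstream of the
    representative ATG, recorded verbatim in the manifest.  ``groups`` gives
    the planted protein class per locus ('I', 'II', 'III' or 'decoy').
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    if isoforms_per_locus is None:
        isoforms_per_locus = [int(rng.integers(1, 4)) for _ in range(n_loci)]
    if len(isoforms_per_locus) != n_loci:
        raise ValueError("isoforms_per_locus length != n_loci")
    if groups is None:
        cycle = ["II", "I", "III", "decoy"]
        groups = [cycle[i % len(cycle)] for i in range(n_loci)]

    proteome_records, prot_manifest = simulate_wrky_proteome(
        n_group1=sum(g == "I" for g in groups) * max(isoforms_per_locus),
        n_group2_per_subgroup=max(1, sum(g == "II" for g in groups)
                                  * max(isoforms_per_locus) // 5 + 1),
        n_group3=sum(g == "III" for g in groups) * max(isoforms_per_locus) + 1,
        n_decoys=sum(g == "decoy" for g in groups) * max(isoforms_per_locus) + 1,
        seed=int(rng.integers(0, 2**31)))
    pools: dict[str, list[SequenceRecord]] = {"I": [], "II": [], "III": [],
                                              "decoy": []}
    for r in proteome_records:
        g = prot_manifest.proteins[r.id]["group"]
        pools[g if g != "decoy" else "decoy"].append(r)
    for pool in pools.values():  # longest first: isoform 0 is representative
        pool.sort(key=lambda r: -len(r.residues))

    motifs = builtin_motifs()
    contig: list[str] = []
    genes: list[GeneModel] = []
    proteome: dict[str, SequenceRecord] = {}
    manifest = TruthManifest()
    manifest.proteins = {}
    cursor = 0

    for li in range(n_loci):
        strand = "+" if li % 2 == 0 else "-"
        n_iso = isoforms_per_locus[li]
        gene_id = f"gene{li:02d}"
        promoter = "".join(_scrub(_bg_dna(rng, promoter_length, 0.35),
                                  motifs, rng))
        cds_len = 3 * int(rng.integers(200, 320))
        cds_seq = "ATG" + "".join(_bg_dna(rng, cds_len - 3, 0.45))
        spacer = "".join(_bg_dna(rng, 5000, 0.4))

        members = []
        if strand == "+":
            contig.append(spacer)
            cursor += len(spacer)
            contig.append(promoter)
            cursor += len(promoter)
            cds_start = cursor
            contig.append(cds_seq)
            cursor += len(cds_seq)
            rep_iv = (cds_start, cds_start + cds_len)
        else:
            contig.append(spacer)
            cursor += len(spacer)
            cds_start = cursor
            contig.append(reverse_complement(cds_seq))
            cursor += cds_len
            contig.append(reverse_complement(promoter))
            cursor += len(promoter)
            rep_iv = (cds_start, cds_start + cds_len)

        pool = pools[groups[li]]
        for iso in range(n_iso):
            tx_id = f"{gene_id}.t{iso + 1}"
            prot = pool.pop(0) if pool else None
            pid = f"{gene_id}.p{iso + 1}"
            if prot is not None:
                residues = prot.residues
                if iso > 0:  # shorter isoform: truncate from the C-terminus
                    keep = max(30, len(residues) - 20 * iso)
                    residues = residues[:keep]
                proteome[pid] = SequenceRecord(pid, residues, "protein")
                if iso == 0 and groups[li] != "decoy":
                    manifest.proteins[pid] = prot_manifest.proteins[prot.id]
            # isoforms shrink by 30 bp per index but always overlap
            if strand == "+":
                iv = (rep_iv[0], rep_iv[1] - 30 * iso)
            else:
                iv = (rep_iv[0] + 30 * iso, rep_iv[1])
            genes.append(GeneModel(
                gene_id=gene_id, transcript_id=tx_id, seq_id="chr1",
                strand=strand, exons=[iv], cds=[iv], protein_id=pid))
            members.append(tx_id)
        manifest.loci[gene_id] = {
            "transcripts": members, "representative": f"{gene_id}.t1",
            "group": groups[li], "strand": strand}
        manifest.promoters[f"{gene_id}.t1"] = {
            "counts": {m.name: 0 for m in motifs},
            "double_wbox_offsets": [], "sequence": promoter}

    contig_rec = SequenceRecord("chr1", "".join(contig), "dna")
    bundle = GenomeBundle(contigs={"chr1": contig_rec}, genes=genes,
                          proteome=proteome)
    bundle.validate()
    return bundle, manifest


def write_bundle(bundle: GenomeBundle, outdir: str | Path) -> dict[str, Path]:
    """Emit genome FASTA, GFF3 and proteome FASTA for a bundle."""
    from .seqio import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": outdir / "genome.fasta",
             "gff3": outdir / "annotation.gff3",
             "proteome": outdir / "proteome.fasta"}
    write_fasta(bundle.contigs.values(), paths["genome"])
    write_fasta(bundle.proteome.values(), paths["proteome"])
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        seen_genes = set()
        for g in bundle.genes:
            lo, hi = g.span
            if g.gene_id not in seen_genes:
                seen_genes.add(g.gene_id)
                fh.write(f"{g.seq_id}\twrkymine\tgene\t{lo + 1}\t{hi}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.seq_id}\twrkymine\tmRNA\t{lo + 1}\t{hi}\t.\t"
                     f"{g.strand}\t.\tID={g.transcript_id};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.seq_id}\twrkymine\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tParent={g.transcript_id}\n")
            for s, e in g.cds:
                fh.write(f"{g.seq_id}\twrkymine\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t0\tID=cds-{g.transcript_id};"
                         f"Parent={g.transcript_id};"
                         f"protein_id={g.protein_id}\n")
    return paths


# ---------------------------------------------------------------------------
# Ct tables


def simulate_ct_table(true_folds: dict[str, float],
                      sd: float = 0.1, replicates: int = 3, seed: int = 0,
                      target: str = "target", reference: str = "UBQ",
                      treatment: str = "MeJa", control: str = "control",
                      reference_ct: float = 20.0, base_dct: float = 5.0):
    """Ct table whose expected Livak fold changes equal ``true_folds``.

    ``true_folds`` maps timepoint -> fold of treatment over control; Gaussian
    replicate noise of the stated sd is added on the Ct scale.
    """
    import pandas as pd

    from .expression_qpcr import CtTable

    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("fold changes must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for tp, fold in true_folds.items():
        for cond in (control, treatment):
            shift = 0.0 if cond == control else -np.log2(fold)
            for rep in range(1, replicates + 1):
                ref_ct = reference_ct + rng.normal(0, sd)
                tgt_ct = ref_ct + base_dct + shift + rng.normal(0, sd)
                sample = f"{cond}_{tp}_r{rep}"
                rows.append((sample, cond, tp, reference, rep, ref_ct))
                rows.append((sample, cond, tp, target, rep, tgt_ct))
    return CtTable(pd.DataFrame(
        rows, columns=["sample", "condition", "timepoint", "gene",
                       "replicate", "ct"]))
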