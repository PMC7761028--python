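"""Family catalog: locus dedup, domain filtering, group/subgroup classification.

The curation funnel mirrors standard TF-family mining practice: collapse
annotation redundancy to unique genomic loci, keep one representative protein
per locus, require a complete WRKY domain, then classify — group I has two
WRKY domains, group II one domain with a C2H2 zinc finger, group III one
domain with a C2HC finger.  Group II is refined into subgroups IIa–IIe by
phylogenetic proximity to labelled reference proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .domain_scanner import DomainPattern, find_wrky_domains
from .seqio import GeneModel, GenomeBundle

log = logging.getLogger(__name__)

SUBGROUPS = ("IIa", "IIb", "IIc", "IId", "IIe")


@dataclass
class LocusCluster:
    """Transcripts sharing a genomic locus (same-strand CDS overlap)."""

    members: list[GeneModel]
    representative: str  # transcript_id

    @property
    def representative_model(self) -> GeneModel:
        for m in self.members:
            if m.transcript_id == self.representative:
                return m
        raise ValueError("representative not among members")


@dataclass
class FamilyEntry:
    """One curated catalog row: a unique WRKY locus with its classification."""

    protein_id: str
    gene_id: str
    transcript_id: str
    locus: tuple[str, str, tuple[int, int]]  # (contig, strand, span)
    n_domains: int
    zf_class: str
    group: str = "unclassified"
    subgroup: str = "none"
    flags: set[str] = field(default_factory=set)


def dedupe_by_locus(genes: list[GeneModel],
                    proteome: dict) -> list[LocusCluster]:
    """Group transcripts by single-linkage CDS overlap (>= 1 bp, same contig
    and strand); representative is the longest protein, ties broken by
    lexicographic protein_id."""
    with_cds = [g for g in genes if g.cds]
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in with_cds:
        by_key.setdefault((g.seq_id, g.strand), []).append(g)

    clusters: list[LocusCluster] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda g: g.cds_span)
        current: list[GeneModel] = []
        current_end = -1
        for g in group:
            s, e = g.cds_span
            if current and s < current_end:  # >=1 bp overlap, single linkage
                current.append(g)
                current_end = max(current_end, e)
            else:
                if current:
                    clusters.append(_make_cluster(current, proteome))
                current = [g]
                current_end = e
        if current:
            clusters.append(_make_cluster(current, proteome))
    return clusters


def _protein_len(g: GeneModel, proteome: dict) -> int:
    if g.protein_id and g.protein_id in proteome:
        return len(proteome[g.protein_id].residues)
    return 0


def _make_cluster(members: list[GeneModel], proteome: dict) -> LocusCluster:
    rep = min(members,
              key=lambda g: (-_protein_len(g, proteome), g.protein_id or ""))
    return LocusCluster(members=list(members), representative=rep.transcript_id)


def classify_group(n_domains: int, zf_class: str) -> str:
    """Group I: two WRKY domains; II: one + C2H2; III: one + C2HC."""
    if n_domains >= 2:
        return "I"
    if n_domains == 1 and zf_class == "C2H2":
        return "II"
    if n_domains == 1 and zf_class == "C2HC":
        return "III"
    return "unclassified"


def build_catalog(bundle: GenomeBundle,
                  pattern: DomainPattern = DomainPattern(),
                  keep_partial: bool = False) -> list[FamilyEntry]:
    """Run the curation funnel and return one entry per WRKY-bearing locus.

    Entries whose representative has a heptapeptide but no zinc finger are
    dropped unless ``keep_partial``, in which case they are flagged
    ``partial_domain``.  Logs the funnel counts (transcripts -> unique loci
    -> domain-bearing).
    """
    if not bundle.proteome:
        raise ValueError("empty proteome")
    clusters = dedupe_by_locus(bundle.genes, bundle.proteome)
    n_tx = sum(len(c.members) for c in clusters)
    entries: list[FamilyEntry] = []
    for cluster in clusters:
        rep = cluster.representative_model
        if not rep.protein_id or rep.protein_id not in bundle.proteome:
            continue
        hits = find_wrky_domains(bundle.proteome[rep.protein_id], pattern)
        complete = [h for h in hits if h.complete]
        if not complete and not (keep_partial and hits):
            continue
        flags = set()
        if not complete:
            flags.add("partial_domain")
        zf = complete[0].zf_class if complete else "none"
        entries.append(FamilyEntry(
            protein_id=rep.protein_id,
            gene_id=rep.gene_id,
            transcript_id=rep.transcript_id,
            locus=(rep.seq_id, rep.strand, rep.cds_span),
            n_domains=len(complete),
            zf_class=zf,
            group=classify_group(len(complete), zf),
            flags=flags))
    log.info("catalog funnel: %d transcripts -> %d unique loci -> %d "
             "domain-bearing entries", n_tx, len(clusters), len(entries))
    return entries


def assign_subgroups(entries: list[FamilyEntry],
                     reference_subgroups: dict[str, str],
                     tree,
                     domain_seqs: dict[str, str] | None = None
                     ) -> list[FamilyEntry]:
    """Label each group-II entry with the subgroup (IIa–IIe) of its nearest
    labelled reference leaf by patristic distance.

    ``reference_subgroups`` maps reference leaf labels to subgroup names and
    must cover all five subgroups.  Ties at machine precision are broken
    toward the reference sharing the longest exact common substring with the
    query's WRKY-domain sequence (``domain_seqs``, optional), then by
    reference label.
    """
    missing = [s for s in SUBGROUPS if s not in set(reference_subgroups.values())]
    if missing:
        raise ValueError(f"missing reference subgroup(s): {', '.join(missing)}")
    dist = tree.patristic_distances()
    leaves = set(tree.leaf_labels())
    refs = {r: s for r, s in reference_subgroups.items() if r in leaves}
    for entry in entries:
        if entry.group != "II":
            continue
        q = entry.protein_id
        if q not in leaves:
            raise ValueError(f"group-II entry {q!r} not in tree")
        best = min(refs, key=lambda r: (
            round(dist[q, r], 12),
            -_lcs_len(domain_seqs.get(q, ""), domain_seqs.get(r, ""))
            if domain_seqs else 0,
            r))
        entry.subgroup = refs[best]
    return entries


def _lcs_len(a: str, b: str) -> int:
    """Length of the longest exact common substring (O(len(a)*len(b)))."""
    if not a or not b:
        return 0
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best
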