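"""Locus dedup, catalog curation, and subgroup assignment."""

import pytest

from wrkymine.domain_scanner import DomainPattern
from wrkymine.family_catalog import (SUBGROUPS, assign_subgroups,
                                     build_catalog, classify_group,
                                     dedupe_by_locus)
from wrkymine.phylogeny import nj, pdistance, progressive_msa
from wrkymine.seqio import GeneModel, GenomeBundle, SequenceRecord
from wrkymine.synthetic_data import (simulate_genome_with_loci,
                                     simulate_wrky_proteome)


def gene(tx, strand="+", cds=(100, 400), contig="chr1", pid=None):
    return GeneModel(gene_id=tx.split(".")[0], transcript_id=tx,
                     seq_id=contig, strand=strand, exons=[cds], cds=[cds],
                     protein_id=pid or tx + ".p")


def prot(pid, n):
    return SequenceRecord(pid, "A" * n, "protein")


class TestDedupe:
    def test_overlapping_isoforms_merge(self):
        genes = [gene("g1.t1", cds=(100, 400), pid="p1"),
                 gene("g1.t2", cds=(300, 500), pid="p2")]
        proteome = {"p1": prot("p1", 100), "p2": prot("p2", 60)}
        (cluster,) = dedupe_by_locus(genes, proteome)
        assert len(cluster.members) == 2
        assert cluster.representative == "g1.t1"  # longer protein wins

    def test_opposite_strands_stay_apart(self):
        genes = [gene("g1.t1", "+", (100, 400)),
                 gene("g2.t1", "-", (100, 400))]
        proteome = {g.protein_id: prot(g.protein_id, 50) for g in genes}
        assert len(dedupe_by_locus(genes, proteome)) == 2

    def test_representative_tie_lexicographic(self):
        genes = [gene("g1.t1", cds=(100, 400), pid="pB"),
                 gene("g1.t2", cds=(100, 400), pid="pA")]
        proteome = {"pA": prot("pA", 80), "pB": prot("pB", 80)}
        (cluster,) = dedupe_by_locus(genes, proteome)
        assert cluster.representative == "g1.t2"

    def test_synthetic_loci_match_manifest(self):
        bundle, manifest = simulate_genome_with_loci(5, [3, 2, 1, 2, 1],
                                                     seed=21)
        clusters = dedupe_by_locus(bundle.genes, bundle.proteome)
        assert len(clusters) == 5
        got = {frozenset(m.transcript_id for m in c.members):
               c.representative for c in clusters}
        want = {frozenset(v["transcripts"]): v["representative"]
                for v in manifest.loci.values()}
        assert got == want


class TestBuildCatalog:
    def test_group_rules(self):
        assert classify_group(2, "C2H2") == "I"
        assert classify_group(3, "C2HC") == "I"
        assert classify_group(1, "C2H2") == "II"
        assert classify_group(1, "C2HC") == "III"
        assert classify_group(0, "none") == "unclassified"

    def _bundle_from_proteome(self, records):
        contig = SequenceRecord("chr1", "A" * (len(records) * 6000 + 6000),
                                "dna")
        genes, proteome = [], {}
        for i, rec in enumerate(records):
            start = 1000 + i * 6000
            genes.append(GeneModel(
                gene_id=f"g{i}", transcript_id=f"g{i}.t1", seq_id="chr1",
                strand="+", exons=[(start, start + 300)],
                cds=[(start, start + 300)], protein_id=rec.id))
            proteome[rec.id] = rec
        return GenomeBundle(contigs={"chr1": contig}, genes=genes,
                            proteome=proteome)

    def test_planted_groups_recovered(self):
        records, manifest = simulate_wrky_proteome(
            n_group1=10, n_group2_per_subgroup=4, n_group3=5, n_decoys=15,
            seed=31)
        bundle = self._bundle_from_proteome(records)
        entries = build_catalog(bundle)
        assert len(entries) == 35  # decoys excluded
        got = {e.protein_id: e.group for e in entries}
        for pid, truth in manifest.proteins.items():
            if truth["group"] == "decoy":
                assert pid not in got
            else:
                assert got[pid] == truth["group"]

    def test_partial_domain_flagging(self):
        partial = SequenceRecord("px", "M" * 10 + "WRKYGQK" + "A" * 60,
                                 "protein")
        bundle = self._bundle_from_proteome([partial])
        assert build_catalog(bundle) == []
        (entry,) = build_catalog(bundle, keep_partial=True)
        assert entry.flags == {"partial_domain"}
        assert entry.group == "unclassified"

    def test_empty_proteome_is_error(self):
        bundle = GenomeBundle(contigs={}, genes=[], proteome={})
        with pytest.raises(ValueError, match="empty proteome"):
            build_catalog(bundle)

    def test_counts_partition_catalog(self):
        records, _ = simulate_wrky_proteome(seed=32)
        entries = build_catalog(self._bundle_from_proteome(records))
        by_group = {}
        for e in entries:
            by_group[e.group] = by_group.get(e.group, 0) + 1
        assert sum(by_group.values()) == len(entries)
        assert set(by_group) <= {"I", "II", "III", "unclassified"}

    def test_idempotent_on_own_representatives(self):
        records, _ = simulate_wrky_proteome(seed=33)
        bundle = self._bundle_from_proteome(records)
        entries = build_catalog(bundle)
        reps = [bundle.proteome[e.protein_id] for e in entries]
        entries2 = build_catalog(self._bundle_from_proteome(reps))
        assert [(e.protein_id, e.group) for e in entries2] == \
               [(e.protein_id, e.group) for e in entries]


class TestSubgroups:
    def _tree_and_entries(self, seed, n_per_subgroup=4):
        records, manifest = simulate_wrky_proteome(
            n_group1=0, n_group2_per_subgroup=n_per_subgroup, n_group3=0,
            n_decoys=0, seed=seed)
        # first member of each subgroup acts as the labelled reference
        refs = {}
        entries = []
        from wrkymine.family_catalog import FamilyEntry
        for rec in records:
            truth = manifest.proteins[rec.id]
            if rec.id.endswith("_000"):
                refs[rec.id] = truth["subgroup"]
            else:
                entries.append(FamilyEntry(
                    protein_id=rec.id, gene_id=rec.id, transcript_id=rec.id,
                    locus=("chr1", "+", (0, 1)), n_domains=1,
                    zf_class="C2H2", group="II"))
        aln = progressive_msa(records)
        tree = nj(pdistance(aln))
        return entries, refs, tree, manifest

    def test_planted_subgroups_recovered(self):
        entries, refs, tree, manifest = self._tree_and_entries(seed=41)
        assign_subgroups(entries, refs, tree)
        correct = sum(e.subgroup == manifest.proteins[e.protein_id]["subgroup"]
                      for e in entries)
        assert correct / len(entries) >= 0.95

    def test_missing_reference_subgroup_reported(self):
        entries, refs, tree, _ = self._tree_and_entries(seed=42)
        refs = {k: v for k, v in refs.items() if v != "IIc"}
        with pytest.raises(ValueError, match="IIc"):
            assign_subgroups(entries, refs, tree)

    def test_tie_break_is_deterministic(self):
        from wrkymine.family_catalog import FamilyEntry
        from wrkymine.phylogeny import Node, Tree
        # query exactly equidistant from the IIa and IIb references
        tree = Tree(Node(children=[
            Node("q", 1.0), Node("refA", 1.0), Node("refB", 1.0),
            Node("refC", 5.0), Node("refD", 5.0), Node("refE", 5.0)]))
        refs = {"refA": "IIa", "refB": "IIb", "refC": "IIc", "refD": "IId",
                "refE": "IIe"}
        entry = FamilyEntry(protein_id="q", gene_id="q", transcript_id="q",
                            locus=("c", "+", (0, 1)), n_domains=1,
                            zf_class="C2H2", group="II")
        assign_subgroups([entry], refs, tree,
                         domain_seqs={"q": "WRKYGQKAAC", "refA": "WRKYGQK",
                                      "refB": "WRKYGQKAA"})
        # longer common substring with refB wins the distance tie
        assert entry.subgroup == "IIb"
        assign_subgroups([entry], refs, tree)  # no sequences: label order
        assert entry.subgroup == "IIa"
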