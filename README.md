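# wrkymine

Genome-wide mining and characterization of **WRKY transcription-factor gene
families** in plants, built as a tested, reusable pipeline. WRKY proteins are
one of the largest plant TF families; they regulate stress responses and
secondary metabolism (for example the jasmonate-responsive WRKYs implicated in
artemisinin biosynthesis in *Artemisia annua*) and are defined by a ~60-residue
DNA-binding domain: the heptapeptide **WRKYGQK** followed by a zinc-finger
motif. The package is aimed at researchers who want to run — or stress-test —
every computational stage of a TF-family survey without depending on remote
databases: all inputs can be simulated with known ground truth.

## What it does

- **Family identification** (`seqio`, `domain_scanner`, `family_catalog`):
  parse genome FASTA + GFF3 + proteome, collapse transcripts to unique genomic
  loci (single-linkage CDS overlap), scan representatives for WRKY domains,
  and classify: group I has two WRKY domains, group II one domain with a
  **C2H2** zinc finger (C-X4–7-C-X22–23-H-X-H), group III one domain with a
  **C2HC** finger. Group II is refined into subgroups IIa–IIe by patristic
  proximity to labelled reference proteins. Leucine-zipper heptads
  (L-X6-L-X6-L-X6-L) and basic-rich NLS candidates are annotated too.
- **Phylogenetics** (`phylogeny`): affine-gap Needleman–Wunsch, progressive
  MSA (3-mer UPGMA guide tree, profile–profile alignment), p-distances,
  Saitou–Nei **neighbor joining** with the Studier–Keppler criterion
  Q(i,j) = (n−2)·d(i,j) − r_i − r_j, and bootstrap supports from column
  resampling (default 1000 replicates).
- **Motif discovery** (`motif_discovery`): MEME-style ungapped motif discovery
  by **ZOOPS** expectation–maximization (up to 6 motifs, widths 6–50).
- **Promoter scanning** (`promoter_scanner`): IUPAC element matching on 3000-bp
  ATG-anchored promoters for the W-box `YTGACY`, MeJa-RE `CGTCA`, G-box
  `CACGTG`, GCC-box `GCCGCC`, ERE and TCA elements, plus the bipartite
  **double W-box** `YTGACYYTGACY` (two TGAC cores spaced by 2 nt).
- **Protein properties** (`protein_props`): average molecular mass and
  isoelectric point (Henderson–Hasselbalch charge balance with Bjellqvist
  pKa values, solved by bisection).
- **qPCR expression** (`expression_qpcr`): the Livak **2^−ΔΔCt** method with
  replicate statistics and one-way ANOVA + Tukey HSD compact letter display.
- **Synthetic data** (`synthetic_data`): deterministic generators for
  proteomes with planted domains, multi-isoform genomes, promoters with exact
  planted element counts, and Ct tables with known fold changes — each with a
  machine-readable truth manifest.

## Worked example

```python
import wrkymine as wm

# a proteome with planted WRKY domains, then scan it
records, manifest = wm.simulate_wrky_proteome(
    n_group1=2, n_group2_per_subgroup=1, n_group3=1, n_decoys=2, seed=42)
for h in wm.find_wrky_domains(records[0]):
    print(f"{records[0].id}: heptapeptide {h.hepta_seq} at {h.hepta_start}, "
          f"zinc finger {h.zf_class}, complete={h.complete}")

# a promoter with five W-boxes, five MeJa-REs and a double W-box at -800
proms, _ = wm.simulate_promoters(
    {"AaWRKY40_like": {"W-box": 5, "MeJa-RE": 5}},
    double_wbox={"AaWRKY40_like": [-800]}, seed=42)
print(wm.count_table({r.id: r for r in proms}).to_tsv())
for h in wm.find_bipartite_wbox(proms[0]):
    print(f"double W-box {h.matched} at offset {h.offset}")

# jasmonate-induction style fold changes recovered by 2^-ddCt
ct = wm.simulate_ct_table({"30min": 25.0, "4h": 1.78, "24h": 1.5},
                          sd=0.1, seed=42, target="AaWRKY1", reference="UBQ")
print(wm.delta_delta_ct(ct, "AaWRKY1", "UBQ", "control").table.to_string(index=False))
```

Output:

```
G1_000: heptapeptide WRKYGQK at 22, zinc finger C2H2, complete=True
G1_000: heptapeptide WRKYGQK at 144, zinc finger C2H2, complete=True
seq	W-box	G-box	GCC-box	TCA-element	MeJa-RE	ERE
AaWRKY40_like	7	0	0	0	5	0
total	7	0	0	0	5	0

double W-box TTGACTTTGACC at offset -800
condition timepoint  mean_fold  sd_fold letter
  control     30min   1.000000 0.083117      b
     MeJa     30min  24.423297 1.395021      a
  control        4h   1.000000 0.079749      b
     MeJa        4h   1.788015 0.042170      b
  control       24h   1.000000 0.030370      b
     MeJa       24h   1.518669 0.106118      b
```

The group-I protein carries two complete WRKY domains, as its class requires.
The promoter row counts 7 W-boxes: the 5 planted singles plus the 2 W-boxes
inside the planted double element at −800 (−1 is the base immediately upstream
of the ATG). In the qPCR table the untreated calibrator is 1 by construction,
the strong 30-min induction earns its own Tukey letter, and the simulated
folds (25, 1.78, 1.5) are recovered within replicate noise.

A `wrkymine` console script exposes the same stages as subcommands
(`simulate`, `identify`, `tree`, `promoters`, `motifs`, `props`, `qpcr`), e.g.

```bash
wrkymine simulate --outdir sim --seed 3
wrkymine identify --genome sim/genome.fasta --gff3 sim/annotation.gff3 \
    --proteome sim/proteome.fasta --out catalog.tsv
```

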