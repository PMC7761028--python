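# Methods

This note documents the models, conventions and numerical choices behind
`wrkymine`, and what the synthetic-data experiments do and do not demonstrate.

## Coordinates and promoters

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
intervals are converted at the parsing boundary, which keeps promoter
arithmetic free of off-by-one ambiguity. A *promoter* is the up-to-3000-bp
stretch immediately 5′ of the first CDS base on the coding strand
(reverse-complemented for minus-strand genes). Offsets reported to users are
negative integers with −1 the base immediately upstream of the A of ATG.
Promoters truncated by a contig edge are kept, with a logged warning, rather
than silently dropped. When a locus has several CDS-bearing isoforms the
promoter is anchored at the representative transcript (below), so each catalog
row has exactly one promoter.

## WRKY domain model

A domain hit is a heptapeptide match followed by a zinc finger. The default
heptapeptide set is `WRKYG[QKE]K` — the canonical WRKYGQK plus the two
commonly reported natural variants; `DomainPattern.strict()` restricts to
WRKYGQK only. Zinc fingers are matched structurally: the first Cys must start
within 40 residues of the heptapeptide (keeping the composite inside the
conserved ~60-residue domain plus slack), and the spacing windows are
C-X(4..7)-C-X(22..23)-H-X(1)-H for the C2H2 class and C-X(4..8)-C-X(22..28)-
H-X(1)-C for C2HC. The C2HC windows are a deliberately permissive superset
since no canonical spacing is established for that class; both are
configurable. The identity of the fourth coordinating residue (His vs Cys)
decides the class, so a hit can never be both. Spacings are scanned in
ascending order and the nearest valid finger wins, making the scanner fully
deterministic.

The leucine zipper detector requires ≥4 leucines at exact heptad period
(L-X6-L-X6-L-X6-L) and reports the first such window. The NLS heuristic marks
maximal 10-residue windows containing ≥4 Lys/Arg, merged when overlapping; it
is a declared, testable replacement for served neural predictors and detects
the canonical SSRKRKLESP-type signal. Both are screening heuristics, not
physical models.

## Family catalog

"Same genomic locus" is operationalized as same-strand CDS overlap of at
least 1 bp with single linkage — the most inclusive deterministic reading.
The cluster representative is the longest encoded protein (ties broken by
lexicographic protein id), maximizing the chance of containing the full
domain. Entries require at least one complete domain; heptapeptide-only
proteins are excluded unless `keep_partial=True`, which admits them flagged
`partial_domain`. Classification follows the family convention: two domains →
group I; one domain + C2H2 → group II; one domain + C2HC → group III.
Subgroups IIa–IIe are assigned to group-II entries by nearest labelled
reference leaf under patristic distance; distance ties (rounded at 1e-12) are
broken toward the reference sharing the longest exact common substring with
the query domain, then by label.

## Phylogenetics

The pairwise aligner is affine-gap global alignment (Gotoh): a gap of length
k costs `gap_open + (k−1)·gap_extend`, defaults BLOSUM62/−10/−1 (community
defaults; nothing in the pipeline is sensitive to the exact choice).
Traceback prefers diagonal over up over left, so alignments are reproducible.
The progressive MSA builds a 3-mer-distance UPGMA guide tree and merges
profiles by the same affine DP with expected-substitution-score columns; it
replaces an external aligner because alignment quality is not this package's
contribution, and pre-aligned FASTA is accepted wherever an alignment is.

Distances are p-distances with pairwise gap deletion (optional Kimura
correction −ln(1 − p − p²/5)). Neighbor joining is Saitou–Nei with the
Studier–Keppler Q criterion; ties on Q are broken by the lexicographically
smallest pair of cluster labels (clusters are labelled by their smallest leaf)
so the algorithm is deterministic even on degenerate inputs. Negative branch
lengths are clamped to zero with the deficit moved to the sibling branch,
preserving the joined pair's path length. The final three clusters form a
trifurcating root via the closed-form three-point formulas. Bootstrap
resamples alignment columns with replacement (one seeded generator per call);
supports are the percentage of replicates whose NJ tree contains each
bipartition of the full-data tree. Because tie-breaking is label-based,
bootstrap supports are permutation-equivariant only on generic (tie-free)
distance matrices; exact ties are resolved reproducibly but not
label-independently.

## Motif discovery

Discovery is ZOOPS (zero-or-one site per sequence) expectation–maximization,
a deterministic surrogate for MEME-style tools. The background is the 0-order
letter frequency of the input; pseudocounts are 0.1 per PWM cell; EM stops at
|Δlog-likelihood| < 1e-4 or 100 iterations. For each candidate width (wmin to
wmax in steps of 2) EM is started from the 5 best substring seeds (ranked by
a consensus-match heuristic over a seeded sample of windows) and the model is
scored by information content per column × expected site count; a shift
hill-climb (±2 columns, re-seeded EM) then guards against phase-shifted local
optima. Sites of an accepted motif are masked before the next motif is
sought. OOPS/ANR site models and MEME's E-value machinery are deliberately
out of scope; motif comparisons should be by content, not index. The planted
8-mer recovery experiment runs widths 6–12: the planted site is 8 residues
and wider scans add cost without information.

## Promoter scanning

Elements are IUPAC patterns matched with overlapping occurrences all counted
(naive pattern-count semantics, oracle-tested). The built-in set matches the
six classes commonly scanned in WRKY promoter surveys; the W-box character
classes written C/TTGACC/T and C/TTGACT/C both expand to the same set
`[CT]TGAC[CT]` and are implemented once as `YTGACY`. The default scan is
forward-strand only — the minimal declared choice, with `both` one flag away;
in `both` mode a palindromic pattern (e.g. G-box CACGTG) matching the same
interval on both strands is counted once. The bipartite double W-box is
`YTGACYYTGACY`: two full W-boxes whose TGAC cores are exactly 6 positions
(2 intervening bases) apart, reported at the offset of the first W-box.

## Protein properties

Molecular mass is the sum of average residue masses plus one water
(18.0153 Da). The isoelectric point solves net charge = 0 by bisection on
[0, 14] to |charge| < 1e-4 (reported to 2 decimals); positive groups
contribute 1/(1+10^(pH−pKa)), negative groups −1/(1+10^(pKa−pH)), termini
included. The default pKa set is the Bjellqvist table (N-term 7.5, C-term
3.55; D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0) — the values
behind the widely used ExPASy-style calculators. Average (not monoisotopic)
masses are the default because reported theoretical masses of TF proteins are
average-mass figures. No post-translational modifications are modelled.

## qPCR fold changes

The Livak method with amplification efficiency fixed at 2: per sample
ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the mean calibrator ΔCt at
the same timepoint; fold = 2^−ΔΔCt. Replicates are aggregated at the ΔCt
level for the calibrator; the reported mean fold is the geometric mean
2^−(mean ΔΔCt), which makes the calibrator exactly 1 by construction, while
the sd is computed on per-replicate folds. ANOVA/Tukey letters default to the
fold scale (a ΔCt-scale option exists since the choice is not standardized);
the compact letter display processes groups in descending mean order, so 'a'
always labels the largest mean. Groups need ≥2 replicates.

## Synthetic data: what it shows and what it does not

Generators are deterministic functions of their parameters and a single seed.
Protein backgrounds are drawn from a 19-letter alphabet without tryptophan,
so planted heptapeptides are provably the only domain anchors and planted
coordinates are exact oracles; zinc-finger blocks use alanine spacers for the
same reason. Promoter backgrounds are mutated ("scrubbed") until free of
every built-in element on the forward strand before planting, insertions are
kept non-adjacent, and each emitted promoter is re-scanned so the manifest is
certified, not assumed. Ct tables place the truth in the mean: Ct(target) =
Ct(reference) + baseline − log2(fold) + Gaussian noise of the stated sd
(defaults mirror a 3-replicate, control-vs-elicitor, three-timepoint design
with fold effects of 25, 1.78 and 1.5 — a strong early induction decaying
toward baseline).

Passing closed-loop tests therefore demonstrates internal correctness —
scanner, dedup, classifier, tree, counter and ΔΔCt recover exactly what was
planted — but not performance on real annotation: real proteomes contain
diverged heptapeptides, fragmented gene models and compositional biases that
the generators deliberately do not emulate (no codon usage, no realistic GC
structure, no phylogenetic signal beyond per-subgroup centroid mutation at
5%). Genome-scale family counts on a real assembly depend on the annotation
and on profile-based domain callers and are expected to differ from the
declared regex/spacing patterns used here.

## Problem sizes in tests

The default test-suite and acceptance-script experiments use desk-scale
problems chosen to make the statistics stable: 50-protein proteomes, 5–6-locus
genomes, 200 random 3000-bp promoters for oracle equivalence, 50 random
5-taxon matrices for the NJ oracle, 20 seeded motif-recovery runs of 20×200
residues, 100-replicate bootstraps, and 2000 null ANOVA tables. The spec-level
defaults for analysis parameters (3000-bp promoters, 6 motifs of width 6–50,
1000 bootstrap replicates) remain the library defaults.

## Known limitations

- No profile-HMM or PROSITE-style probabilistic domain scoring; heavily
  diverged WRKY domains will be missed by design.
- NJ tie-breaking is deterministic but label-dependent (see above).
- Motif discovery is single-strand for proteins and forward-strand for DNA.
- The MSA is a guide-tree progressive aligner without iterative refinement.
- No remote data access: accession-based replication of published
  genome-scale counts is intentionally out of scope for the test suite.
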