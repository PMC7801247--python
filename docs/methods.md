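# Methods

## Problem and approach

`wgdscan` detects and dates paleo-polyploidization (ancient whole-genome
duplication, WGD) inside a single genome by combining two independent lines
of evidence:

1. **Positional**: colinear (syntenic) blocks — runs of homologous gene pairs
   that preserve gene order between two genomic regions. A WGD leaves every
   region of the genome with one or more homoeologous partner regions, so
   block coverage and its *depth* (how many blocks cover a locus) carry the
   ploidy signature even after heavy gene loss.
2. **Temporal**: the synonymous divergence (Ks) and the fourfold-degenerate
   transversion rate (4Dtv) of the gene pairs inside blocks. Pairs created by
   one duplication event share one divergence time, so events appear as peaks
   in the Ks distribution.

Retrotransposition waves or tandem expansions can fake a Ks peak but not a
colinearity pattern; residual haplotype divergence can fake colinearity at
very low Ks but is excluded by a divergence guard. The combination is what
identifies polyploidy.

## Coordinate system

All block inference runs on 1-based *gene ranks* per scaffold, never base
pairs: the gap cap ("at most 50 intervening genes") is a gene-count rule, and
ranks make block length, gap, and depth integer quantities. Base-pair
coordinates, when present in the input annotation, are carried through for
reporting only. Strand is recorded but does not affect rank assignment;
reversed segments are found as antiparallel chains.

## Colinear block inference

Homologous gene pairs on a scaffold pair are points (x, y) in the rank grid.
A block is a chain strictly increasing in x and strictly monotone in y
(increasing = parallel, decreasing = antiparallel) in which consecutive
points satisfy (Δx − 1) ≤ max_gap and (|Δy| − 1) ≤ max_gap. The longest
chain (node count, not score sum — published block lengths are gene counts)
is extracted by O(n²) dynamic programming over both orientations, its points
are removed, and the search recurses until no chain of `min_len` points
remains; a gene pair therefore belongs to at most one block, and a gene
occurs at most once per block (tandem arrays contribute one pair). Defaults:
`max_gap=50`, `min_len=5` within a genome and 4 between genomes, matching
common practice for plant comparative maps.

Ties between equal-length chains break by smaller total gap sum, then
smallest starting x, then smallest starting y — a pure determinism rule.

**Significance.** Each block is tested against a uniform re-scatter null: the
same number of points is re-placed uniformly (without replacement) on the
scaffold pair's rank grid and the best chain length recomputed; the p-value
is the fraction of permutations reaching the observed length with the
+1/(n_perm+1) correction, so p is never exactly 0. All blocks on one scaffold
pair share one permutation sample (the null depends only on the context, not
the block). Blocks with p above `alpha` (default 0.05) are discarded. A
closed-form significance test could later replace the permutation behind the
same interface.

**Self-comparison specifics.** The gene-vs-itself diagonal is dropped, each
unordered pair is kept once (scaffold_a ≤ scaffold_b, x ≤ y on a shared
scaffold), and same-scaffold pairs within `diagonal_window=5` ranks of the
diagonal are excluded as tandem shadow.

## Homology

The internal protein search is a shared-k-mer prefilter (k = 6) followed by
global alignment (BLOSUM62, gap open −10, extend −0.5); the top
`max_hits_per_query=5` hits per query are kept and labeled best /
second-best / other, the classic dot-plot coloring. An E-value-like
significance is attached via Karlin–Altschul statistics so that externally
computed 12-column (outfmt-6) tables and internal tables behave identically
downstream. Genes whose family size (distinct partners at significance
≤ 1e-5) exceeds `max_copies=30` are removed entirely: high-copy repetitive
families produce dense spurious dot clouds that chain by chance.

## Divergence estimation

Protein pairs are globally aligned and the alignment is back-translated to
codons; columns with a gap, ambiguity, or stop in either sequence are
masked. Pairs retaining fewer than 30 codon columns are excluded — per-pair
Ks variance below that length is too high to be useful.

Ka/Ks follows the Nei–Gojobori (1986) counting method exactly: per-codon
synonymous site fractions (synonymous immediate neighbors / 3 per position,
averaged over the two codons), difference counts averaged over all shortest
substitution paths that avoid stop codons (equal path weighting; if every
path crosses a stop, all paths are used), and the Jukes–Cantor correction
Ks = −(3/4)·ln(1 − (4/3)·pS). Codon-pair difference counts are precomputed
into a table; an explicit path-enumeration oracle written against
Biopython's translation machinery verifies the table to 1e-9 in the test
suite. Pairs with pS ≥ 3/4 (the correction's singularity) are flagged
saturated and excluded from peak fitting. 4Dtv counts transversions at third
positions of columns where both codons belong to fourfold-degenerate
families and encode the same amino acid; it is reported uncorrected, as an
independent proxy that must co-vary with Ks.

## Peak detection, event assignment, dating

Ks values of block pairs (within `ks_range = 0.02–3.0`; the upper bound is a
saturation guard) are fitted on the log scale with Gaussian mixtures,
k = 1..4 components. The number of components is selected by the integrated
completed likelihood (ICL = BIC + 2 × classification entropy), not raw BIC:
on realistic sample sizes (thousands of pairs) BIC splits a single skewed
peak into two heavily overlapping Gaussians, because it measures density fit,
while an *event* is a separated cluster — exactly what the entropy term
enforces. Components with weight < 0.05 are dropped as noise. Peak location
is reported as exp(μ) of the component (the back-transformed log-scale
mode); assignment intervals are the posterior crossing points of adjacent
components.

Blocks are assigned to events by median Ks with the dot-plot thresholds:
median < 0.5 → the younger event ("xi"), 1.0 < median < 1.7 → the older
event ("eta"). Blocks with median Ks below the heterozygosity guard (0.07,
configurable, off for cross-species runs) are left unlabeled: divergence
that low is indistinguishable from residual haplotype divergence in a
partially phased assembly (~98.5% DNA identity corresponds to Ks well below
the younger peak).

Ages come from the synonymous clock T = Ks/(2r) with r given as an interval,
default 6.0–7.0 × 10⁻⁹ synonymous substitutions/site/year (the angiosperm
range); the division by 2 is because a pair's divergence accumulates along
two lineages. The package reports the formula's inputs and output verbatim
and makes no attempt to reconcile externally published age ranges whose
effective Ks inputs are not stated.

## Depth and ancestral reconstruction

A gene's homologous depth is the number of significant blocks (length ≥
`min_len`) whose rank span covers it; for self-comparison both of a block's
regions are counted (`axis="both"`). Depth distributions are reported as
fractions of *genes* — the gene is the resolution unit of the whole
pipeline — and every table prints the fractions with their sum (100.00).

Ancestral reconstruction collapses one event's blocks: blocks are processed
in order of ascending p-value (then descending length); within a block the
copy on the longer scaffold anchors ancestral order (a determinism rule —
the data cannot distinguish the copies), each colinear pair collapses to one
ancestral gene mapping to both extant copies, and unpaired genes inside an
anchored span are retained as single-copy ancestral genes. A gene claimed by
two region groups stays with the stronger block; conflicts are logged. The
same collapse with ploidy=3 serves hexaploid histories. On a loss-free
simulated tetraploid the collapse is exact: n ancestral genes, two copies
each.

## The simulator

The generator produces the statistical structure the analysis assumes, with
full ground truth. Defaults and the reasoning behind them:

- **Ancestral genome**: codon sequences drawn uniformly over the 61 sense
  codons, 150–450 codons per gene (typical plant CDS lengths), on a few
  scaffolds. Uniform codon usage is deliberate: it makes the NG86 site
  counts well conditioned without favoring any codon family.
- **WGD events**: ordered oldest-first with strictly decreasing target Ks.
  Each event copies every scaffold; each duplicated gene is then dropped
  independently with probability 1 − retention (gene-wise fractionation, no
  biased subgenome — the simplest model consistent with what the analysis
  tests).
- **Divergence** is parameterized directly in Ks units — the simulator
  asserts no molecular clock; dating is tested by pushing truth Ks through
  the same T = Ks/(2r) rule the pipeline uses. Events sit on a per-lineage
  timeline: a pair split at target Ks K accumulates K/2 on each side.
- **Substitution process**: per codon position with m synonymous
  single-nucleotide alternatives, a Poisson number of events drives a
  uniform-jump walk over the m+1 synonymous states, with the rate solved so
  the *Jukes–Cantor-corrected* NG86 estimate is unbiased for the target
  (for a fourfold site the process is exactly Jukes–Cantor at rate Ks per
  synonymous site; twofold and threefold sites get correspondingly smaller
  rates). Multiple hits are real, so the correction — not raw counting — is
  what recovers the target. Nonsynonymous noise runs the same machinery over
  nonsynonymous non-stop neighbors at rate ω·Ks, ω = 0.1 (strong purifying
  selection, typical of retained duplicates).
- **Rearrangements**: inversions reverse a rank interval and flip strands;
  translocations move an interval to another scaffold; fragmentation splits
  scaffolds at random rank boundaries. These fragment blocks the way real
  scaffold-level assemblies do.
- All randomness flows from one seed through named child streams, so runs
  are byte-reproducible.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: codon-usage bias and GC drift, rate variation
across genes and sites, biased fractionation between subgenomes, tandem
duplication, transposable elements, segmental (non-whole-genome)
duplication, assembly and annotation error beyond scaffold fragmentation.
Recovery results on simulated histories demonstrate the machinery is
correct, not that every real genome's history is identifiable.

## Problem sizes used in the checks

The bundled end-to-end recovery runs 2,000 ancestral genes through an older
WGD (Ks 1.2, retention 0.3) and a younger WGD (Ks 0.12, retention 0.6), with
20 inversions, 10 translocations, and fragmentation into 40 scaffolds
(~4,100 extant genes, ~2,500 colinear pairs). The null control shuffles the
gene order of a 2,000-gene duplicated genome across 20 seeds. Reconstruction
checks use 150–400 ancestral genes. These sizes give stable peak estimates
and tight binomial bounds while keeping a full run in minutes on one core.

## Numerical notes and known limitations

- Permutation p-values are discrete; the uniformity check in the acceptance
  suite uses the standard randomized p-value construction.
- GMM fits use 5 initializations and `reg_covar=1e-4`; fits are
  deterministic for a fixed seed.
- Peak-location error grows with Ks (Jukes–Cantor variance inflation);
  beyond Ks ≈ 2 peaks are biased and beyond the `ks_range` cap they are
  ignored entirely. Events older than that are visible only through depth,
  not through Ks.
- The internal homology search is meant for desk-scale and simulated runs;
  genome-scale analyses should supply precomputed tabular hits, which enter
  the identical code path.
- GFF3 reading keeps one point per gene (first mRNA where only mRNAs are
  annotated); alternative isoforms are ignored by design.
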