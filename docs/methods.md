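# Methods

`fermase` re-implements, as one tested pipeline over synthetic data, the
computational analyses used to characterise a highly heterozygous diploid
*Saccharomyces cerevisiae* bioethanol strain sampled during industrial
fed-batch fermentation under two conditions — typical (TF) and bacterially
co-aggregated / flocculated (FL).  Four analyses share a common alignment
layer: expression quantification with an intergenic background filter,
two-library differential expression, allele-specific expression with
loss-of-heterozygosity (LOH) detection, and taxonomic profiling of residual
bacterial rRNA reads.

## Alignment model

Reads are short (36 bp by default), single-end and unstranded, placed
ungapped on the forward strand of a feature set (gene sequences, intergenic
regions, or rRNA references) allowing at most `max_mismatches`
substitutions (default 2).  A read whose best placement score is achieved
at more than one location is discarded as a repeat.  The matcher is k-mer
seeded (k = 12) with the pigeonhole guarantee — a read split into
`max_mismatches + 1` disjoint seeds must match one seed exactly at any
admissible placement — and every candidate is verified by direct
comparison, so the result equals a brute-force scan over all offsets (the
test suite asserts this equivalence on small references).  SAM files from
external aligners are accepted through the same result type.

Alignment is performed against the haplotype-1 gene sequences.  Because the
generator spaces SNPs at least one read length apart, a haplotype-2 read
carries at most one mismatch against this reference and is never lost to
the mismatch allowance.

## Expression and the background threshold

Expression is RPKM, `1e9 * C / (N * L)`, with `N` the reads aligned to
genes in that library.  Genomic background transcription is estimated from
intergenic regions longer than 500 bp: the per-library threshold is the
nearest-rank 0.95 quantile of the intergenic RPKM distribution.  The
quantile replaces a by-eye reading of the gene/intergenic RPKM
distributions with a reproducible statistic; the distributions can still be
plotted (`fermase threshold --plot`), and the quantile is tunable.  A gene
below threshold in every library of a comparison is excluded from DE
calling; a gene expressed in only one of two compared libraries is
retained, since exclusion requires falling below threshold in the
respective libraries being compared.

## Differential expression

The calling criteria are an expression ratio of at least 2 in either
direction and p < 0.01, with no multiple-testing correction by default
(Benjamini–Hochberg is available behind a flag).  The original analysis
fixed only these thresholds, so the statistic is specified here:

* **Two libraries.**  The exact conditional binomial construction for a
  rate ratio: given `C1 + C2` reads of one gene, `C1 ~ Binomial(C1+C2,
  N1/(N1+N2))` under the null of equal relative expression.  Two-sided
  p-values use the minimum-likelihood rule (`scipy.stats.binomtest`); an
  exact Fraction-arithmetic enumeration backs it in the tests.  Fold
  changes are ratios of normalised counts with a pseudocount of 1 applied
  to zero counts.
* **Two groups of libraries** (time points within a condition treated as
  replicates).  Welch's unequal-variance t-test on log2(RPKM + 1); fold
  change is the ratio of group mean RPKM, a zero mean replaced by 1.

The two-library test is exact and conservative at small counts — a 3:1
count split alone is never significant (p = 0.625) — which is the intended
behaviour of pairing a fold-change cutoff with an exact test.

## Allele-specific expression and LOH

Phased heterozygous SNPs assign each gene two haplotype sequences.  A read
overlapping a gene votes at every covered SNP; unanimous votes assign it to
haplotype 1 or 2, mixed votes make it conflicting (excluded from
informative depth), and SNP-free reads are uninformative.  Counting is per
read, so a read spanning several SNPs contributes once — the gene record is
the cumulative imbalance across all its phased SNPs.

Differential allelic expression (DAE) is called at a 2-fold ratio between
alleles: the major allele must hold at least 2/3 of informative reads.
The boundary is inclusive (exactly 2:1 qualifies; the integer comparison
`major >= 2 * minor` avoids floating-point edges), matching the reading of
"more than 66%" as the prose gloss of the 2-fold rule — at the exact
boundary the major-allele share floors to 66%.  A minimum informative depth
of 20 reads is required before any call; below that a 2-fold ratio is
statistically meaningless.  The original analysis stated no depth floor;
this is a deliberate tightening, and it is CLI-exposed.

DAE is determined per condition by pooling the condition's libraries, since
the reported quantity is DAE per fermentation condition rather than per
time point.

LOH appears as a run of consecutive genes whose reads derive essentially
from one allele.  The detector scans each chromosome's genes in coordinate
order and emits maximal runs of genes with major-allele fraction >=
`mono_fraction` (default 0.95) and the *same* dominant haplotype, bridging
up to `max_uninformative_gap` (default 2) consecutive uninformative genes —
the analogue of a SNP-free stretch inside a homozygous region.  Runs
shorter than `min_genes` (default 10) are dropped.  A segment's span is
first-gene start to last-gene end, inclusive; the breakpoint convention is
gene-based because expression data carries no finer signal.  An exhaustive
window-enumeration oracle checks the detector in the tests.

The restriction-digest utility (`insilico_digest`) predicts fragment sizes
for a cutter such as MboI (^GATC): cuts fall immediately before each site
occurrence, fragment lengths sum to the sequence length, and a SNP that
destroys the site yields no cut — which is exactly what makes the digest an
allele genotyping assay for a heterozygous site.

## rRNA taxonomy

Reads that fail gene/intergenic alignment are classified against a
lineage-labelled rRNA reference (SILVA-convention FASTA, semicolon
taxonomy) with the same matcher.  A unique best hit adopts the full
lineage.  Tied best hits are truncated to the lowest common ancestor of the
tied lineages — a documented, information-preserving variant of discarding
repeats; `--strict` reproduces pure discarding, and ties sharing nothing
below the domain are discarded either way.  Counts are tallied per rank
with an explicit unresolved bucket, families below 5% of classified reads
are dropped (the boundary is retained), and within-family species fractions
are computed for the survivors.  The bundled reference is synthetic (a few
short random fragments per lineage); real SILVA FASTA is accepted by the
same reader.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume:

* genes laid along chromosomes with intergenic gaps sampled above 500 bp,
  so every gap qualifies for the background set;
* phased SNPs per gene (sampling range configurable), spaced at least one
  read length apart so each read covers at most one SNP;
* a planted LOH block occupying the last genes of one chromosome (the
  "right arm"); the block's genomic span is a config field and the inner
  gaps are rescaled so it is honoured exactly;
* planted allelic imbalance (default 3:1) in three disjoint gene sets —
  both conditions, condition A only, condition B only — placed off the LOH
  chromosome; the favoured haplotype alternates between planted genes;
* optional intergenic background reads and an rRNA admixture specified as
  lineage -> read fraction.

Reads are error-free, and all planted compositions use exact
largest-remainder allocation rather than multinomial sampling: a gene at
informative depth 200 with a 3:1 ratio receives exactly 150 + 50
haplotype-tagged reads, and an rRNA lineage at fraction f receives exactly
round(f·N) reads.  Informative reads are placed over SNPs; the remaining
gene reads avoid SNP windows, so observed allele counts equal planted
counts.  Consequently the recovered quantities are deterministic given the
planted architecture and stable across seeds — at depth 200 the planted
major-allele count (150) clears the call boundary (134) by a fixed 16-read
margin, and sampling noise never enters.  Each library's RNG stream is
derived from (config seed, condition label hash), so conditions are
independent but reproducible, and identical configs produce byte-identical
FASTQs.

What the generator does **not** model: sequencing errors (an aligner
tolerance of 2 mismatches is still enforced and tested with mutated reads),
mapping bias between haplotypes, paired ends, introns/isoforms, coverage
heterogeneity along genes, overdispersed expression between conditions, and
phylogenetically realistic rRNA similarity (references are random, so
cross-lineage ambiguity is absent unless constructed).  Passing recovery
tests therefore demonstrates the correctness of the analysis logic under
the stated model, not robustness to real-data artefacts such as mapping
bias — the known caveat of ASE from RNA-seq alignment.

### Presets

* `smoke` — 2 chromosomes x 25 genes, informative depth 40, a 12-gene /
  24-kb LOH block, 3/2/2 imbalanced genes; builds and simulates in seconds.
* `paper_fig5` — 16 chromosomes, 1,510 genes (chr13 carries 160 so the
  140-gene block fits its right arm), informative depth 200 per gene per
  condition, 323,400 reads per library (1% intergenic background), a
  140-gene block spanning exactly 600 kb, and 55 / 61 / 33 imbalanced
  genes at 3:1.  The 3:1 ratio for the imbalanced sets is a modelling
  choice (their real ratios were not reported); the block size, span and
  set sizes are the reported values.
* `paper_fig1b_fl` / `paper_fig1b_tf` — 20,000 reads, half from a
  bacterial rRNA mock community.  Within Lactobacillaceae, *L. fermentum*
  holds exactly 93% (FL) or 41% (TF) of family reads — the reported
  values; the family-level envelope (60/25/15% and 50/30/20% across
  Lactobacillaceae, Acetobacteraceae, Bacillaceae) is a modelling choice
  satisfying "at least two other families, each at or above the 5%
  cutoff".  Fractions are chosen so every planted allocation is integral.

## Numerical choices and degenerate inputs

* Integer arithmetic at the DAE boundary; nearest-rank (not interpolated)
  quantiles; largest-remainder allocation with stable tie-breaks.
* RPKM with N = 0 or L = 0 raises rather than returning NaN.
* `de_two_library` with `C1 + C2 = 0` reports p = 1 and no call.
* Degenerate grouped tests (zero variance in both groups) report p = 1.
* An LOH run must start and end on a monoallelic gene; trailing
  uninformative genes are never absorbed.
* Empty references, unsorted gene lists, overlapping planted gene sets and
  fraction budgets exceeding 1 are rejected with explicit errors.

## Problem sizes

The default verification runs use the preset sizes above: the full
`paper_fig5` workflow (two 323k-read libraries, alignment, DAE, LOH,
comparison) completes in well under a minute on one CPU, and the
mock-community presets in about a second each.  These sizes were chosen as
the smallest at which the planted architecture matches the reported gene
counts one-to-one (140-gene block, 55/61/33 sets) while keeping 200x
informative coverage per gene.

## Known limitations

* The matcher is exhaustive-equivalent but desk-scale; it is not a
  replacement for a production aligner on real genomes (SAM import exists
  for that).
* No statistical ASE model (beta-binomial, overdispersion) — the 2-fold
  rule with a depth floor is the re-implemented decision rule.
* Grouped DE uses a t-type test on log-RPKM, not a count-dispersion model;
  with two few replicates the exact two-library test is the primary tool.
* Real Table-1-scale DE counts and alignment percentages depend on the
  deposited libraries and are out of scope here; the synthetic DE
  comparison is a null by construction.
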