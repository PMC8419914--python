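# Methods

`fstscan` implements a wild-vs-domestic divergence analysis as a reusable,
tested pipeline: SNP quality control, a windowed Weir–Cockerham Fst scan
with candidate-region extraction and gene annotation, genotype PCA, a
negative-binomial differential-expression stage with an FPKM summary, and
the intersection of Fst candidate genes with differentially expressed
genes. A synthetic-data module generates genotype, annotation and
expression data with known truth so every stage can be validated
end-to-end.

## Coordinate conventions

All coordinates are 1-based inclusive internally. BED input (0-based
half-open) is converted once at the boundary; region BED output converts
back. Windows are nominal `[start, start + window − 1]` spans on a grid of
starts `1 + k·step`; trailing windows keep their nominal bounds past the
chromosome end (no SNPs exist there, so only the printed bounds are
affected). Window bounds are reported as `[s, s + 49999]` for the default
50-kb window; some windowing tools print the open end (`s + 50000`)
instead, a purely cosmetic difference.

## Variant quality control

Three filters run in fixed order — hard thresholds, SNP-cluster removal,
missing-rate — followed by optional chromosome exclusion (for sex
chromosomes). The hard filters retain records with QUAL > 30, QD > 5,
FS < 60, MQ > 40, MQRankSum > −12.5 and ReadPosRankSum > −8.0, all strict
as written, so boundary values are removed. A record that lacks an INFO
annotation passes that one test by default: rank-sum annotations are
undefined at sites without heterozygotes, and failing on absence would
discard records for reasons unrelated to quality. The policy is
switchable (`missing_info="fail"`).

The cluster rule removes every SNP that lies in *any* placement of a
10-consecutive-base span containing more than three SNPs (the semantics of
the usual SNP-cluster annotations, not a fixed genomic grid). The
implementation is a sliding scan over sorted positions; the test suite
checks it against a brute-force enumeration of all span placements. The
missing-rate filter removes records whose missing-call fraction strictly
exceeds 0.1; a rate of exactly 0.1 is retained.

Each removal is attributed to the first rule, in the order listed, that
fails the record, so the per-rule counts in the QC report reconcile
exactly with the input and output totals.

## Fst estimation and the sweep scan

Per SNP, the two-population Weir–Cockerham (1984) variance components are
computed from non-missing diploid genotypes: `a` (between populations),
`b` (between individuals within populations) and `c` (within
individuals), with `θ̂ = a/(a+b+c)`. θ̂ is undefined — flagged, never
silently NaN-averaged — when a group has no calls at the SNP or the site
is monomorphic (`a+b+c = 0`). A fixed difference with no heterozygotes
gives θ̂ = 1 exactly. The test suite verifies the vectorized
implementation against an independent nested-ANOVA (mean-squares)
transcription of the same estimator, looped per individual, to 1e−10 on
random genotype configurations. Hudson's estimator is provided as a
cross-check (`hudson_fst`), not used by the scan.

Windows (default 50 kb, 25-kb step) aggregate as the ratio of sums
`Σa / Σ(a+b+c)` over the SNPs they contain — the standard weighted
windowed estimator, well-behaved under unequal group sizes; the mean of
per-SNP θ̂ is carried as a diagnostic. Each SNP contributes to every
window containing it (two, on this grid, except within the first step of
a chromosome). Windows with fewer than `min_snps_per_window` SNPs
(default 1) are ineligible for ranking. Negative window values are
reported as computed, not clamped.

The top fraction (default 1%) of eligible windows is selected with a
ceiling count, including all windows tied with the cutoff value, so the
selection is deterministic and never under-selects. Top windows are
extended by 50 kb on each side, clipped to the chromosome, and
overlapping or book-ended extensions are merged into candidate regions.
Any gene whose body overlaps a region by at least 1 bp is a candidate
gene; it is annotated with the best overlapping-region window Fst.

## Genotype PCA

The samples × SNPs dosage matrix is mean-imputed per SNP, centered, and
scaled by `√(2 p̂ (1 − p̂))` (allele-frequency, i.e. Patterson, scaling);
zero-variance columns are dropped and the decomposition is an exact SVD —
the inputs here are desk-scale, so no randomized sketching is needed.
Scores are scaled so the squared norm of each component equals its
eigenvalue, and the sign is fixed by making the largest-magnitude score
positive, which makes outputs reproducible across platforms. No LD
pruning is applied before PCA.

## Differential expression

FPKM is `count · 10⁹ / (gene length · library size)` and is reported as a
per-condition summary. Testing operates on counts: samples are normalized
by median-of-ratios size factors (falling back, with a logged warning, to
library-size ratios when no gene is nonzero everywhere). The per-gene NB
dispersion α (Var = μ + αμ²) is estimated by method of moments pooled
across the two conditions with weights `n_i − 1`, floored at 1e−8. The
Wald statistic divides the log2 fold change (condition 2 vs condition 1,
computed on moderated means with a 0.5 pseudo-count so one-sided zeros
stay finite) by its delta-method standard error.

Two-sided p-values use a Student-t reference with `n1 + n2 − 2` degrees
of freedom rather than a normal reference: with 7 samples per group the
moment estimate of α is noisy, a normal reference is anticonservative
(empirical type-I ≈ 0.074 at nominal 0.05 in null simulations), and the
t reference restores nominal calibration (≈ 0.050). This is the standard
small-sample correction for a variance estimated from the data.

Benjamini–Hochberg adjustment runs over all tested genes; genes with
all-zero counts are excluded from testing and from the BH denominator.
The DEG rule is `|fold change| > 1.5` on the raw (unshrunken) log2 fold
change and BH-adjusted p < 0.05, both strict, so exact-boundary genes are
not called. This stage is deliberately not a DESeq2 clone — no shrinkage
estimators, no outlier replacement — so gene lists will not match DESeq2
run-for-run; its guarantees are calibration and recovery on synthetic
truth, which the acceptance tests measure.

## Integration and enrichment

The integration table has one row per (gene, tissue) where the gene is
both an Fst candidate and a DEG in that tissue, sorted by tissue then
best window Fst. Gene identity is exact string match; no ortholog
mapping. Over-representation of a query gene list against user-supplied
gene sets (GMT) uses the one-sided hypergeometric tail `P(X ≥ k)` with BH
correction across sets; the universe defaults to all genes supplied and
is user-overridable. Depletion is out of scope.

## Synthetic data

Genotypes follow the Balding–Nichols model: per SNP an ancestral
frequency `p ~ Uniform(maf_min, 1 − maf_min)`, daughter-population
frequencies `p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, and diploid dosages
`Binomial(2, p_k)`. The closed-form property `E(Fst) ≈ F` gives an
analytic surface for calibration tests. Defaults describe the study
conditions the pipeline models: background F = 0.06 (near the
genome-wide wild-vs-domestic divergence), 20 diploids per group, one SNP
per ~500 bp, minimum ancestral frequency 0.05. Sweeps are planted by
raising F locally. SNP positions are uniform per chromosome (window
occupancy is then Poisson, which the tests exploit); missingness is
genotype-wise uniform. The model has no linkage disequilibrium,
recombination, demography or selection dynamics — passing tests
demonstrate estimator correctness and power under idealized marginal
divergence, not robustness to the haplotype structure of real data.

The annotation simulator draws QUAL/QD/FS/MQ/MQRankSum/ReadPosRankSum
values from strictly-passing or strictly-failing ranges (never boundary
values) for disjoint per-criterion failure subsets, so the hard filter's
output can be compared with planted truth exactly. Expression counts are
NB with per-sample size factors `Uniform(0.7, 1.3)` and planted ±log2
fold changes; the default design is 7 vs 7 samples, 5,000 genes, 10% DE
at |lfc| = 2, dispersion 0.05 — with explicit gene indices available for
planting DE genes inside a sweep in end-to-end fixtures.

## Problem sizes in the test and acceptance runs

Calibration uses 20+20 diploids and ~20,000 SNPs per divergence value;
sweep recovery uses twenty replicates of a 5-Mb genome at one SNP per
500 bp with a 100-kb planted sweep (F 0.25 over background 0.05); DE
calibration uses a 5,000-gene null and twenty 1,000-gene signal
replicates; the end-to-end fixture is a 1.5-Mb genome with 60 genes and
one sweep. These sizes make the Monte-Carlo bands in the tests (e.g.
type-I 0.05 ± 0.01, recovery ≥ 19/20) tight enough to be meaningful while
keeping the whole suite fast.

## Known limitations

- No LD/haplotype structure in the simulator; power estimates are
  optimistic relative to real data with background selection or
  bottlenecks.
- The DE stage's gene lists are not expected to match DESeq2's.
- Multiallelic records are skipped, not split, on VCF input.
- Enrichment depends entirely on the user-supplied gene sets and
  universe; there is no built-in annotation database.
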