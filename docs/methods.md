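# Methods and design notes

This note records the models, conventions and design choices behind the
package, in the order the pipeline runs them. Coordinates are 0-based,
half-open (BED convention) everywhere; a SNP at base k occupies [k, k+1).

## Locus definition

Independent risk loci are found by iterative clumping of SNP-level summary
statistics. The most significant remaining SNP becomes an index; every SNP
on the same chromosome within `exclude_dist` bp or with r² ≥ `exclude_r2`
is excluded; the process repeats until no candidate remains. Indices are
returned in increasing p order, with deterministic tie-breaking by
(p-value, chromosome, position). Two tiers are produced: supra-threshold
(p ≤ 5×10⁻⁸) and sub-threshold (5×10⁻⁸ < p < 10⁻⁴), the latter only after
removing every candidate in physical or LD proximity to a supra-threshold
index, so the two tiers are disjoint by construction. A single
`exclude_dist` serves both tiers.

`exclude_dist` defaults to 500 kb. A distance cutoff in the hundreds of
megabases would leave at most one locus per chromosome, which contradicts
the basic use case (several independent loci on one chromosome is the norm
in cancer GWAS); 500 kb is the conventional clumping radius. The parameter
is exposed for sensitivity analysis.

r² is the squared Pearson correlation of unphased dosage vectors
(composite LD), the convention used by standard clumping tools on dosage
data. It is computed from exact integer sums,
(n·Sxy − Sx·Sy)² / ((n·Sxx − Sx²)(n·Syy − Sy²)), with no square roots, so
copied columns give exactly r² = 1 and rational cases stay exact; the
block-membership test (r² ≥ 0.8) is inclusive and therefore sharp at the
threshold. LD is evaluated within chromosomes only; cross-chromosome
sample correlation is noise around 1/(n−1) and is never used for
exclusion. SNPs present in the statistics but absent from the panel are
dropped (with a warning) since their LD is undefined; a monomorphic index
yields a singleton block and distance-only exclusion.

The haplotype block of an index is the index plus every same-chromosome
panel SNP with r² ≥ `block_r2`; the block span is the half-open interval
covering all member SNP bases.

## Consensus binding sites

Peaks from all replicate datasets are pooled and clustered by
single-linkage with a strict ≥ 1 bp overlap criterion (bookended intervals
do not join). A cluster supported by at least `min_datasets` distinct
datasets becomes one consensus site spanning the union of its members. The
union (rather than the intersection) is the conservative choice for
overlap counting — it cannot split one binding event into two — and it is
what a downstream SNP-in-peak test sees.

## Overlap statistics

Three counting statistics are defined on a set of loci and a set of peaks:

* locus-wise overlap — loci with ≥ 1 member SNP inside a peak (`snp`
  mode; a `span` mode intersects the block span instead). A locus counts
  once however many peaks it touches.
* peak-wise overlap — distinct peaks containing ≥ 1 member SNP of any
  locus. This is the statistic for the converse (peak-shuffling) test,
  where one locus may legitimately hit two sites.
* proximity — loci overlapping or lying within `window` bp (default
  25 kb) of a peak. Distance is measured between the nearest covered
  bases, inclusive at the window, implemented by padding the merged peak
  intervals; `window=0` reduces exactly to direct overlap, and the count
  is monotone non-decreasing in the window.

The default mode is `snp` because the scientific question is whether an
associated variant itself sits in a binding site; `span` mode is kept for
sensitivity analysis.

## Permutation null models

Two shuffling schemes give the two directions of the enrichment question.

*Block shuffling*: each haplotype block keeps its length and internal SNP
offsets and is re-placed uniformly at random in the genome — destination
chromosome drawn with probability proportional to (length − block length
+ 1), start uniform over valid positions. Blocks are placed independently
and may overlap one another; an optional gap mask (rejection sampling) and
a no-overlap mode exist but are off by default, since the simplest uniform
model is the stated null. *Peak shuffling*: each peak keeps its length and
is re-placed fully inside a background region set (e.g. active enhancers),
with the destination region drawn proportionally to the number of valid
start positions it offers.

The empirical p-value is m/n_iter, m = #{iterations with null count ≥
observed}. This convention makes reported p-values integer multiples of
1/n_iter; at the default 100,000 iterations the granularity is 10⁻⁵.
When m = 0 the result is the bound p < 1/n_iter, carried as a flag and
never printed as p = 0. Two variants exist: add-one, (m+1)/(n_iter+1),
for conservative reporting; and mid-p (half weight on ties), used in the
calibration tests because the plain upper-tail p of a very discrete null
is stochastically larger than uniform by construction. The test is
one-sided for enrichment, matching the scientific question; depletion can
be read from the same histogram.

Both tests have a vectorised implementation (all iterations drawn at once
per locus/peak; 100,000 iterations of a 13-locus test run in ~0.3 s) and a
generic `permutation_test(observed, counter, shuffler, cfg)` that accepts
arbitrary counting/shuffling callables. The two consume randomness
differently, so they agree statistically, not draw-for-draw; each is
exactly reproducible under a fixed seed.

## Gene assignment

A locus's genes are the union of (a) genes whose span lies within
`near_window` (default 25 kb) of the block span and (b) genes whose
promoter — TSS ± `tss_window` (default 2 kb), inclusive at both ends —
intersects the target of a long-range chromatin interaction anchored at
the locus (matched by locus id, or by the interaction viewpoint
overlapping the block span). Interaction calls are consumed as a table;
deriving them from raw chromosome-conformation reads is out of scope.

## Ranking metric and GSEA

Genes are ranked by π = φ·(−log₁₀ pv) with φ the log₂ fold-change and pv
the differential-expression p-value, so the ranking rewards genes that are
both strongly and confidently regulated; pv = 1 gives π = 0, pv ≤ 0 is a
domain error, and p-values from the LRT are floored at 10⁻³⁰⁰ before the
log. Ties in π are broken by gene id for a deterministic order.

The enrichment score walks the ranked list; set members add
|π|^weight / Σ_set |π|^weight (weight defaults to 1; weight = 0 recovers
the classic Kolmogorov–Smirnov statistic; an all-zero-metric set falls
back to equal steps), non-members subtract 1/(N − N_set); ES is the
running-sum value of largest magnitude (first such rank on ties). The
null is random gene-label sets of the same size drawn from the ranked
universe — with three-replicate designs, phenotype permutation would be
too coarse to be useful. p is the fraction of same-sign null scores with
magnitude ≥ |ES| among same-sign nulls, and NES = ES / mean(|null ES| of
matching sign); this normalisation is stated here explicitly because
several conventions circulate. ES is invariant to positive rescaling of
π and is negated when every π flips sign.

## Count models

Counts are modelled as NB2: Var = μ + αμ², log link,
μ = exp(offset + β₀ + β₁x). Offsets are log median-of-ratios size factors
(geometric-mean reference over genes with no zero count; total-count
scaling with a warning when no such gene exists). Per gene, the dispersion
α is estimated by maximum likelihood — the joint MLE via statsmodels'
discrete NB model, falling back to profiling the likelihood over log α
(bounded 10⁻⁸…10⁴) with an inner IRLS fit when the joint optimiser fails
or leaves the admissible range — and the coefficients are then IRLS
estimates at that α (relative tolerance 10⁻⁸). Log-likelihoods are always
evaluated through the same NB pmf (Poisson below α = 10⁻⁸), so full and
null models are compared on one scale.

The genotype test fits expression against dosage (additive 0/1/2 by
default; a categorical coding with df = groups − 1 is available — which
coding a given study used is rarely stated, so both are exposed) and
compares it with an intercept-only fit by likelihood ratio, with
significance from the upper chi-square tail. The dispersion is estimated
under the full model and held fixed for the null fit — standard LRT
practice that keeps the comparison to one parameter. Negative LRT
statistics beyond −10⁻⁸ are clipped to zero with a warning. There is no
empirical-Bayes dispersion shrinkage: each gene's likelihood is
self-contained and therefore checkable against a generic optimiser, a
deliberate divergence from DESeq2-class moderation that costs some power
at very small n but keeps every fit auditable. The differential-expression
table used for GSEA comes from the same machinery with the condition coded
0/1 (the second sorted condition label is the "treatment"; φ = β₁/ln 2),
all-zero genes dropped.

Paired comparisons (e.g. tumour vs matched normal) use the Wilcoxon
signed-rank test on pair differences — the paired member of the Wilcoxon
family — two-sided, exact null for ≤ 25 informative pairs, normal
approximation with continuity correction beyond, zero differences dropped;
all-zero differences give the degenerate p = 1 with a flag.

## Synthetic data: what it emulates, and what it does not

The generator produces every input with planted truth, at a scale chosen
so the full suite runs in minutes on one CPU: a 4×5 Mb genome, a
100-sample panel with 260 LD blocks of 10 SNPs (25 kb each), 100 peaks
(400–1200 bp, ~0.4% genome coverage), 300 enhancers, 400 genes, and NB
counts with dispersion 0.05 and means 50–2000.

LD is generated by block-copy-with-flip: each block has a template dosage
column (binomial with MAF drawn from 0.1–0.5, redrawn if monomorphic) and
every member SNP copies it with per-entry resampling probability ε.
A flipped copy correlates with the template at 1 − ε, so two members
correlate at (1−ε)² and pairwise r² is (1−ε)⁴; ε = 1 − r²^(1/4) centres
pairwise r² on the target (default 0.9). Different blocks are independent,
so cross-block r² fluctuates around 1/(n−1).

GWAS truth: 6 causal blocks get an index SNP inside a peak and 6 outside
(defaults), with index p = 10^−U(9,20), linked same-block SNPs attenuated
(log₁₀ p scaled by U(0.4, 0.85)) and everything else i.i.d. Uniform(0,1) —
null p-values need no LD structure because the permutation null never uses
them, while the planted blocks carry the LD signal. Causal blocks are
mutually separated by ≥ 600 kb so that 500-kb clumping can resolve them;
to guarantee enough in-peak candidates, the feature generator centres one
peak on a member SNP of each of 6 well-separated blocks (with jitter) and
places the rest inside enhancers (80%) or uniformly, all peaks mutually
disjoint. Replicate peak datasets jitter each true peak's edges by ≤ 80 bp
in ≥ 2 of 3 datasets and add single-dataset noise peaks (mutually
disjoint, also across datasets), so a ≥ 2-dataset consensus recovers
exactly the true peaks.

Deliberately not emulated: coalescent/recombination-map realism, allele
frequency spectra, population structure, signal-dependent peak widths,
GC or chromatin covariates of peak placement, and library-size variation
between samples (size factors are therefore ≈ 1 in simulated data; the
size-factor code is tested on constructed cases instead). Passing tests
demonstrate the statistical machinery is correct and calibrated under the
stated model — not that real data meet that model.

The printed 13-locus susceptibility table is encoded verbatim as a fixture
(names, index SNPs, p-values, proximity labels, one long-range interaction
flag, per-gene regulation labels). Its geometric realization places each
locus on its own 2-Mb synthetic chromosome and lays peaks so that the
published counting is reproduced (4 direct overlaps, 5 distinct sites hit,
7 loci within 25 kb); which overlapping locus hits two sites is not
identified in print, so the realization assigns the double hit to the
most significant locus — a synthetic choice that affects geometry only.
The regulation arrows are labels only; those genes are not simulated.

## Pipeline

`run_full` executes load → consensus → clump (both tiers) → permutation
tests (direct, ±25 kb, converse) → gene assignment → rank table → GSEA of
the locus-assigned gene set → genotype LRT per assigned gene → paired
comparison, logging at stage boundaries with input checksums, and aborts
with the stage name on failure. One global seed is expanded into
independent per-stage seeds via `SeedSequence`, so a config + seed pair
yields a byte-identical JSON report. `summarize` renders the report as
text plus null-histogram figures (observed-value marker) and the GSEA
running-sum curve.

## Numerical conventions collected

* empirical p = m/n_iter; m = 0 reported as a bound; add-one and mid-p
  variants by flag.
* r² from exact integer sums; inclusive thresholds (≥) for block
  membership and proximity windows.
* proximity = padded-interval membership, inclusive at the window.
* ES extremum: largest magnitude, earliest rank on ties; π ties broken by
  gene id.
* NB dispersion bounded to [10⁻⁸, 10⁴]; Poisson likelihood below the lower
  bound; LRT clipped at 0.
* GSEA p floored as a bound when no same-sign null score reaches |ES|.

## Known limitations

* The clumping r² loop is O(loci × candidates) per chromosome; fine for
  tens of thousands of SNPs, not tuned for biobank-scale panels.
* The converse test's vectorised path counts peak-wise hits only; other
  statistic/shuffle combinations go through the generic (slower) route.
* No multiple-testing layer across gene-set collections; the GSEA here
  tests the handful of locus-derived sets the analysis defines.
* The NB fallback optimiser profiles a single dispersion per gene; designs
  with more than one covariate column per model are not exposed.
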