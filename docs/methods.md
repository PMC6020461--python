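# Methods

This note documents the statistical model behind `m5ctopo`, the choices the
package makes where the methodology is genuinely open, and what the
synthetic test bed does and does not establish about real data.

## Observation model

Bisulfite treatment converts unmethylated cytosine to uracil (read as T);
methylated cytosine resists conversion. At a cytosine covered by `n` reads,
with true methylation level `m` and background nonconversion probability
`p0`, each read is unconverted with probability

    q = m + (1 - m) * p0,        n_meth ~ Binomial(n, q)

The methylation ratio (mRatio) is the plug-in estimate
`n_meth / (n_meth + n_unmeth)`, i.e. one minus the observed conversion
rate — the RNA analogue of the DNA beta value. `p0` defaults to 0.0275, a
typical noise floor for poly(A)+ RNA bisulfite libraries (observed floors
in published libraries span roughly 0.8–3%).

## Site calling

The background is the pooled (unconverted, converted) counts over all
retained sites — valid because the vast majority of covered cytosines are
unmethylated, so the pool estimates `p0`. Each site with coverage ≥ 10 is
tested by a one-sided Fisher's exact test of its 2×2 against the pool,
alternative "site's unconverted odds exceed the background odds"; the
site's own counts are first removed from the pool so it is never tested
against itself. A binomial-tail mode (`P(X ≥ n_meth)`,
`X ~ Binomial(n, p0)`) is exposed as the large-pool limit. P-values are
Benjamini–Hochberg adjusted within each replicate; a site is called when
FDR < 0.05.

Multi-replicate rule: a site is called methylated only when it passes
FDR < alpha in *every* replicate; a non-called site is retained only when
present with coverage above the minimum in every replicate. Counts are
summed across replicates for the combined record. With a single replicate
the combination step is the identity. Whether the background should be
pooled per replicate or across replicates is not settled; the package pools
per replicate (each library has its own conversion efficiency), and this is
the only mode the pipeline uses.

Filtering precedes background estimation and calling: sites inside
predicted RNA secondary-structure regions (double-stranded RNA resists
conversion and mimics methylation) are removed via a user-supplied BED
mask, and sites off annotated exons are removed — except on the
mitochondrial chromosome, which is kept wholesale. Structure prediction is
deliberately external; for long sequences the conventional tiling is
2000 nt windows with 1000 nt steps, applied above 8000 nt, and
`tile_windows` reproduces exactly that tiling. The structure filter is
unstranded by default (a stranded flag exists): a mask interval usually
marks a paired region whose reverse complement is equally suspect.

## Enrichment

Enrichment of called sites in a stratum (mRNA region, chromosome,
trinucleotide context) is

    OR = (k_in / n_in) / (K_total / N_total)

with covered cytosines — not all nucleotides — as denominators, and a
two-sided Fisher's exact test on the in/out 2×2. Because the headline OR
divides by the *total* rate (which contains the stratum), it understates a
simulated in/out factor; `EnrichmentResult` therefore also reports the
in-vs-out rate ratio with a Katz log-scale 95% CI and the in/out sample
odds ratio. The Katz interval assumes independently placed sites; under
block-clustered placement the true sampling variance is larger and any
independence-based interval undercovers, which is why the recovery checks
run the generator in i.i.d. placement mode.

Site-to-region assignment splits each site's unit weight evenly over all
(isoform, region) associations at its position, so isoform information is
retained rather than collapsing to a longest transcript. Weighted counts
are rounded to integers only for the Fisher test; ratios use exact weights.

The default enrichment background is non-called covered sites
complemented by called sites (i.e. all covered cytosines); using called
sites of another class as background is possible by passing the
corresponding result subsets.

## Metagene profile

Transcripts whose 5'UTR, CDS and 3'UTR each exceed 100 nt are placed on a
tripartite axis [0, 3), one unit per region (not length-proportional — a
dedicated 5'UTR panel is the point). A site at fractional offset `f`
(5'→3' in transcript orientation) of region `u ∈ {0,1,2}` maps to `u + f`;
ambiguous sites contribute split weight. Called and non-called histograms
(150 bins) are each normalised to unit mass.

## Clustering

Three statistics on deduplicated called positions per (chromosome, strand):

* proportion of called sites with another called site within `d` nt
  (default 10), genomic distance;
* fraction of called sites whose adjacent (1 nt) candidate cytosine is
  also called (dimers);
* Pearson correlation of mRatios over site pairs, binned by distance
  (1–3, 4–10, 11–30, 31–100, 101–300 nt), each unordered pair entering
  symmetrically so the estimator is order-invariant.

The null for the first two is a conditional permutation: within each gene
carrying at least one called site, the number of called states is
preserved and re-placed uniformly over that gene's covered cytosines;
p = (1 + #{null ≥ observed}) / (1 + n_perm) (add-one, so p > 0). Distances
are genomic rather than transcript-relative because the input reports are
genomic; a transcript-coordinate variant would differ only across splice
junctions. Correlations are computed over all covered sites (coverage
≥ 10), not only called ones, so the estimate reflects co-methylation of
levels rather than co-detection.

## DNA–RNA comparison

RNA and DNA records are paired at identical (chromosome, position) with
the DNA strand required to equal the RNA strand; CpG strand symmetry is
*not* collapsed by default because the RNA side is intrinsically stranded
(a merge flag exists for sensitivity analysis). Per-context Pearson and
Spearman correlations of the two mRatios are reported, the CG-containing
contexts (ACG/CCG/GCG/TCG) being the informative strata since DNA
methylation is CpG-confined. mRatios enter raw (no logit), matching the
scale on which they are defined.

## Differential methylation

The fold change at a site is the odds ratio
`(n_meth_1/n_unmeth_1) / (n_meth_2/n_unmeth_2)` with Haldane–Anscombe +0.5
on all four cells exactly when some cell is zero. Significance is a
two-sided Fisher's exact test on the pooled counts; the test sits behind a
narrow interface so a dispersion-aware count-model backend (e.g. paired
negative-binomial tests) can be slotted in where biological replicates
warrant it. The default significance rule is unadjusted p < 0.05, with an
FDR mode. Genes are classified hyper / hypo only when every significant
site agrees; otherwise mixed — the strict rule keeps both bookkeeping
styles (disjoint hyper/hypo partitions, and explicit overlap counts)
consistent. Region placement of hypermethylated sites reuses the
enrichment machinery with hyper sites as foreground and all differential
sites as background.

## Expression and half-life association

Expression and methylation both derive from the same libraries, so their
errors are coupled. The replicate-splitting device removes the coupling:
for each of the three leave-one-in splits, expression fold change is
computed from one replicate per condition (median-of-ratios size factors,
pseudocount 0.5 — dispersion shrinkage is irrelevant since only the FC
enters a correlation) and methylation fold change (gene-level pooled log2
odds ratio) from the other two. No replicate ever informs both sides of a
split, which tests verify structurally.

Half-life association is a binomial-family GLM — logistic regression of
methylation status on log half-life with log2 expression as the covariate.
Expression enters as the confounder: better-expressed genes yield more
reads and are easier to call methylated regardless of biology. The GLM
direction is fixed this way because methylation status is the binary
variable; half-life enters on the log scale (half-lives are right-skewed).
Fitting is plain IRLS to score norm < 1e-8 (cap 100 iterations); complete
separation is detected and flagged rather than silently reported. The
visual check restricts to genes with log2 expression in [7, 11] and draws
tricube-weighted local-linear (loess-style) curves per methylation class;
local-linear fitting is exact on linear data, which the tests exploit.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume:

* disjoint gene loci (1–3 exons; 5'UTR/CDS/3'UTR each ≥ 100 nt by
  default) on four nuclear chromosomes plus a mitochondrial chromosome
  holding single-exon noncoding transcripts (5% of genes by default);
  uniform-composition random sequences supply trinucleotide contexts;
* methylation placement by region-specific probabilities (defaults 0.06
  for 5'UTR vs 0.02 elsewhere — the 3× 5'UTR enrichment; 0.4 on
  mitochondrial transcripts), optionally through a block model: the
  transcript is tiled into 10 nt blocks, a block switches on with
  probability `p_region / p_within`, and sites in an on-block are
  methylated with `p_within` (default 0.8), sharing the block's base
  mRatio up to sd 0.05 jitter — this produces the proximity clustering,
  dimers and distance-decaying mRatio correlation; the marginal per-site
  rate is `p_region` either way;
* true mRatios of methylated sites from Beta(5, 2) (right-skewed, high
  levels), coverage from a negative binomial (mean 30, dispersion 5 —
  overdispersed, so the coverage ≥ 10 filter is exercised);
* a paired DNA methylome over every exonic cytosine on both strands: at
  CG-context sites shared with the RNA truth, the DNA level is drawn
  through a Gaussian copula targeting Spearman correlation `rho` with the
  RNA level (default −0.5; normal-score transform, so the target is
  attained exactly only for continuous RNA marginals — the pairing
  experiment therefore draws continuous Beta(2,2) RNA levels at CG sites);
  non-CG DNA sites are unmethylated;
* a two-condition expression/methylation experiment with per-gene latent
  log2 fold changes drawn bivariate-normal at correlation `rho_fc`
  (default 0.3, 1000 genes — the sampling sd of a correlation at n genes
  is ≈ (1−ρ²)/√n ≈ 0.03, small against the recovery checks); and a
  half-life table with
  `log(halflife) = a + b·methylated + c·log2(expr) + noise` plus an
  expression-dependent methylation probability, giving the GLM a
  recoverable effect behind a real confounder.

All randomness flows from one integer seed through numpy's PCG64;
identical configs give byte-identical outputs.

The generator makes no claim to be a model of real libraries. It does not
emulate alignment or M-bias artifacts, PCR duplicates, sequence-specific
conversion failure, isoform diversity (one transcript per gene), realistic
base composition, or dependent noise between expression and methylation
within a replicate. Passing recovery tests therefore demonstrates that the
estimators and tests are correct and calibrated under their stated
assumptions — not that those assumptions hold in any particular dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen to
make Monte-Carlo error small relative to each check: 10,000 sites for
calling calibration; exhaustive Fisher enumeration over all ~35,000 2×2
tables with margins ≤ 20 (exact rational arithmetic in the oracle, ties
included by integer comparison); 100 seeded simulations of 100 genes for
enrichment-CI coverage; 500 permutation-test replications (199 permutations
each) for null calibration; ≥ 2000 CG pairs for copula recovery; 100 GLM
power runs at 3000 genes and 300 null runs for the KS uniformity check.
Degenerate inputs are handled explicitly: zero-coverage sites are dropped
before calling, zero cells trigger the continuity corrections noted above,
correlation strata with fewer than 3 pairs or zero variance are reported
absent with a warning rather than as NaN surprises.

## Known limitations

* Fisher's exact test is conservative on discrete tables; at shallow
  coverage its null rejection rate sits below nominal (the calibration
  test runs at coverage 500 where discreteness is mild).
* The per-replicate pooled background slightly deflates p-values for the
  tiny fraction of truly methylated sites contaminating the pool; with
  methylation rates of a few percent the effect is negligible.
* The clustering permutation null conditions on per-gene called counts;
  it does not model coverage-dependent placement of candidate sites.
* `distance_correlation` weights every pair equally, so genes with many
  covered cytosines dominate short-distance bins.
* The differential test ignores within-condition biological dispersion
  when replicates are pooled; treat borderline sites accordingly.
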