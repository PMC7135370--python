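# Methods

`pleioscan` implements a transcriptome-based analysis of local
adaptation and pleiotropy: variants called from expressed genes are
scanned for spatially varying selection, the candidate genes are
characterized with diversity and sweep statistics, their regulatory
reach is measured by trans-eQTL mapping and signed co-expression
connectivity, and a forward Wright-Fisher simulation asks when a
pleiotropic QTL is favoured.  Everything runs against synthetic
cohorts with planted, machine-readable truth, so each stage can be
scored for calibration and recovery without external data.

## Data model and filtering

Genotypes are biallelic SNP dosages (0/1/2, `-1` missing) over
individuals x sites; one transcript contig is one gene.  Filtering
follows standard transcriptome-SNP practice: site quality >= 30,
genotype quality >= 20 and genotype depth >= 6 (per-genotype masks, as
in VCFtools), per-site heterozygosity < 80%, missingness < 20%, and —
only for the association analyses (selection scans and eQTL mapping) —
minor allele frequency >= 0.05.  Diversity, SFS and sweep statistics
run on the non-MAF-filtered call set, since removing rare variants
destroys exactly the spectrum classes those statistics read.
A coverage QC reports the squared correlation between genotype and
read depth (additively coded and as a heterozygote indicator); in
expression-derived genotype data these should be near zero after
filtering.

Unfolded site frequency spectra are built from sites with known
ancestral allele and complete genotypes, so every included site shares
one haploid sample size and the spectrum total equals the number of
included polymorphic sites.  Real panels with pervasive missingness
would need hypergeometric projection; the synthetic cohorts have
near-complete calls, so projection is out of scope.

## Diversity and neutrality statistics

Per gene (span = genotyped sites assigned to the gene, so theta values
compare only within a run): pairwise diversity theta_pi, Watterson's
theta_W, Tajima's D with the 1989 variance constants, and a normalized
Fay & Wu's H contrasting theta_pi with the high-frequency-weighted
theta_L = (1/(n-1)) sum_i i, using theta_W and the unbiased theta^2
estimator S(S-1)/(a1^2 + b_n) in the variance.  Differentiation
between two focal populations uses the Hudson-form FST with
ratio-of-averages aggregation (chosen for documented small-sample
behaviour; the estimator choice is isolated behind one function) and
absolute divergence d_XY.  Missing genotypes are dropped pairwise;
each site uses its own haploid n.

## Sweep composite likelihood ratio

Each gene is tested for a recent sweep against the dataset-wide
unfolded SFS.  A lineage at distance d bp from the swept site escapes
the sweep with probability `p_escape(d) = 1 - exp(-d / alpha)`, where
alpha (bp) is the sweep's footprint scale: alpha -> 0 recovers the
background; larger alpha distorts a wider region.  Lineages that fail
to escape coalesce into the single hitchhiking lineage, so the
post-sweep spectrum is the background subsampled to the escapees plus
one, conditioned on polymorphism; class probabilities are tabulated on
a 201-point escape-probability grid.  The candidate position grid is
the gene's variable sites; the candidate site itself is treated as the
sweeping allele (its likelihood term equals the background term),
which nests the null exactly, and a minimum escape probability
(`pe_floor = 0.05`) admits soft or incomplete sweeps so
near-fixed-but-not-fixed frequencies do not categorically reject a
sweep centred on them.  The alpha grid is 20 log-spaced values chosen
so escape probability at the gene half-width spans (0.01, 0.99); ties
resolve toward the smaller (more conservative) alpha.  CLR = 2 x
(max sweep log composite likelihood - background log likelihood) >= 0.
Distances run along transcript coordinates, which understates genomic
recombination distance; this is a known limitation of transcript data.

## Selection scans

The differentiation scan regresses each scaled SNP on K orthonormal
genotype PCs, converts the per-axis t statistics to exact normal
scores by probability integral transform, and takes a robust
(median-centred) Mahalanobis distance, rescaled by the genomic
inflation factor lambda = median(d^2)/median(chi^2_K), with chi^2_K
p-values.  LD pruning (r^2 < 0.1 in a trailing 200-SNP window) is
available for the PCA itself.

The environmental-association scan regresses each SNP on an
environmental axis plus K latent factors.  The latent factors are the
leading PCs of the dosage matrix *after projecting out the
environmental axes*: plain genotype PCs absorb a latitudinal cline
almost completely and leave the scan powerless, whereas the ridge
LFMM estimates factors jointly; the residual construction is the
package's one-step approximation of that behaviour, and the method is
labelled "env" to make clear it is not the LFMM estimator.  The env
term's t is inflation-corrected against its t reference; the per-SNP
summary takes the best axis with a Sidak correction for the number of
axes (without it the min-p across axes is non-uniform under the null).

q-values use Storey's procedure: pi0 estimated on the lambda grid
0.05..0.95 with a cubic smoothing spline evaluated at the grid
maximum (pi0 = 1 for fewer than 100 tests).  A gene is an outlier
under a method when any constituent SNP has q < 0.05 (the counting
rule of the emulated analysis); note this aggregation does not control
FDR at the gene level — calibration guarantees are stated for the
SNP-level q-values.  The S-controlled regression (z-scored per-gene
minimum p on S and outlier status) checks that outlier status is not
an artifact of gene SNP counts.

## Trans-eQTL mapping

Expression is first residualized on its leading two expression PCs
(removing the geographic expression gradient), then every SNP x gene
pair is tested with expression ~ dosage + admixture covariates (K-1
simplex columns), streamed in SNP blocks through a precomputed QR
covariate projection — exact OLS algebra throughout.  Storey q over
the pooled test set; sources of significant associations are eQTLs,
targets are eGenes; self-pairs are tested by default (transcript SNPs
have no cis/trans positional split) with a `drop_self_pairs` option.
The eGenes-per-eQTL model is a logistic regression of the
multi-target indicator on outlier status with S as covariate, with an
L2-penalized fallback flagged under separation.

## Co-expression network

Signed WGCNA-style adjacency a_ij = ((1 + cor)/2)^6 over corrected
expression; connectivity k_i = sum of adjacencies — the pleiotropy
proxy.  TOM_ij = (sum_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 - a_ij).
Modules come from average-linkage clustering of 1 - TOM with a static
cut at the 0.97 quantile of merge heights and a 30-gene minimum
(smaller clusters are unassigned, label 0).  Dynamic tree cutting is
deliberately simplified to a static cut: downstream analyses consume
only module membership and connectivity, and connectivity does not
depend on the cut at all.  Per-module outlier enrichment is a Fisher
exact test with q-values across modules.

## Integration statistics

Fisher exact enrichment with conditional-MLE odds ratios; percentile
bootstrap CIs for flagged-gene percentages; standardized (z-scored
response and continuous predictors, ddof = 0) OLS models of diversity
on connectivity/expression level/expression variance and of
connectivity on outlier status; a logistic model of eQTL status on
outlier status controlling S; and the label-permutation fit test:
observed R^2 of stat ~ S + outlier against the R^2 distribution under
random outlier reassignment, with the add-one p convention
(1 + #{perm >= obs})/(n_perm + 1), default 10,000 permutations.  The
connectivity-vs-p-value trend fits a cubic smoothing spline and
reports the overall sign, an OLS slope CI, and whether the fitted
derivative changes sign in the interior (an intermediate mode).

## Synthetic cohorts

The generator emulates the study design: 15 populations x 5
individuals along a 15-degree latitudinal transect; two ancestral
clusters (Balding-Nichols drift, F = 0.05 between clusters) blended by
a smooth admixture gradient, plus population-level
isolation-by-distance drift (0.004 per degree of latitude); derived
allele frequencies from a truncated neutral 1/p density.  5% of genes
(10% in the denser test fixtures) are adaptive: their sites get a
monotone latitudinal frequency cline (default delta 0.3 across the
transect), and half of them additionally get sweep-distorted spectra —
derived counts pushed into the rare and high-frequency classes, with
derived copies placed along the latitude gradient in the direction the
site already leaned, because local sweeps in this design drive the
North-South differentiation rather than erase it.  Read depth is
log-normal and independent of genotype, giving the coverage QC a true
null; ~5% of sites have unknown ancestral state.

Expression: 8 modules with one latent factor each; hub genes load 0.9,
others 0.45; a north-south factor (loading 0.6) mimics the structure
removed by expression-PC correction; Gaussian noise sd 0.5.  10% of
background genes are hubs, but adaptive genes are hubs at five times
that rate — the elevated network centrality of adaptive loci is the
planted pattern the connectivity comparisons are built to detect, and
the coupling is set strong enough (half of adaptive genes) to shift
their whole connectivity distribution, not just its tail.
Planted trans-eQTLs: adaptive genes are sources at rate 0.30 with two
targets, background genes at 0.12 with one target (anchored to the
emulated study's ~14% transcriptome-wide eQTL rate); targets are drawn
from non-adaptive genes, which is the mechanism behind eGene depletion
among adaptive genes; the causal SNP is a common variant (sample MAF
>= 0.2 — a trans-eQTL detectable in 74 individuals is necessarily
common), with default effect 1.0 (~30% of target variance).

What the generator does not emulate: linkage disequilibrium within
genes beyond shared drift, realistic transcript length variation,
count-based expression noise (it generates on a normalized scale
directly), cis-regulatory architecture, or coalescent genealogies
(Balding-Nichols drift keeps the neutral SFS only approximately
neutral).  Passing recovery tests therefore demonstrate the methods'
correctness and calibration on the assumed structure, not performance
guarantees on real transcriptome panels.

## Forward simulation

A single 50 kb region (10 kb genic core) in N = 10,000 random-mating
diploids; mutation 1.5e-8 and recombination 5e-8 per site per
generation; 10N burn-in; after selection starts, new mutations are QTL
mutations with probability 0.10 (genic) / 0.01 (elsewhere), drawing
additive effect vectors on all n phenotypes from a multivariate
Gaussian (sd 1, pairwise covariance 0.1; a zero-covariance variant is
one flag away).  Phenotypes start at 0; fitness is the printed
double-damped Gaussian w = exp(-(1/2) sum (z_i - z0)^2 / (2 Vs)) with
Vs = 10 (a `fitness_form="standard"` option drops the outer 1/2).
Burn-in mutations are permanently neutral, which both respects the
stated order of events and guarantees the exact initial phenotype of
0 — and implies burn-in length cannot influence recorded fitness.

Because log fitness is additively separable across phenotypes, a
class controlling n phenotypes has raw mean fitness approximately
equal to the per-trait fitness to the n-th power; raw mean fitness
therefore always decreases with pleiotropy at a distant optimum, at
any scale or recording time (verified empirically up to the full
N = 10,000 configuration).  The quantity on which pleiotropy classes
are comparable is the adaptive gain — mean fitness relative to the
class's selection-onset baseline w(z = 0) — and that is the fitness
estimate the grid summarizes and normalizes by default (the raw means
are always retained in the replicate table).  Far from the optimum
(z0 = 10) the gain rises steeply with pleiotropy, because a mutation
touching many displaced traits offers a much larger selective
advantage; near the optimum (z0 = 1) pleiotropic mutations are mostly
deleterious and the less pleiotropic classes keep the advantage.

Desk-scale configuration (`SimConfig.desk_scale()`): N = 200, L = 5
kb, rates x 50 (preserving per-site population-scaled mutation and
recombination), burn-in 200 generations (legitimate because burn-in
variants never touch fitness), recording after 500 generations.  The
window is an absolute duration rather than 0.1 N of the rescaled
population: the window must admit a meaningful QTL mutation supply
(~20 expected mutations here), whereas 0.1 x 200 = 20 generations
would leave most replicates mutation-free and the reference class
degenerate.  Per-(n, z0) classes are summarized by medians and IQRs
and normalized against the n = 1 class (median 0, IQR 1, exact by
construction).

## Problem sizes used by tests and the acceptance script

Chosen as the package's standard desk-scale configurations: pipeline
fixtures of 600 genes x ~20 sites/gene (75 individuals), calibration
fixtures of 150-250 genes, power simulations of 100-gene cohorts over
10 seeds, and simulation grids of 30 replicates over
n in {1, 5, 10, 20} x z0 in {1, 10} with five master seeds for the
direction checks.

## Known limitations

- The CLR model's escape-probability table is discretized (201 bins);
  likelihoods are accurate to ~5e-3 in class probability.
- The environmental scan is an approximation of latent factor mixed
  models, not a reimplementation; with environment-confounded
  structure its false-positive control relies on the genomic inflation
  correction.
- Static-height module cutting merges or drops modules that dynamic
  tree cutting would resolve; module counts are therefore
  configuration-sensitive even when connectivity is stable.
- The Wright-Fisher engine tracks whole haplotypes as mutation-id
  tuples; it is designed for desk-scale parameters, and full-scale
  runs (N = 10,000, 10N burn-in) are supported but slow (minutes per
  replicate).
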