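# Methods

`ovinet` re-implements, as a tested library, a multi-trait genomic analysis
of 14 milk and cheese-making traits in a commercial dairy-ewe population:
quality control and genomic relationships, REML genetic parameters and
genomic breeding values, mixed-model GWAS, a multi-trait pleiotropy
statistic, random-candidate-set stepwise marker selection, and PCIT
co-association networks. A synthetic-data module generates populations with
the published genetic architecture so that every stage is testable without
access to the original genotypes.

## The mixed model

Every variance-component computation rests on the GBLUP mixed model

    y = Xb + Za + e,    a ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2)

where `G` is the VanRaden method-1 genomic relationship matrix
`ZZ' / (2 * sum_j p_j (1 - p_j))` with `Z = M - 2p`, observed allele
frequencies, and mean-imputed missing dosages. The fixed design `X` holds an
intercept, drop-first dummies for age-at-parturition x number-of-births
(18 levels), flock test day (12 levels) and number of born lambs (2 levels),
plus days in milk as a covariate; rank-deficient columns realized in small
simulated data sets are dropped with a warning.

**Univariate REML.** The GRM is eigendecomposed once (`G = U D U'`), data and
design are rotated by `U'`, and the restricted likelihood is profiled over
the variance ratio `lambda = sigma_a^2 / sigma_e^2`: at fixed lambda the
residual variance and fixed effects have closed forms, leaving a 1-D
optimization over `log lambda` in [-18.5, 18.5]. Because the profile can
have local optima when the phenotype's covariance deviates from the GRM, a
41-point coarse scan brackets the global optimum before the bounded refine
(tolerance 1e-6). Standard errors of `(sigma_a^2, sigma_e^2)` come from the
inverse average-information matrix at the optimum, with the h^2 SE by the
delta method. Boundary solutions (h^2 near 0 or 1) are clamped, not errors.
A 200-point log-spaced grid search over lambda serves as an independent
cross-check in the test suite (agreement to |dh^2| <= 0.01).

**Bivariate REML.** On the same rotated scale the 2-trait covariance is
block-diagonal in 2x2 blocks `V_i = d_i * Sigma_g + Sigma_e`, so one
likelihood evaluation is O(n p^2). The restricted likelihood is maximized
over `(log sigma_a1^2, log sigma_a2^2, atanh r_g, log sigma_e1^2,
log sigma_e2^2, atanh r_e)` by Nelder-Mead started at the univariate fits
(plus one restart from the incumbent); the atanh parameterization absorbs
the |r| -> 1 boundary, with |atanh r| capped at 6 (|r| <= 0.99999) and
flagged. SEs come from the observed information (numerical Hessian) with the
delta method for `r_g`. This direct maximization reaches the same optimum as
sequential average-information updates and is more robust near the
correlation boundary; multi-start checks on low-heritability replicates
confirmed the reported optima are global. Both traits' complete cases are
used (the fit requires >= 50 overlapping animals).

**GEBVs and the cheese-merit z-score.** Breeding values are the BLUP
`a_hat = sigma_a^2 G V^{-1} (y - X b_hat)`; animals without phenotypes
(non-coagulating ewes on cheese traits) are predicted through their genomic
covariance with phenotyped animals. The across-trait z-score standardizes
each GEBV column, flips the sign for the traits where smaller values mean
better cheese-making (rennet clotting time, curd-firming time, the RCT/A60
ratio, somatic cell count, milk pH), sums, and standardizes the sum — mean
exactly 0, SD exactly 1 by construction.

## GWAS and pleiotropy

The default association backend is EMMAX-style: variance components fixed at
the null-model REML estimates, each SNP tested as a fixed covariate by GLS
under `V = G sigma_a^2 + I sigma_e^2` (one rotation shared across all SNPs
and traits). A GBLUP back-solving backend (SNP effects from the breeding
values) is available and labelled in the output; at `sigma_a^2 = 0` the
EMMAX test reduces to OLS exactly. P-values are two-sided normal on
`t = beta/se` — at n ~ 1000 the t-distribution correction is negligible.

The pleiotropy statistic of gene i is `MT_i = t_i' V^{-1} t_i` over its
signed t-values across the 14 traits, with `V` the trait-correlation matrix
of t-values estimated over all genes (optionally trimming the top |t| rows;
ridge 1e-6 if singular). Under the null MT is approximately chi-square with
df = number of traits; p-values use that reference.

## Gene-representative SNPs and stepwise selection

SNPs are assigned to genes when they fall within the gene span or 20 kb on
either side (inclusive at exactly 20,000 bp). Each SNP keeps its nearest
gene body (ties: smaller gene start, then gene id) and each gene keeps the
single SNP nearest its midpoint (ties: smaller position), so all downstream
analyses operate on one representative SNP per annotated gene.

Stepwise selection grows a marker set from the gene-linked pool: each step
draws `n_candidates` random blocks of `step_size` SNPs from the unselected
pool, scores each block by the across-trait mean of
`sigma_a^2(current + block) / sigma_a^2(full pool)` (subset GRM, univariate
REML per trait, eigendecomposition shared across the 14 traits), and keeps
the best block permanently. Fractions are reported unbounded above 1. The
published run used 1000 candidate blocks of 50 SNPs; desk-scale defaults are
100 blocks of 10, with the published values one config switch away.
Candidate blocks may overlap each other (not the selected set) — the
simplest reading of random sampling per step. Ties break on the lowest
candidate index within the step's RNG stream; per-step streams are spawned
from the master seed so interrupted runs resume bit-identically. Candidate
REML refits warm-start from the full-pool variance ratios with an
automatic fall-back to the full search range, which the tests require to
match cold starts within 1e-4.

From the trace, two gene sets are extracted: the first step whose mean
fraction strictly exceeds 0.95, and the argmax step (earliest on ties). A
random baseline re-scores `n_rep` uniformly drawn same-size subsets; the
off-diagonal Pearson correlation between each step's GRM and the full-pool
GRM tracks how relationships re-organize along the selection.

## PCIT co-association networks

Gene-gene co-association is the Pearson correlation between two genes'
t-value profiles. PCIT examines every trio (x, y, z): first-order partials
`r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))`, trio tolerance
`eps = (r_xy.z/r_xy + r_xz.y/r_xz + r_yz.x/r_yz) / 3` (zero-denominator
ratios contribute 0), and edge (x, y) is rejected if for some z both
`|r_xy| <= |eps r_xz|` and `|r_xy| <= |eps r_yz|`. Note that an edge equal
to the exact product of its two flanking correlations is *kept* by this
rule — the vanishing partial also shrinks eps; rejection requires the direct
correlation to be weak relative to the indirect path. A naive O(n^3)
triple-loop is kept as the reference; the production implementation
vectorizes over the conditioning gene and is tested bit-identical to the
reference on 1000 random matrices. Off-diagonal |r| >= 1 - 1e-12 is clamped
before partials. No |r| floor is applied before the trio test.

The filtered network keeps genes that (i) are PCIT-significantly
co-associated with at least 5 (first gene set) or 50 (second gene set)
transcription + co-transcription factors and (ii) have nominal GWAS p < 0.05
for at least one trait. TF/CF nodes must themselves meet criterion (i)
(configurable, `regulators_must_qualify`). Displayed gene-gene edges
additionally satisfy |r| >= 0.80 / 0.95 by preset; the full significant edge
set is always written alongside. Negative edges keep a sign attribute.
Genes are labelled milk / cheese / both from which trait groups reach
nominal significance. QTL overlap uses closed 1-based intervals with the
same 20-kb window. Exports are GraphML (Cytoscape-ingestible) plus node and
edge TSVs; a round-trip read reproduces the graph exactly.

## The synthetic population

`simulate_genotypes` draws two haplotypes per animal from a latent Gaussian
AR(1) chain per chromosome (lag-1 correlation `ld_rho`, thresholded at each
SNP's allele frequency), giving dosages with tunable local LD;
`ld_rho = 0` gives independent markers. Allele frequencies are uniform on
the configured MAF range (default 0.05-0.5, matching the post-QC panel).
SNPs sit on 3 chromosomes at 1-kb spacing by default.

`simulate_phenotypes` applies the generative form of the mixed model.
Causal SNPs (default 200) are drawn uniformly (from the gene-linked pool
when one is supplied); per-trait effects are multivariate normal across
traits with the architecture's genetic correlation matrix, applied on the
raw dosage scale so the implied genetic covariance matches the VanRaden GRM
scaling. True breeding values and residuals are rescaled to hit the target
genetic and residual variances exactly in-sample, which removes one layer of
Monte-Carlo noise from recovery studies without touching the correlation
structure. Fixed-effect level values are drawn once per simulation
(SD = 0.2 phenotypic SD per factor by default); DIM is uniform on [5, 210].
Exactly `round(rate * n)` animals are flagged non-coagulating (131 of 1039
at the default rate) and lose all seven cheese-making traits. Residual
correlations are zero by default — the architecture specifies only the
genetic correlation matrix — and can be supplied explicitly.

The default 14-trait architecture carries the published phenotypic means and
SDs, heritabilities (0.04 for FP up to 0.37 for pH), and the published
genomic correlation matrix. That matrix, as printed, is strongly indefinite
(smallest eigenvalue -1.49); it is bent to the nearest PSD correlation by
iterated eigenvalue clipping at 1e-6 with diagonal renormalization, and the
Frobenius-norm adjustment (2.66) is recorded on the architecture object.
Bending necessarily shrinks the extreme printed entries (for example
pH-ILCY moves from -0.89 to about -0.59), so bivariate recovery studies
that target a specific *printed* correlation use a dedicated two-trait
architecture in which that value is PSD as-is.

### What the generator does not emulate

No pedigree or family structure (the study population is described as
non-structured), no dominance, epistasis or imprinting, no selection or
drift history, no genotyping error, and LD is a one-parameter local chain
rather than a realistic recombination map. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated
additive model, not robustness to real-data violations of it.

## Parameter-recovery benchmarks

`scripts/acceptance.py` re-runs four recovery studies from scratch, all at
the study scale and design (n = 1000, m = 2000, 200 causal loci): mean
univariate REML h^2 over 20 replicates simulated at the published pH
(0.3706) and A60 (0.1658) heritabilities, and mean bivariate REML genetic
correlation over 30 replicates at the published pH-ILCY (-0.89, h^2
0.3706/0.3366) and logSCC-A60 (0.83, h^2 0.0479/0.1658) values. The
low-heritability pair is the hard case: with h^2(logSCC) = 0.048 the
genetic SD sits near the REML estimation noise floor, so per-replicate
correlation estimates are intrinsically dispersed (SD ~ 0.4 across
replicates at this design), a fraction clamp at |r_g| = 1, and the
30-replicate mean is mildly attenuated toward zero. Multi-start checks
confirm these are properties of the restricted likelihood at this sample
size, not of the optimizer. The same studies run in the acceptance test
suite at the tolerances stated there.

## Numerical choices and degenerate inputs

- HWE: 1-df chi-square goodness-of-fit by default (standard at n ~ 1000);
  the Wigginton exact test is selectable. Monomorphic markers return p = 1
  and fail the MAF filter instead.
- QC thresholds are strict inequalities (MAF > 0.05, HWE p > 0.05).
- GRM requires >= 2 polymorphic SNPs; an all-monomorphic panel is an error,
  an empty QC result is a warning.
- Zero-variance t-value rows get co-association 0 and a flag; zero-variance
  GEBV columns contribute 0 to the z-score with a warning.
- All RNG flows from `numpy.random.SeedSequence` spawning; every stage's
  draws trace to one master seed and runs are bit-reproducible.

## Known limitations

- The bivariate engine handles 2 traits only; the 14x14 genetic covariance
  is never estimated jointly.
- The stepwise stage is single-machine; at the published scale
  (12,426 markers, 1000 candidates of 50) it is a cluster-sized computation,
  and the desk-scale defaults exist for exactly that reason.
- SE conventions for the published weighted-average heritability are
  ambiguous in the source; the inverse-SE convention is isolated in
  `se_weighted_h2` so it can be swapped.
- GEBV prediction for unphenotyped animals assumes the fitted variance
  components transfer to them (standard GBLUP assumption).
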