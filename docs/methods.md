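# Methods

This note documents the models, numerical choices and known limitations of
`landgen`. It is written for a reader who wants to know exactly what each
stage computes and what the synthetic benchmarks do and do not demonstrate.

## Generating model (`landgen.synthdata`)

The generator emulates a range-wide ddRAD SNP panel of an outcrossing
plant. Defaults mirror a Germany-scale study design: 735 individuals at
534 sites (1–2 per site), 8,348 biallelic SNPs, 16.6% missing genotypes,
K = 4 admixed ancestral clusters, and a rectangle of ~4° × 6° so geodesic
distances are meaningful.

* **Ancestry.** K focal points are spread over the grid; individual i's
  membership vector is softmax(−d_ik / T) over clusters k, with d the
  grid distance to focal point k and T a temperature (default 4.0 cells).
  The default T makes roughly half of all individuals "fully assigned"
  (max q > 0.9) while transition areas stay admixed, matching how strong,
  spatially coherent but admixed ancestry typically looks in range-wide
  plant panels. Ancestry is therefore spatially *continuous*: its Q matrix
  has effective rank above K, which deliberately stresses
  structure-correction methods the way real clines do.
* **Neutral loci.** Ancestral frequency p₀ ~ U(0.1, 0.9); cluster
  frequencies follow the Balding–Nichols Beta distribution with drift
  F (default 0.03). The default reproduces the differentiation envelope
  reported for widespread European grassland herbs (zone-level Φ_ST and
  Nei F_ST of roughly 0.01–0.03); larger F produces visibly stronger
  clustering than such data show.
* **Adaptive loci.** Each adaptive locus (default 20) is driven by one
  designated environmental variable: its expected allele frequency is
  logistic(logit p₀ + β·b) with b the standardized driver value at the
  individual's site and β the effect size (default 2 per SD). Two driver
  variables are used round-robin, so variable selection has exactly two
  true positives to find. No epistasis, pleiotropy or linkage is
  simulated.
* **Environment.** Each variable is a unit-variance Gaussian random field
  (smoothed white noise; length scales of 3–12 cells, climate variables
  smoother than soil variables) plus a deterministic north–south or
  west–east gradient of amplitude 1. Future grids add a per-variable shift
  (optionally with a west–east gradient); soil variables stay constant.
  Per-site values are bilinear samples; standardization statistics
  (mean, SD per variable) always come from present-period *site* values,
  so site-fitted models and grid projections share one calibration.
* **Missingness** is completely at random; the mechanism of real ddRAD
  missingness (coverage- and allele-dependent) is not emulated. Genotypes
  are diploid; tetraploids genotyped as diploids are represented only in
  that simplified form.

What passing tests on this generator show: the estimators recover the
structure the model actually contains (drift-scaled clusters, logistic
clines, known drivers). What they do not show: robustness to linkage,
allele-frequency spectra of real ddRAD pipelines, informative
missingness, or isolation-by-distance without discrete clusters.

## Locus filtering (`landgen.genio`)

Minor-allele frequency is computed over non-missing allele calls only;
the default floor is 0.05. Within a contig a single SNP is retained —
the one with the highest call rate, ties broken by lowest position — a
deterministic rule standing in for the unspecified choice most SNP-calling
pipelines make. Filtering is idempotent. VCF input is minimal (diploid GT
only; multiallelic records are rejected and counted); the canonical
interchange format is a 0/1/2 TSV. Rasters use the ESRI ASCII grid dialect
with cell-center registration and half-open cell intervals for site→cell
lookup.

## Ancestry estimation (`landgen.popstruct`)

`estimate_ancestry` maximizes the admixture binomial likelihood
x_il ~ Binomial(2, Σ_k q_ik f_kl) by EM, with missing entries excluded.
Two departures from a plain MLE matter:

* **Balding–Nichols shrinkage.** With K·L free cluster frequencies, the
  MLE at a few thousand loci drifts toward over-admixed Q (fitting noise
  in f pulls memberships off the simplex vertices; in our experiments the
  mean |Q − Q_true| *worsened* monotonically with EM iterations). Cluster
  frequencies therefore carry a Beta prior centred on the overall locus
  frequency with concentration κ = (1 − θ̂)/θ̂ — the Balding–Nichols
  relation between drift and Beta concentration — where θ̂ is the
  Weir–Cockerham differentiation of the k-means initial partition. This
  empirical-Bayes choice has no free knob, vanishes for strongly
  differentiated clusters (θ̂ large ⇒ κ ≈ 0), and stabilizes recovery
  independent of iteration count.
* **Determinism and monotonicity.** Initialization is k-means on leading
  PCs (seeded); the best of `n_restarts` fits by penalized objective is
  returned; MAP-EM makes the penalized negative log-posterior
  monotonically non-increasing (checked every 10 iterations; the EM
  algebra runs in float32 for speed, the objective is accumulated in
  float64).

K is chosen by masked-entry cross-validation: a fraction (default 10%) of
observed entries is hidden, the model fitted on the rest, and the squared
error of the predicted dosage 2·(QF) at hidden entries reported per K.
Because the shrinkage prevents extra clusters from overfitting, the CV
curve can flatten above the true K; `select_K` therefore applies the
one-standard-error parsimony rule (smallest K within one SE of the
minimum) and excludes K values that are biologically implausible — those
where some cluster contains no individual with q > 0.9. A spatial
coherence score (mean fraction of an individual's 5 nearest geographic
neighbours sharing its modal cluster) operationalizes the "geographically
contiguous" half of that plausibility judgment, which is otherwise visual.
The pipeline thins the panel to at most `cv_locus_cap` (3,000) seeded
random loci for the K scan only — the CV *ranking* of K stabilizes well
below the full panel size — and fits the final model on all loci.

Missing genotypes are imputed by the modal genotype under Binomial(2, QF).
The expected exact-recovery rate of any modal imputation is bounded by the
Bayes rate E[max pmf], about 0.61 under the generator's frequency
distribution — mid-frequency SNP panels are intrinsically hard to impute,
and the tests check proximity to that analytic ceiling rather than an
arbitrary percentage.

## Differentiation and IBD

One-level AMOVA on squared Euclidean genotype distances (locus-mean
substitution for missing values), with the unequal-group-size n₀
coefficient and permutation p-values (add-one estimator, default 999 in
the library, 199 in the pipeline defaults). Pairwise F_ST is the
Weir–Cockerham multi-locus ratio of sums; the global value is Nei-style
1 − ΣH_S/ΣH_T. Both estimators are exposed because they answer slightly
different questions and differ numerically on the same data. Geodesic
distances use the haversine formula on a sphere of radius 6371.0088 km
(< 0.5% error at sub-continental scale); the Mantel statistic is the
Pearson correlation of off-diagonal entries under joint row/column
permutations, one-sided; the IBD slope is OLS of pairwise F_ST on distance,
reported per 100 km.

## Ordination engine (`landgen.ordination`)

RDA: predictors standardized to unit SD, response columns centered but not
scaled (dosage/frequency data); fitted values by least squares; canonical
axes from the SVD of the fitted matrix. Partial RDA residualizes both
response and predictors on [1, Z]. Predictors fully absorbed by the
conditioners are dropped (a model may legitimately end up with zero
canonical axes, e.g. Z = X); remaining rank deficiency is an error naming
the aliased columns. The permutation test permutes rows of the
residualized predictors (a simple scheme, valid for these designs) and
uses the add-one p estimator. Forward selection greedily maximizes
Ezekiel-adjusted R² and stops on p > α for the candidate's marginal
(conditioned) test, an adjusted-R² decrease, or surpassing the
all-variables model's adjusted R². Variance partitioning computes pure
fractions as differences of adjusted R² (full minus leave-block-out), so
the accounting identity pure + confounded = full holds exactly; p-values
come from the corresponding partial-model permutation tests.

## GEA scans (`landgen.gea`)

All three scans return per-locus statistics, p-values, BH q-values and
hits at q < 0.05; the consensus set keeps loci flagged by at least two.

* **rdadapt-style**: Mahalanobis distance of each locus's loadings on the
  leading RDA axes (environment-constrained, structure-conditioned).
* **pcadapt-style**: per-locus regression z-scores on the leading genotype
  PCs, screened by Mahalanobis distance.
* **latent-factor model**: factors from the exact closed-form ridge
  solution of min ‖Y − W − EBᵀ‖² + λ‖B‖² (the factors absorb the
  environment-collinear component of neutral structure), then a per-locus
  joint F-test of all environmental coefficients controlling the factors.

Calibration is the load-bearing choice. Because the generator's ancestry
is spatially continuous, no fixed number of factors or PCs removes all
structure; the residual leakage gives null statistics a
noncentrality-mixture distribution whose tail a median-based genomic
inflation factor under-corrects (we measured empirical FDR up to 0.9 that
way). All scans therefore fit an *empirical null* in Efron's
central-matching spirit: a scale and an effective degrees-of-freedom are
chosen so the 50th and 95th percentiles of the statistic match a scaled
χ², both anchors sitting below the outlier range (candidate loci are ~1%
of a panel). Mahalanobis covariances are estimated robustly (minimum
covariance determinant) so outliers cannot mask themselves. With
K_latent = 0 the latent-factor scan reduces exactly to the ordinary
multivariate regression F-test and no calibration is applied.

## Offsets and z′ (`landgen.offset`)

The adaptively enriched RDA describes per-site allele frequencies of the
candidate loci with the selected environmental variables; its first two
axes (configurable) define the adaptive space. Distances weight axes by
the square root of their canonical-eigenvalue share by default (switch:
unweighted); the choice matters little when axis 1 dominates. The
reference distribution uses all unordered pairs of valid grid cells up to
a cap of 2×10⁶, beyond which pairs are subsampled with a seed.

z′ is a rank-based standardization: F̂ is the empirical CDF of the
reference with linear interpolation between order statistics and clamping
to [1/(n+1), n/(n+1)]; z′(x) = Φ⁻¹((1 + F̂(x))/2). This half-normal
quantile map makes z′ = 1 fall at the 68.27th reference percentile and
z′ = 2 at the 95.45th by construction, for *any* continuous reference —
which is the Empirical-Rule behaviour the standardization is meant to
have — while deliberately abandoning any interpretation in reference
standard deviations. The invariance of z′ under monotone rescaling of the
offset scale is exact at reference sample points and accurate to the
interpolation error between them. Degenerate references (fewer than two
distinct values) are an error, not a silent zero.

Donor suitability standardizes the donor-present-vs-recipient-future
offset with the *same* contemporary reference; evaluated at the recipient
cell it equals that cell's temporal offset by construction.

## Pipeline defaults and problem sizes

The pipeline's default simulation runs the full study-scale problem
(735 × 8,348). Test-suite and acceptance checks run the generator at
reduced sizes chosen to keep the whole suite in a few minutes of one CPU:
2,000 loci × 400 individuals for recovery and GEA power/FDR experiments
(power and FDR are reported as means over four generator replicates, since
a single replicate with 20 adaptive loci measures FDR at a granularity of
~0.05), 200 permutation replicates for type-I checks, and ≤ 10×10
fixtures for the brute-force oracle comparisons. Permutation defaults are
999 in library functions and 199 in pipeline configuration.

## Known limitations

* The ancestry model is a stand-in for full model-based clustering
  software: same interface and likelihood family, but no supervised mode,
  no bootstrap SEs, and the BN shrinkage (however principled) is our
  choice, not a community standard.
* Gradient-Forest-based offsets are not implemented; the consensus rule
  operates over the three implemented scans.
* Offsets assume linearity of the adaptive index in standardized
  environmental values and a single climate scenario per run; uncertainty
  across scenarios or genotype-environment model error is not propagated.
* ESRI ASCII is the only raster dialect; coordinates are WGS84 lon/lat
  with no projection support.
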