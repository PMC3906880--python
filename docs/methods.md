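# Methods

## Model

A dataset holds G genes measured on N observation columns, each column a
`(condition, replicate, time)` triple; values are log ratios.  Gene `g`
belongs to a latent cluster `u_g ∈ {1..K}` with proportions π.  Given its
cluster, the gene's observed vector (masked entries deleted) is Gaussian:

    y_g | u_g = k ~ N( X_g β_k , V_gk ),   V_gk = Z_g D_k Z_gᵀ + σ²_k I.

The general clustering-of-regression-models idea only fixes the mean
structure E[y|X, u=k] = μ(X; β_k) and leaves the error law to the chosen
regression family; this package commits to the linear-mixed (Gaussian)
completion above, which is the standard choice for longitudinal designs
and makes every EM update closed-form.

* **Fixed design `X_g`** — a B-spline basis in time evaluated at the
  gene's observed rows.  Defaults: cubic, 7 interior knots equally spaced
  on the open time range, boundary knots at the range ends with full
  multiplicity, giving 11 columns; clustering results in this family are
  known to be insensitive to the knot count within a reasonable range.
  With `condition_blocking`, each condition receives its own coefficient
  block (p = 11 × number of conditions), so conditions have free,
  separately estimated mean curves.  The basis is a partition of unity and
  spans constants; coefficients are reported on the raw B-spline scale and
  `fitted_cluster_profile` renders interpretable curves.
* **Random design `Z_g`** — how a gene deviates from its cluster curve.
  Default `per-condition-intercept`: one random intercept per condition
  (q = number of conditions), shared by all the gene's observations in
  that condition — in particular by both technical replicates, which is
  the minimal hierarchical treatment of replication.  `basis-subset` puts
  random coefficients on the first q basis columns instead, allowing
  smooth gene-level curve deviations.  `none` gives q = 0: the mixture of
  ordinary linear models.  Which structure the original longitudinal
  applications used is not documented; both are provided and the default
  is the simpler one.

Missing values are carried by an explicit mask and enter the likelihood by
row deletion, which is valid when data are missing at random.  No
imputation happens inside EM; the only imputation in the package
(gene-mean fill) is used to build starting values and never touches the
likelihood.  Outlier cells are supplied by the user as a mask list — an
automatic signal-strength outlier rule is deliberately not provided.

## EM algorithm

Memberships `u_g` and random effects `b_g` are both treated as missing
data.  The E-step computes, per gene and cluster,

    p_gk ∝ π_k f_k(y_g)            (log-sum-exp normalized)
    b̂_gk = D_k Z_gᵀ V_gk⁻¹ (y_g − X_g β_k)
    C_gk = D_k − D_k Z_gᵀ V_gk⁻¹ Z_g D_k

and the M-step the closed-form updates

    π_k  = (1/G) Σ_g p_gk                         (unless fixed at 1/K)
    β_k  = (Σ_g p_gk X_gᵀX_g)⁻¹ Σ_g p_gk X_gᵀ(y_g − Z_g b̂_gk)
    D_k  = Σ_g p_gk (b̂_gk b̂_gkᵀ + C_gk) / Σ_g p_gk
    σ²_k = Σ_g p_gk [ ‖y_g − X_gβ_k − Z_g b̂_gk‖² + tr(Z_g C_gk Z_gᵀ) ] / Σ_g p_gk n_g

(β_k, then D_k and σ²_k given the new β_k, is an exact joint maximization
of the expected complete-data log-likelihood, so the observed-data
log-likelihood is non-decreasing; the test suite enforces a 1e-8 slack.)
An ECM variant with a GLS β-update was considered and rejected: the
closed-form updates are guaranteed-ascent and equally cheap.

**Numerics.**  All per-gene quantities reduce to cross products
(yᵀy, Xᵀy, XᵀX, Zᵀy, ZᵀX, ZᵀZ) computed once; the EM loop never touches
n-length vectors.  V_gk is never formed: with A = (σ²I + D ZᵀZ)⁻¹D (a q×q
solve, q ≤ number of conditions in practice), b̂ = A Zᵀr, the quadratic
form is rᵀr − (Zᵀr)ᵀb̂, and log det V = (n−q)log σ² + log det(σ²I + D ZᵀZ).
Floors and projections: σ²_k ≥ 1e-8; D_k is projected to PSD by clipping
negative eigenvalues at zero (the update is PSD in exact arithmetic).
MAP and nearest-center ties resolve to the lowest index everywhere.

**Initialization and restarts.**  Lloyd's K-means on replicate-averaged
per-gene profiles (gene-mean imputation, init only) gives base labels;
restart r > 0 reassigns a random 10% of genes.  Starting parameters come
from the hard labels by pooled per-cluster least squares (β, σ²) and a
method-of-moments estimate of D from per-gene least-squares random-effect
estimates, inflated by 0.1σ²I so EM can move off the boundary.  Default
10 restarts; best final objective wins, ties to the lowest restart index.
Convergence: relative log-likelihood change < 1e-6 (soft) or label
stability (hard), max 500 iterations.

**Degenerate clusters.**  If a cluster's posterior mass falls below one
gene, the worst-fitting gene (lowest per-gene log-likelihood) is moved
into it; if this recurs more than three times in a restart, the restart is
abandoned.  If every restart degenerates the fit fails with a clear error.

**Classification EM and the K-means identity.**  `hard_assign` collapses
posteriors to MAP indicators before each M-step and traces the
classification log-likelihood (the monotone objective of that variant).
Constraining the model to a saturated design, q = 0, shared σ², π = 1/K
and hard assignment makes the E-step a nearest-center assignment and the
M-step a center recomputation — Lloyd's algorithm.  The package's own
Lloyd implementation mirrors the mixture arithmetic (expanded-form squared
distances, lowest-index ties, and the same reseed-the-farthest-point rule
for empty clusters) precisely so that this identity holds exactly, label
for label, under matched initialization; it is asserted over dozens of
random datasets in the tests.

## Prediction, diagnostics, comparison

* `predict_new_gene` applies the E-step arithmetic to a new gene under
  frozen parameters — valid for partial profiles, no refitting.
* `residuals` returns y_g − X_gβ_{û_g} − Z_g b̂_g per gene and a
  per-cluster variance-by-time table (one row per cluster per distinct
  time, pooled over conditions and replicates); `blup_summary` gives BLUP
  variances per cluster and random-effect element.  Flat variance across
  time and structureless residuals are the expected picture when the
  model fits.
* `pca_scores` eigen-decomposes the column-centered profile covariance
  (centering is a flag, on by default; the convention is documented
  because display conventions vary) and projects genes and cluster means
  on the top two eigenvectors, reporting the variance fraction explained.
* `relabel_by_peak` renumbers clusters by the first interior local
  maximum of their fitted curves (global maximum as fallback, earliest
  time on ties) so cluster numbering follows biological phase order.
* `cross_tab` compares two labelings; its agreement score is the diagonal
  fraction after a maximum-weight one-to-one matching of cluster names
  (scipy's assignment solver).  This is a documented operationalization —
  published "percent agreement" numbers for such tables rarely state
  their matching rule, so no specific published percentage is claimed.
  The two bundled 256-gene reference tables are transcriptions of
  published comparisons for the yeast cell-cycle benchmark and are used
  as fixtures for the summarizer.
* `select_informative_genes` runs a per-gene OLS F-test (spline design vs
  intercept, replicates as independent residual rows) with
  Benjamini–Hochberg adjustment; the FDR procedure is fixed to BH as the
  standard choice.

## Synthetic data

The generators define the study conditions the tests run under.

* **Replicated time course** (`simulate_lwr_timecourse`): defaults are
  300 genes in 3 equal clusters; sinusoidal templates with amplitude 1
  (log-ratio scale), period 60 min (two cycles over the 0–120 min grid —
  a realistic cell-cycle period for synchronized yeast), phases evenly
  spaced over one period (0/20/40 min at K = 3); conditions WT and SM
  with amplitude multipliers 1.0 and 0.6 (the mutant damps but keeps
  periodicity); 2 technical replicates; 5-min sampling; bad time points
  WT {105} and SM {25, 40, 55} dropped; per-condition random intercepts
  with sd 0.3; residual variance 0.0625; 5% of cells missing at random.
  Values the underlying study design does not fix (period, phases,
  amplitudes, variances) were chosen once as realistic for log-ratio
  cell-cycle data and are not tuned.
* **Cross-sectional benchmark** (`simulate_clm_figure1`): 8 genes in two
  clusters of four, a 10-level covariate with 10 samples per level
  (N = 100), cluster slopes ±0.5 per level, gene offsets sd 0.2, noise
  sd 0.5 — documented constants giving separation well above noise.

What the generators do *not* emulate: array-level artifacts (dye bias,
spatial effects, background), informative missingness, heavy-tailed or
heteroscedastic noise, non-periodic transient responses, and correlation
between genes beyond shared cluster membership.  Passing tests therefore
demonstrate correctness of the estimation machinery under the assumed
model, not robustness to these real-data violations.

## Problem sizes and checks in the test suite

The suite and the acceptance script use desk-scale problems chosen to
exercise every code path: the 100-seed cross-sectional recovery study, 50
random datasets for the exact K-means identity, and one study-scale
replicated simulation (G = 300, K = 3, ~87 observed entries per gene after
bad-point removal and 5% MAR).  For that simulation the mean-curve
tolerance is 3 Monte-Carlo standard errors per grid point, with
SE = sqrt((d² + σ²/R)/G_k) — the standard error of a naive cluster-mean
estimate implied by the generator's variance components; the spline
estimator is more efficient, so this is a conservative band, though as a
pointwise bound evaluated at ~560 grid points its extreme order statistic
can brush the boundary.  Residual variances must land within 15% of truth
and MAP misclassification below 5% after best-matching cluster names.

## Known limitations

* Maximum-likelihood (not REML) variance components: σ² and D are biased
  low by the fixed-effect degrees of freedom, negligible at n_g ≈ 90 but
  visible on short profiles.
* The EM objective is multimodal; restarts mitigate but do not guarantee
  the global optimum.  Determinism is per seed.
* K is reported (log-likelihood, BIC, cluster sizes per K), never chosen
  automatically: with few replicates, resampling-based choices of K are
  unreliable, and the intended workflow is inspection across a small K
  range.
* No GO/annotation enrichment, no formal inference for genes whose
  cluster changes between condition sets (the cross-tab comparison is
  descriptive), and no nonlinear or nonparametric cluster models beyond
  the spline-coded linear family.
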