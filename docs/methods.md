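# Methods

## Model

`denialmap` estimates tract-level relative risk of mortgage denial within
each metropolitan statistical area (MSA) with a Besag–York–Mollié (BYM)
binomial-logit hierarchical model. Each loan application *i* in tract *j*
is a Bernoulli trial:

    y_ij ~ Bernoulli(θ_ij),    logit(θ_ij) = α + H_ij β + u_j + v_j

The binomial statement of the likelihood with loan-level covariates is
implemented as one Bernoulli term per application, since the covariate row
H_ij (applicant-sex indicator, loan-to-income ratio) varies by loan;
aggregating identical (tract, covariate) cells to binomial counts would be
the same likelihood.

The tract residual decomposes into a spatially structured effect u and an
exchangeable effect v:

* **u** carries an intrinsic conditional autoregressive (ICAR) prior:
  conditionally, u_g | u_{-g} ~ N(mean of neighbors, σ²_u / d_g) where d_g
  is the neighbor count; jointly, the density is proportional to
  exp(−(1/2σ²_u) Σ_{g~j} (u_g − u_j)²), a degenerate Gaussian whose
  precision is the graph Laplacian divided by σ²_u.
* **v_j ~ N(0, σ²_v)** absorbs unstructured tract heterogeneity.

Neighbors are defined by queen contiguity — w_gj = 1 iff the tract
polygons share at least one boundary point — with binary (not
row-standardized) weights.

The ICAR prior is improper (its null space is spanned by per-component
constants). Identifiability is restored by constraining u to sum to zero
within each connected component of the adjacency graph, so α carries the
MSA-wide level. A tract with no neighbors is its own component, and the
constraint pins its u to zero; only v operates there. Tracts present in
the graph but without eligible loans contribute no likelihood and are
smoothed purely by their neighbors (prediction-only nodes).

β is global within an MSA (one coefficient per covariate, shared across
tracts): a per-tract coefficient under a single diffuse prior would be
unidentifiable alongside the tract effects. Covariates enter
unstandardized, matching the stated prior scale; an optional
standardization can be emulated by rescaling `beta_prior_var`.

### Priors and defaults

| parameter | prior | default | notes |
|---|---|---|---|
| β (each) | N(0, c) | c = 1000 | diffuse; `beta_prior_var` |
| α | flat (improper) | — | configurable to N(m, s²); flat is proper a posteriori once any loan is observed |
| 1/σ²_u | Gamma(shape, rate) | Gamma(1, 0.0005) | long-tailed, weakly informative; `tau_u_*` |
| 1/σ²_v | Gamma(shape, rate) | Gamma(1, 0.0005) | `tau_v_*` |

Sampler defaults: 4 chains, 5,000 iterations, 2,500 burn-in, no thinning,
mandatory seed. All are configurable; the test-suite and demo runs use
shorter chains because the posteriors involved are low-dimensional and
fast-mixing (bulk effective sample sizes per 100 kept draws are high for a
conjugate blocked Gibbs sampler — diagnostics are attached to every fit).

## Inference engine

The posterior is sampled with a Gibbs sampler built on Pólya-Gamma (PG)
data augmentation. Conditional on ω_i ~ PG(1, η_i), the Bernoulli-logit
likelihood is Gaussian in the linear predictor η, so each sweep is:

1. ω_i | η_i ~ PG(1, η_i) for every loan.
2. (α, β, u, v) as **one joint Gaussian block**. u is parameterized as
   u = Bw, where B's columns are the Laplacian eigenvectors with positive
   eigenvalue — an orthonormal basis of the per-component sum-to-zero
   subspace — so the constraint holds by construction (and is still
   asserted numerically, tolerance 1e-8, every sweep) and the ICAR prior
   precision is diagonal (τ_u λ_k) in that basis. Drawing the whole linear
   predictor jointly, rather than u | v and v | u in turn, matters because
   only u + v is strongly identified by the data: alternating updates of
   two effects competing for the same tract signal mix slowly. All blocks
   of the joint precision reduce to per-tract sufficient statistics of ω
   and κ = y − ½, so assembly is cheap.
3. Precisions 1/σ²_u, 1/σ²_v from their conjugate Gamma conditionals; the
   ICAR term contributes rank(L)/2 = (J − #components)/2 to the shape and
   the pairwise-difference energy uᵀLu/2 to the rate.
4. An ancillarity-sufficiency interweaving (ASIS) rescale of each variance
   component: re-express the field in its non-centered parameterization
   (ũ = u/σ_u, fixed), then redraw σ_u from its conditional there — given
   the ω's the log-density in s = σ_u is a·s − b·s²/2 plus the transformed
   Gamma prior, sampled exactly by 1-D slice sampling in log s (and the
   same for σ_v). Without this move the posterior's funnel geometry
   between each scale and its field's magnitude leaves the σ² chains with
   effective sample sizes in the single digits on spatially strong data;
   with it they mix two orders of magnitude faster, at ~25% extra cost
   per sweep.

PG(1, z) variates are drawn from the representation as an infinite
convolution of exponentials, truncated at 128 terms with the mean of the
discarded tail added back deterministically. The draw's mean is therefore
exact (tanh(z/2)/(2z)) and the neglected tail variance is O(K⁻³) ≈ 5e-7 —
negligible against the likelihood's own scale. This choice keeps the
sampler fully vectorized over loans.

With zero loans the sampler returns prior draws (requiring a proper α
prior), which the suite uses to verify prior recovery.

The u-block uses dense Cholesky factorizations, appropriate for the tract
counts per MSA this package targets (tens to a few thousand); for much
larger graphs a sparse factorization would be the natural upgrade.

### Why MCMC

A popular computational route for BYM models is the integrated nested
Laplace approximation. This package instead implements an exact-target
MCMC sampler: the posterior being approximated is identical, the conjugate
PG construction requires no tuning, and correctness can be validated
internally — against a dense-grid quadrature oracle on small instances and
by simulation-based calibration — without reference to any external
implementation.

## Moran screening

Before modeling, each MSA's crude tract denial proportions Y_j/n_j are
screened for spatial autocorrelation with Global Moran's I on the binary
queen weights:

    I = (n/S0) · Σ_g Σ_j w_gj (x_g − x̄)(x_j − x̄) / Σ_g (x_g − x̄)²

The input surface is a configurable choice (`moran_variable`); crude rates
are the natural pre-model screen and the default. Inference is by random
relabeling: 999 permutations by default, two-sided around the permutation
mean, α = 0.05, seeded. Tracts with zero eligible loans are excluded from
the statistic; isolated (degree-0) nodes are dropped with a warning.
Constant surfaces and n < 3 are errors, since I is undefined.

## Synthetic data generator

The generator draws from exactly the model above, on planar lattices of
unit-square tracts (one grid per MSA, spatially separated so no cross-MSA
contiguities arise): u from the ICAR distribution via the spectral
decomposition of the Laplacian (independent N(0, σ²_u/λ_k) weights on
non-null eigenvectors — hence exactly sum-to-zero per component, with
covariance σ²_u L⁺), v i.i.d. normal, sex ~ Bernoulli(p_female),
loan-to-income ratio log-normal, and denial through the logit link. Loans
are written in the public 2010–2014 LAR CSV schema so synthetic data
exercise the real reader; the truth table (per-tract u, v) is a separate
file the pipeline never reads.

Default regime: baseline denial α = logit(0.103) — denial is rare, about
one application in ten — with β_sex = 0.25, β_lti = 0.10, σ²_u = 0.25,
σ²_v = 0.05, p_female = 0.30, and log-normal loan-to-income with median
≈ 2.0 (location 0.7, scale 0.4). The covariate effect sizes and the LTI
distribution are configurable defaults chosen as plausible magnitudes for
loan-level underwriting covariates, not calibrated estimates; the empirical
LTI distribution in real LAR data is heavier-tailed and correlated with
income in ways the generator does not emulate. Randomness uses one root
seed with per-MSA substreams keyed by MSA id, so adding an MSA never
perturbs the others.

What passing tests on synthetic data do show: the filters, the adjacency
builder, the Moran statistic, the sampler and the RR summaries are correct
for data that follow the model. What they do not show: robustness to
model misspecification in real HMDA data (unmodeled lender effects,
covariate measurement error, informative missingness, irregular tract
geometries with slivers or water gaps).

## Validation design

* **Oracle equivalence (Moran).** The sparse-matrix statistic must equal a
  brute-force O(n²) double loop to 1e-12 on random graphs; the 2×2
  checkerboard value −1/3 is exact.
* **Oracle equivalence (posterior).** With tract effects disabled, the
  model is a three-parameter logistic regression; on a 3-tract, 60-loan
  instance the Gibbs posterior means of (α, β) must agree with dense-grid
  quadrature (81³ grid spanning ±6 SE around the MLE) within 0.05.
* **ICAR correctness.** Monte-Carlo draws are checked against the
  closed-form constrained Gaussian: on two nodes u₁ ~ N(0, σ²/4); on
  larger graphs the sample covariance matches σ²L⁺ and E[uᵀLu] = σ²·rank(L).
* **Simulation-based calibration.** 200 replicates of
  draw-parameters-from-prior → simulate → fit → rank-of-truth, on one
  5×5-tract MSA with 30 loans per tract; ranks of α, β_sex, β_lti, σ²_u,
  σ²_v among 25 thinned draws must pass a chi-square uniformity test at
  p > 0.01. SBC requires proper generator priors, so this study uses the
  spec-configurable narrow settings (α ~ N(logit 0.103, 1), β variance
  0.25, Gamma(2, 1) precisions) for both generator and model.
* **Frequentist coverage.** 200 simulate-then-fit replicates at fixed
  truth (4×4 tracts, 30 loans/tract): 95% CrIs for α and both β must cover
  in 89–99% of replicates. Tract-risk ranking: Spearman correlation of
  true vs estimated RR above 0.8 at σ²_u = 0.5 with 100 loans per tract.

Replicate counts follow the validation design; the per-replicate problem
sizes (grids of 16–25 tracts, 30 loans per tract) are the package's own
choice of the smallest instances at which all five parameters remain
comfortably identified, keeping the full suite convenient to run routinely.

## Numerical choices and edge cases

* Income ≤ 0 or missing ⇒ record dropped (loan-to-income undefined); the
  complete-case set is {tract, MSA, sex, income, amount}. Sex codes
  "not provided"/"not applicable" are dropped; female is coded 1.
* Filter order: eligibility → outcome classification → exclusion of
  withdrawn/incomplete → complete-case. Order affects only the audit
  report's attribution, not the final record set; every drop is counted
  and drops + retained always equals rows read.
* Unknown action-taken codes classify as excluded and are counted as
  warnings, never silently dropped. Unparseable action codes are
  quarantined as malformed.
* MSA assignment is taken from the record's MSA field as published; no
  re-derivation from county codes, avoiding delineation-vintage ambiguity.
* Loan rows are canonically sorted (tract, covariates, outcome) before
  sampling, so posterior draws are byte-identical under input-row
  permutation.
* Equal-tailed 95% intervals (2.5/97.5 percentiles) on the exponentiated
  scale, not highest-posterior-density.
* "Precision" of a tract estimate is summarized as the width of the 95%
  credible interval of RR (posterior SD available as an option).
* Elevated/decreased classification defaults to the point rule
  (posterior mean vs 1, ties → "null"); an interval rule (95% bound clear
  of 1) is available and recorded in every output row.
* Moran p-values are (1 + #{|I_perm − mean| ≥ |I_obs − mean|}) / (R + 1),
  so with R = 999 they live on the grid {1/1000, …, 1}.
* All pipeline outputs are written atomically (temp file + rename);
  a failing MSA is quarantined in the manifest while others proceed.

## Limitations

* The ICAR/BYM formulation does not separate the scale of u and v in a
  directly interpretable way (the BYM2 reparameterization would); variance
  comparisons between the two components should be made cautiously.
* Dense linear algebra in the u-block caps comfortable MSA sizes at a few
  thousand tracts per MSA.
* The pipeline models denial vs approval only; withdrawn and incomplete
  applications are excluded, so the estimand is conditional on a completed
  determination.
* No lender random effects, no race/ethnicity covariates, no temporal
  structure: the residual u + v absorbs everything tract-correlated that
  the two loan-level covariates do not explain, and the relative ratio is
  a descriptive, not causal, quantity.
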