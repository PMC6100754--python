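# Methods

## The problem

Clinical evidence on ketogenic therapy — ketogenic diets (KD) and
calorie restriction (CR), alone or combined with another treatment
(KD+, CR+) — in high-grade glioma is sparse: three small non-randomised
patient cohorts. Preclinical evidence is comparatively rich: seventeen
survival experiments in four rodent models. `ketosynth` combines both
levels in a Bayesian hierarchical model so that animal evidence, prior
mechanistic reasoning and published case-report experience can all bear
on the clinical question: by how much does ketogenic therapy prolong
patient survival?

## Effect scale

Each study contributes a restricted mean survival time (RMST) per arm:

    RMST(t*) = E[min(T, t*)] = ∫₀^{t*} S(t) dt,

the area under the Kaplan–Meier curve up to a horizon t*, taken per arm
as the last recorded time of that arm. With no censoring and the
horizon at the largest observation this is exactly the sample mean
survival. The treatment effect is the RMST ratio MR = RMST_T / RMST_C,
log-transformed so that ln(MR) > 0 favours treatment. Unlike a hazard
ratio, the MR needs no proportional-hazards assumption — survival
curves in these studies frequently cross or plateau — and it is
unit-free, so day-scale animal studies and month-scale human studies
are directly comparable.

Standard errors: the RMST variance is the Greenwood-type expression
Σ_i A_i² d_i / (n_i (n_i − d_i)) with A_i the area under S from event
time t_i to the horizon (terms with n_i = d_i skipped); ratio SEs
follow from the first-order delta method,
se²_ln(MR) = (se_T/RMST_T)² + (se_C/RMST_C)². Both are cross-checked in
the test suite against the R `survival` package (to 1e-10) and against
a nonparametric bootstrap. Ties of events and censorings at one time
are resolved events first, the standard convention.

## The hierarchical model

The model input is a 5 × 4 grid (species: humans, athymic mice, C57BL
mice, SCID mice, Fisher rats; interventions: KD, KD+, CR, CR+) of
ln(MR) estimates y_ij with known standard deviations c_ij; 12 cells are
observed, 8 are empty. The model:

    y_ij     ~ N(θ_ij, c_ij²)            observed cells
    θ_ij     ~ N(α_i + γ_j, σ²)          all 20 cells
    α        ~ N(μ_α, R_α)               species effects (5-vector)
    γ        ~ N(μ_γ, R_γ)               intervention effects (4-vector)
    σ        ~ N(0.5, 0.01) truncated to σ > 0.

The additive structure α_i + γ_j encodes *equal relative potency*: the
ratio between two interventions' effects is the same in every species,
up to a lognormal deviation of scale σ. The σ prior (mean 0.5, variance
0.01 — scalar normals are mean/variance throughout) says this
assumption is expected to hold within a factor exp(0.4)–exp(0.6) with
68% probability. Cells with several studies are first pooled by a
normal–normal random-effects meta-analysis (see below); cells with no
study are pure predictions.

Where a grid cell is empty the model still yields an estimate: the
human CR cell, for which no patient study exists, is informed by the
animal CR studies through γ_CR and by the human KD/KD+/CR+ studies
through α_humans.

## What the reported summaries mean

Reported "MR for humans" summaries are posteriors of
exp(α_humans + γ_j): the model's estimate of the true human effect of
intervention j under equal relative potency. Two alternatives are
exposed by `summarize(..., level=...)`: the posterior-predictive
replication exp(α_i + γ_j + σε) (wider — it includes the
potency-deviation noise a new study-level effect would carry) and the
latent exp(θ_ij) (narrow for well-measured cells — it is pinned to that
cell's datum). The species-level quantity is the default because it is
the scale on which the published analysis that this package reproduces
reports its results, and the one whose tail probability
P(MR > 1) answers the clinical question.

## Prior catalogue

Eleven named (μ_α, R_α, μ_γ, R_γ) configurations span the belief
spectrum; all share the σ prior above.

| name | species side | intervention side |
|---|---|---|
| SP1 | N(0, 10 I) | N(0, 10 I) |
| SP2 | N(0, I) | N(0, I) |
| FSP | N(−0.35, I) | N(−0.35, I) |
| RP1 | mouse strains corr 0.9995, var 10 | KD↔CR, KD+↔CR+ corr 0.9, var 10 |
| RP2 | RP1 + mouse↔rat corr 0.9 | as RP1 |
| RP3 | RP2 + human↔animal corr 0.3 | as RP1 |
| MP1 | N(0, I) | means (0, .3, 0, .3), diag(1, 1.3, 1, 1.3) |
| MP2 | N(0, I) | MP1 + covs 0.99 (KD,CR), 1.287 (KD+,CR+) |
| EP | humans N(.336, .378²), mice N(.117, .08²) cov .0063, rats N(0,1) | N(0, I) |
| EP_MP1 | EP side | MP1 side |
| EP_MP2 | EP side | MP2 side |

Notes on reconstruction choices:

* MP1/MP2 encode a synergy term η ~ N(0.3, 0.3): γ₂ = γ₁ + η and
  γ₄ = γ₃ + η on top of unit-variance monotherapy effects, giving the
  diagonal (1, 1.3, 1, 1.3) and, with the KD↔CR correlation of MP2, the
  off-diagonal 1.287.
* Where a combination leaves one side unstated (the species side of MP,
  the intervention side of EP), a weakly informative N(0, I) is used.
* The enthusiastic human constants come from case-report grading: an
  expected 40% prolongation (mean ln 1.4 = 0.336) with 42.9%
  probability of an MR in [1.1, 2], hence SD
  [ln 2 − ln 1.1]/(2·0.79) = 0.378; the mouse constants
  (ln 1.124 = 0.117, SD 0.080) translate a mouse-survival
  meta-analysis. The published derivation of the mouse SD contains an
  arithmetic slip; the operative value is the printed 0.080, which is
  what the covariance matrix squares.
* The negative-σ mass of the normal σ prior is truncated at 0; σ enters
  the model only through σ², and the truncation leaves the stated 68%
  band untouched.

All matrices are validated symmetric positive semidefinite (minimum
eigenvalue ≥ −1e-10) at construction.

## Random-effects pooling

For grid cells backed by k > 1 studies, the cell estimate is the
posterior mean ± SD of μ in y_s ~ N(μ, sd_s² + τ²) with a flat prior on
μ and a choice of τ prior: uniform U(0, 5·max sd), half-normal
HN(max sd), or DuMouchel p(τ) = s₀/(s₀+τ)², s₀² the harmonic mean of
the sd_s², truncated at its 99% quantile (99 s₀). The truncation is
part of the model: with a flat μ prior the un-truncated DuMouchel
posterior SD of μ diverges (logarithmically at k = 2). Inference is
deterministic: given τ the μ posterior is an explicit normal with a
closed-form marginal likelihood, and τ is integrated by the trapezoid
rule on a 2001-point grid — uniform in the prior CDF for DuMouchel so
that both the likelihood's sharp region near τ = 0 and the heavy tail
are resolved. No Monte Carlo anywhere; verified against an independent
adaptive-quadrature oracle to 1e-4. The
packaged grid ships the published cell values verbatim rather than
re-pooled ones: the original analysis does not state which τ prior
produced them, and its single-study animal cells carry SDs about half
the delta-method value, so exact reproduction of the pooled animal
cells is not attainable from the study table alone. Pooling is used for
sensitivity reruns and new data.

## Posterior computation

A partially collapsed Metropolis-within-Gibbs sampler:

1. (α, γ) | σ, y — conditional on σ the latent θ integrates out,
   leaving the linear-Gaussian regression y_ij = α_i + γ_j + ε_ij with
   Var ε = c² + σ², so the nine effects are drawn jointly from their
   exact multivariate-normal conditional.
2. σ | α, γ, y — random-walk Metropolis on log σ against the truncated
   normal prior times the θ-marginalised likelihood. The proposal scale
   is adapted every 200 burn-in iterations toward a 20–50% acceptance
   rate, then frozen (acceptance typically ≈ 0.32).
3. θ | α, γ, σ, y — exact conjugate draw for observed cells,
   posterior-predictive draw N(α_i + γ_j, σ²) for empty ones; θ is
   never conditioned on, so it is refreshed only at retained
   iterations.

Collapsing θ out of steps 1–2 was chosen over the plain sequential
scheme (θ, then α, then γ, then σ) because the sequential sampler's
random walk between θ and the effects left visible autocorrelation:
at the default schedule its seed-to-seed wobble on the widest cell's
median reached 0.023, while the collapsed sampler's stays near 0.01.
Correctness is tested two ways: against closed-form multivariate-normal
posteriors with σ fixed, and against an exact quadrature oracle (θ
marginalised analytically, σ integrated on a grid) on the real data.

Chain schedule (the published run's settings, kept as defaults):
100,000 burn-in iterations, 200,000 sampling iterations, thinning 20 —
10,000 retained draws. A `fast` profile (10,000 / 40,000 / 4, same
10,000 retained draws) gives near-identical summaries in a tenth of
the time and is used where many fits are needed; a `toy` profile
(1,000 / 4,000 / 2) drives the simulation studies. Initialisation:
α, γ at their prior means, σ = 0.5. All randomness flows from a single
integer seed; equal seeds give bit-identical output.

No sum-to-zero constraint is imposed on α and γ: their split is
regularised only by the priors, and every reported quantity is a
function of sums α_i + γ_j, θ, or σ, which are identified.

## Model comparison

The deviance is the data-node quantity
D(θ) = −2 Σ_observed ln N(y_ij | θ_ij, c_ij²); DIC = D̄ + p_D with
p_D = D̄ − D(θ̄), θ̄ the posterior mean of θ. DIC differences act as a
quasi-evidence proxy via the threshold exp(p_D1 − p_D2) on the plug-in
likelihood ratio. A second summary is the differential entropy
0.5 ln(2πe σ̄²) at the posterior median of σ² (median of σ² and squared
median of σ coincide — squaring is monotone on σ > 0). On the packaged
grid the enthusiastic-plus-mechanistic prior EP_MP2 attains both the
smallest DIC and the smallest entropy, and no two priors differ by more
than 2 DIC units.

## Synthetic data

`simulate_arm` draws per-subject event times (exponential by default —
one parameter and a closed-form RMST (1 − e^{−λt*})/λ; Weibull
available to exercise non-proportional hazards) with independent
exponential censoring, a statistical stand-in for the administrative
and adherence censoring of the real studies. `simulate_table` draws
whole evidence grids from the hierarchical model itself with known
(α, γ, σ) and the real missingness pattern available as `PAPER_MASK`.
`recovery_experiment` runs repeated simulate-and-fit cycles and reports
per-cell credible-interval coverage and bias; with a well-specified
prior, 95% intervals cover at close to nominal rate (the suite checks
[0.90, 0.99] over 200 replicates).

What the generators do not emulate: tumour-model biology, correlated
censoring, publication bias, or any systematic bias in the source
studies — passing recovery tests shows the inference machinery is
correct for data generated by the assumed model, not that the model is
right for the real studies.

## Numerical choices and edge cases

* Survival arms must contain at least one event; fully censored arms
  are rejected. Times must be positive; the RMST horizon must be
  positive and defaults to the arm's last recorded time.
* Evidence grids with zero observed cells are fitted (with a warning):
  the posterior is the prior, which is also a test oracle.
* `sigma_fixed` pins σ for exactness tests; `sigma_fixed=0` collapses
  θ to α + γ.
* Covariance matrices are accepted down to a minimum eigenvalue of
  −1e-10 to tolerate rounding in the printed matrices.
* Pooling integrates τ over the uniform prior's own support, six
  half-normal scales, or the DuMouchel prior's 99% quantile; μ needs no
  grid (its conditional moments are closed-form).

## Known limitations

* The printed posterior table this package reproduces is matched
  closely but not entirely: the CR+ column under the plain skeptical
  and fundamentalist-skeptical priors, and a few upper interval
  endpoints, differ from two independent exact computations of the
  stated model (the printed SP2 intervals are also narrower than the
  printed FSP intervals, which the stated model — in which the two
  priors differ only in their means — cannot produce). The package
  reports what the model implies.
* Single-study animal-cell SDs in the packaged grid are the published
  values, which are not reproducible from the published per-arm RMSTs
  by the delta method; the grid is therefore shipped verbatim and
  checksummed rather than recomputed.
* DIC at short chain lengths is noisy; comparisons use the default
  schedule where the <2-unit bound matters.
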