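# ketosynth

Bayesian cross-species evidence synthesis of survival benefit from
ketogenic therapy — ketogenic diets (KD) and calorie restriction (CR),
alone or combined with another treatment (KD+, CR+) — in high-grade
glioma.

Only three small, non-randomised patient cohorts have measured survival
under ketogenic therapy in glioma, but seventeen animal survival
experiments exist across four rodent tumour models. This package
implements a hierarchical model that lets the animal evidence, prior
mechanistic reasoning, and published case-report experience all inform
the human effect estimate. It is written for biostatisticians and
meta-analysts interested in cross-species extrapolation and in
prior-sensitivity analysis with structured (covariance-matrix) priors.

## The model

Every study arm is summarised by its restricted mean survival time,
RMST(t\*) = ∫₀^{t\*} S(t) dt (the area under the Kaplan–Meier curve up
to the last recorded time), and every study by the log RMST ratio
ln(MR) of treatment to control, with delta-method standard errors —
no proportional-hazards assumption. The study estimates fill a
5 species × 4 intervention grid (12 observed cells, 8 empty), modelled
as

```
y_ij ~ N(θ_ij, c_ij²),   θ_ij ~ N(α_i + γ_j, σ²),
α ~ N(μ_α, R_α),   γ ~ N(μ_γ, R_γ),   σ ~ N(0.5, 0.01) truncated at 0,
```

where α_i are species effects, γ_j intervention effects, and σ measures
how far the *equal-relative-potency* assumption (intervention ratios
preserved across species) may bend. Eleven named prior configurations —
skeptical (SP1, SP2), fundamentalist-skeptical (FSP), relational
(RP1–RP3), mechanistic (MP1, MP2), enthusiastic (EP) and combinations
(EP_MP1, EP_MP2) — encode different beliefs through the covariance
matrices R_α and R_γ. Inference is a partially collapsed
Metropolis-within-Gibbs sampler; models are compared by DIC and a
differential-entropy summary. See `docs/methods.md` for the full
account.

## Worked example

Fit the packaged evidence grid under the combined
enthusiastic + mechanistic prior and print the human posterior:

```python
import ketosynth as ks

data = ks.load_table2()                      # the 5 x 4 ln(MR) grid
res = ks.run_mcmc(data, ks.make_prior("EP_MP2"),
                  ks.MCMCConfig(seed=1))     # 100k burn-in, 200k draws, thin 20
print(res.summarize("Humans").round(2).to_string(index=False))
print("sigma:", {k: round(v, 2) for k, v in res.sigma_summary().items()})
```

```
intervention  median_mr  cri_low  cri_high  p_gt_1
          KD       1.50     0.88      2.61    0.94
         KD+       1.53     0.95      2.51    0.96
          CR       1.53     0.89      2.70    0.94
         CR+       1.57     0.94      2.64    0.96
sigma: {'median': 0.37, 'cri_low': 0.19, 'cri_high': 0.57}
```

Each row is the posterior of exp(α_humans + γ_j): the model's estimate
of the true human survival ratio for that intervention. Under this
optimistic-but-mechanistic prior every ketogenic intervention shows a
median survival prolongation of ~50% with at least 94% posterior
probability of benefit — including CR monotherapy, for which no human
study exists: that cell is pure cross-species extrapolation. The
posterior σ of 0.37 (prior mean 0.5) says the data find the
equal-relative-potency assumption more accurate than assumed a priori.

The same analyses run from the shell:

```
ketosynth fit --prior EP_MP2 --seed 1 --out fit.json
ketosynth reproduce table3 --fast --out table3.csv   # all 11 priors
ketosynth reproduce sensitivity rieger --fast        # drop the human KD cohort
ketosynth compare --priors all --fast                # DIC / entropy table
```

## Layout

| module | contents |
|---|---|
| `ketosynth.km_rmst` | Kaplan–Meier curves, RMST ± SE, RMST ratios |
| `ketosynth.study_data` | packaged study fixtures, evidence grid, study-removal sets |
| `ketosynth.pooling` | random-effects pooling of multi-study cells |
| `ketosynth.priors` | the eleven-prior catalogue |
| `ketosynth.mcmc` | the Gibbs sampler and posterior summaries |
| `ketosynth.model_compare` | deviance, DIC, p_D, entropy |
| `ketosynth.simulate` | synthetic arms and grids, coverage experiments |
| `ketosynth.pipeline` | one-call reproduction and sensitivity runs |
| `ketosynth.cli` | the `ketosynth` command |
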