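# mixlearn

A mixture learning model for **responses and response times** in
computer-based learning programs, with a full Bayesian estimation stack:
simulator, MH-within-Gibbs sampler, convergence and model-fit
diagnostics, and parameter-recovery evaluation.

## The problem

Learners working through an online program differ not only in what they
know but in *how* they engage. Some answer each item by actually solving
it; others rapid-guess — answering far faster than solution behaviour
allows, with accuracy near a flat chance level — and learn nothing from
the intervening material. Treating everyone as engaged biases both the
skill diagnoses and the item parameters. This package models each
learner-module cell with a latent engagement mode and lets the responses
*and* the response times say which mode it was.

## The model

N learners, K binary skills, T modules of diagnostic items with Q-matrix
`q_{jk}`. Per learner i and module t there is a skill profile
α_{i,t} ∈ {0,1}^K and a mode D_{i,t} ~ Bernoulli(ω), D = 1 meaning
disengaged.

Engaged (D = 0):

- responses follow DINA:
  P(X = 1) = (1 − s_j)^η g_j^{1−η}, η = ∏_k α_k^{q_jk};
- log response times are normal:
  log L ~ N(γ_j − (τ_i + φ·G), 1/a_j²), with G = 1 once all the item's
  skills are mastered (φ̂ < 0: masters answer *more slowly* — solution
  behaviour, not recognition);
- unmastered skills are acquired between modules with probability
  logistic(λ0 + λ1·θ_i + λ2·#other mastered skills); mastered skills
  are never lost.

Disengaged (D = 1): every item is answered correctly with one
probability g\*, log times are N(μ1, σ1²) for every item, and the
profile is frozen across the transition.

Initial profiles are multinomial over the 2^K classes (simplex π);
θ_i ~ N(0,1) and τ_i ~ N(0, σ_τ²). Estimation is by
Metropolis-Hastings-within-Gibbs, with profile *segments* (runs of time
points tied by disengaged modes) sampled jointly over the 2^K classes.
See `docs/methods.md` for the full conditionals, prior layer and
numerical choices.

## Worked example

Simulate the reference study design (585 learners, 4 skills, 4 modules
of 10 items, 3 % disengagement, the packaged reference truth) and refit
it:

```python
import mixlearn as ml

sim = ml.simulate_dataset(ml.SimDesign(n_learners=585, omega=0.03, seed=20))
res = ml.MixtureLearningModel(sim.data).fit(draws=2000, burn=500, seed=21)
print(res.summary())
```

```
Mixture learning model results
==============================================
learners: 585   modules: 4   items: 40   skills: 4
chains: 1   draws/chain: 2000   burn-in: 500
----------------------------------------------
     parameter        EAP         SD
       lambda0     -2.114      0.326
       lambda1      1.512      0.493
       lambda2      0.285      0.127
         omega      0.027      0.003
         gstar      0.518      0.021
           mu1      2.620      0.042
     sigma1_sq      1.070      0.064
           phi     -0.357      0.015
  sigma_tau_sq      0.713      0.043
      pi[full]      0.562      0.036
----------------------------------------------
learner-module cells flagged disengaged: 60
MH acceptance: theta 0.50, lambda 0.24
```

The generating values were ω = 0.03, g\* = 0.503, μ1 = 2.528
(exp(2.528) ≈ 12.5 s of rapid guessing per item), σ1² = 1.158,
φ = −0.332, λ = (−2.214, 2.757, 0.286), π_full = 0.527: the measurement
and mixture parameters are recovered closely, while the transition block
(λ, and θ behind it) is data-poor — at most three observed transitions
per learner — and stays noisy, as expected. Scoring the latent states
against the simulation truth:

```python
summ = res.summary_data
aar, par, _ = ml.attribute_agreement(sim.latent.alpha, summ.alpha_hat, summ.d_hat)
sens, spec = ml.mode_detection_metrics(sim.latent.d, summ.d_hat)
```

gives AAR per module `[0.885 0.911 0.932 0.935]` — skill diagnoses
agree with the truth for ~89–94 % of learner-skill cells, improving over
modules as mastery accumulates — and disengagement detection with
sensitivity 0.909 and specificity 1.000.

Diagnostics hang off the results object: `res.max_psrf()` (needs
`chains=2+`), `res.dic()` (joint deviance information criterion,
conditional on latents), `res.ppc()` (posterior predictive p-values for
change-score and change-time statistics).

## Command line

```bash
mixlearn simulate --n 585 --omega 0.03 --seed 1 --outdir run/
mixlearn fit      --data run/data.csv --q run/q.csv --draws 5000 --burn 1000 --outdir run/
mixlearn diagnose --data run/data.csv --q run/q.csv --fit run/fit.npz --outdir run/
mixlearn evaluate --data run/data.csv --q run/q.csv --truth run/truth.json --fit run/fit.npz --outdir run/
```

Every command writes a manifest with the seed, a config hash and timing;
identical seeds reproduce outputs byte-for-byte.

## Layout

| module | contents |
|---|---|
| `mixlearn.types` | domain containers (Q-matrix, data, latent states, parameter blocks) |
| `mixlearn.likelihood` | mode-conditional components and the complete-data log-likelihood |
| `mixlearn.simulate` | study designs, reference truth, dataset generator |
| `mixlearn.sampler` | the Gibbs machinery, chain storage, posterior summaries |
| `mixlearn.diagnostics` | PSRF, joint DIC, posterior predictive checks |
| `mixlearn.evaluation` | agreement rates, detection metrics, bias/RMSE/correlations |
| `mixlearn.model` | `MixtureLearningModel` / `MixtureLearningResults` facade |
| `mixlearn.io`, `mixlearn.cli` | CSV/JSON readers and writers, the `mixlearn` command |
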