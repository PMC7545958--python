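# rtcdm

Cognitive diagnostic models of item responses **and** response times, with
a latent rapid-guessing indicator.

## The problem

Cognitive diagnostic models (CDMs) classify test-takers as masters or
non-masters of a set of fine-grained skills ("attributes") from their item
responses, using a J×K binary Q-matrix that says which skills each item
requires. On computer-based tests, however, some responses are *rapid
guesses* — quick answers made without solution effort. Treating those
cells as genuine solution attempts biases item parameters (slipping up,
time intensity down), degrades attribute classification, and corrupts
estimates of each person's working speed.

`rtcdm` addresses this by modeling, for every person×item cell, a latent
behavior indicator ξ_ij:

* **solution attempt (ξ_ij = 1)** — correctness follows a CDM response
  rule (DINA: success 1−s_j only with *all* required attributes, g_j
  otherwise; DINO: success 1−s′_j with *at least one*; the saturated
  G-DINA rule is available in the forward model), and
  log RT_ij ~ N(β_j − τ_i, 1/κ_j²): item time intensity β_j minus person
  speed τ_i;
* **rapid guess (ξ_ij = 0)** — success probability drops to the guessing
  intercept, and log RT_ij ~ N(β₀, 1/κ₀²), a short, person-independent
  time law;
* ξ_ij ~ Bernoulli(π_j), where 1−π_j is the item's rapid-guessing rate.

Estimation is Bayesian, by a vectorized Metropolis-within-Gibbs sampler
with exact conditional draws over all 2^K latent classes (see
`docs/methods.md`). The package is aimed at psychometricians who want to
fit RT-DINA(-RG)/RT-DINO(-RG) models, and at methodologists who want a
reproducible simulator and recovery harness for the benchmark designs.

## Worked example

```python
import numpy as np
from rtcdm import table1_design, simulate_dataset, RTCDModel
from rtcdm.evaluate import classify_attributes, classification_accuracy, reliability

design = table1_design(rg_level=0.1)          # 30 items, 5 attributes, 1,000 persons
data = simulate_dataset(design, seed=7)

model = RTCDModel(data, model_form="DINA", rg=True)
res = model.fit(n_chains=2, n_iterations=2000, n_burnin=1000, seed=42)

print(res.summary().head(8).to_string(index=False))
acc = classification_accuracy(classify_attributes(res.alpha_probs), data.truth["alpha"])
rel = reliability(res.tau_mean, data.truth["tau"])
print(f"attribute classification accuracy: {acc:.3f}")
print(f"speed reliability (corr^2):        {rel:.3f}")
print(f"mean solution-attempt rate pi:     {res.posterior_mean('pi').mean():.3f}")
print(f"RG time intensity beta0:           {float(res.posterior_mean('beta0')):.3f}")
print(f"DIC:                               {res.dic():.0f}")
```

prints

```
parameter     mean       sd     2.5%    97.5%     rhat
 g[item1] 0.223889 0.024057 0.175101 0.271577 0.999564
 g[item2] 0.285316 0.024669 0.238570 0.332853 1.003014
 g[item3] 0.301902 0.025515 0.253339 0.350446 1.011107
 g[item4] 0.104790 0.022095 0.065115 0.150855 1.009632
 g[item5] 0.115982 0.019021 0.081670 0.154172 1.004726
 g[item6] 0.288131 0.024197 0.239003 0.334911 1.000956
 g[item7] 0.053281 0.015618 0.025621 0.087076 1.004800
 g[item8] 0.312703 0.024848 0.264910 0.361173 1.007507
attribute classification accuracy: 0.942
speed reliability (corr^2):        0.727
mean solution-attempt rate pi:     0.844
RG time intensity beta0:           1.997
DIC:                               301292
```

94% of the 5,000 person×attribute mastery decisions are correct; the
posterior mean of π averages 0.84 (the design's true average solution-
attempt rate is 0.85), and the rapid-guess time intensity β₀ is recovered
at 2.0 (truth 2.0). `res.xi_probs` gives each cell's posterior probability
of being a genuine solution attempt, and `res.plot_rt_densities()` draws
the item-level and rapid-guess RT densities.

## Command line

The same workflow is available from a shell:

```bash
rtcdm simulate --design study1 --rg 0.1 --reps 2 --seed 7 --out sim/
rtcdm fit --model dina --rg --responses sim/rep001/Y.csv \
      --rt sim/rep001/RT.csv --q sim/rep001/Q.csv --seed 3 --out fit/
rtcdm evaluate --alpha-posterior fit/alpha_posterior.csv \
      --truth sim/rep001/truth.json --out eval/
rtcdm recover --design study1 --rg 0.1 --models rg,base --reps 10 --seed 1 --out rec/
```

Q-matrices are headerless 0/1 delimited text; response and RT matrices
carry one header row of item labels; every run writes a `run_log.json`
with its seed, config hash and diagnostics.

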