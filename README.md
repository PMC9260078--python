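# labferm

Viability modeling and process optimization for lactic-acid-bacteria dough
fermentation.

Sourdough-style fermentation of wheat/soy flour blends with *Lactobacillus
plantarum* and *L. casei* (alone or as a co-culture) is characterized by the
viable count — log10 CFU/mL — as a function of fermentation time and flour
composition. `labferm` implements the two empirical model families used to
describe and optimize such processes, for food-bioprocess researchers who
want the whole fit-compare-optimize workflow as a tested library:

1. **Cubic response surfaces.** With x1 = time (h), x2 = wheat flour (%),
   x3 = soy flour (%), the response is fitted by ordinary least squares over
   the cubic family

   y = a0 + Σ ai·xi + Σ aii·xi² + Σ aij·xi·xj + Σ aii·xi³ + Σ aijk·xi·xj·xk,

   with sequential ANOVA (Linear → two-factor-interaction → Quadratic →
   Cubic blocks, each tested against the full-cubic residual mean square),
   structural pruning driven by the complementarity constraint x2 + x3 = 100,
   and OLS diagnostics (Cook's distance, normal-probability straightness).

2. **Single-hidden-layer neural networks.** y = A·f(B·X + bi) + bii with at
   most 10 hidden neurons and a sigmoid transfer bounded in (−1, 1), trained
   by Levenberg–Marquardt, BFGS, Møller's scaled conjugate gradient, or
   Fletcher–Reeves / Polak–Ribière conjugate gradients, on a 75/25
   systematic response-stratified split.

Fitted surfaces are maximized on a lattice over the experimental domain
(time 0–24 h × WF 90–100 %, SF = 100 − WF) to find optimal fermentation
conditions. The coefficient sets published in the reference fermentation
study — three pruned regressions and three 8-neuron networks — ship as
fixtures (`labferm.reference`), and a synthetic-data generator reproduces
the study's design (3 blends × 7 sampling times × triplicates) so every
stage is testable without the unpublished raw data.

## Worked example

```python
from labferm import (TrainingConfig, culture_preset, evaluate,
                     maximize_response, simulate_dataset, split_systematic,
                     train)

ds = simulate_dataset(culture_preset("LpLc", seed=1))   # 63 rows
train_ds, test_ds = split_systematic(ds, seed=1)        # 47 / 16 rows
model, _ = train(train_ds, TrainingConfig(neurons=8, seed=1, max_epochs=200))
print(evaluate(model, test_ds))
res = maximize_response(model.predict, grid_points=49)
print(res.optimum, res.time_h, res.wf_pct)
```

prints

```
FitMetrics(mse=0.011118..., r_value=0.99462..., p_value=3.42e-15)
11.7733... 10.5 96.6666...
```

— the held-out mean squared error and correlation of the trained network,
then the lattice optimum and its coordinates. (Network optima can exceed
every observed viability; between samples the surface is unconstrained, so
optima should be judged against the observed plateau, here ≈9.67.) The
scripts in `examples/` walk each capability: simulation, response-surface
fitting, trainer comparison, optimization, and the reference models. A thin
CLI mirrors the stages: `labferm simulate | fit-rsm | fit-ann | optimize |
run | reference-report`.

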