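"""Train the five network trainers on one culture and rank them.

Splits the data 75/25 with the systematic stratified rule, trains an
8-neuron network per method, and prints the comparison table (test MSE,
correlation R, regression p-value).  Smaller MSE and R near 1 mean the
network reproduces the held-out viability curve.
"""

from labferm import (TrainingConfig, culture_preset, evaluate,
                     model_comparison, simulate_dataset, split_systematic,
                     train)

ds = simulate_dataset(culture_preset("LpLc", seed=1))
train_ds, test_ds = split_systematic(ds, seed=1)
print(f"train {len(train_ds)} rows / test {len(test_ds)} rows")

candidates = []
for method in ("levenberg_marquardt", "quasi_newton_bfgs",
               "scaled_conjugate_gradient", "cg_fletcher",
               "cg_polak_ribiere"):
    cfg = TrainingConfig(method=method, neurons=8, seed=1, max_epochs=200)
    model, history = train(train_ds, cfg)
    candidates.append((f"{method}/8", evaluate(model, test_ds)))

print(model_comparison(candidates).to_string(index=False))
print("(winner on top: lowest held-out mean squared error)")
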