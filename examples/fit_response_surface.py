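"""Fit the cubic response surface to synthetic data, with model selection.

Runs the sequential ANOVA (is each polynomial block worth its degrees of
freedom?), fits the structurally admissible cubic terms, prunes, and prints
the coefficient table and fit summary.  Because wheat and soy percentages
sum to 100, the surviving term set is {x1, x1^2, x1^3, x2^2, x2^3, x3^3}
with no intercept — the same structure as the reference models.
"""

from labferm import culture_preset, sequential_anova, simulate_dataset
from labferm.models import FULL_CUBIC_TERMS
from labferm.rsm import STRUCTURAL_REMOVALS, cooks_distance, fit_rsm, prune_terms

ds = simulate_dataset(culture_preset("Lp", seed=1))

print("sequential ANOVA (F against the full-cubic residual mean square):")
print(sequential_anova(ds).table.to_string(index=False))

base = [t for t in FULL_CUBIC_TERMS if t not in STRUCTURAL_REMOVALS]
model, report = fit_rsm(ds, base)
terms = prune_terms(report)
if terms != report.terms:
    model, report = fit_rsm(ds, terms)

print("\npruned model coefficients:")
print(report.to_frame().to_string(index=False))
print(f"\nRMSE {report.rmse:.4f} log10 CFU/mL   R^2 {report.r_squared:.4f}")
print(f"max Cook's distance {cooks_distance(report).max():.4f} "
      "(< 1: no influential outliers)")
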