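"""Generate a synthetic viability dataset for one culture.

Builds the L. plantarum preset (triplicates on the 3-blend x 7-time study
design, plateau 9.61 log10 CFU/mL) and prints the per-time means.  The
numbers show the logistic rise from the ~7 log10 CFU/mL inoculation level
to the 24-h plateau.
"""

from labferm import culture_preset, simulate_dataset

ds = simulate_dataset(culture_preset("Lp", seed=1))
print(f"{len(ds)} rows (3 blends x 7 times x 3 replicates)")
means = ds.df.groupby("time_h")["viability_log10cfu_ml"].mean()
for t, v in means.items():
    print(f"  t = {t:4.0f} h   mean viability = {v:.3f} log10 CFU/mL")
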