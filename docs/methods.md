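# Methods

## Scope and data model

The package models the viable count (log10 CFU/mL) of *Lactobacillus*
cultures fermenting wheat/soy doughs as a function of fermentation time
(0–24 h) and flour composition (wheat-flour percentage 90–100, soy flour
the complement). The universal input is a `ViabilityDataset`: one row per
(time, blend, culture, replicate) observation, validated so that
`wf + sf = 100` within 1e-9, times are non-negative, and viability is
positive. Replicates are always fitted as individual rows, never averaged.

## Response-surface track

**Model family.** The full cubic polynomial in the raw (unscaled) process
variables: constant, linear, pairwise and triple interaction, quadratic and
cubic terms. Raw scales are deliberate — the reference coefficient sets
(e.g. 0.0021154 for the WF square) are only meaningful with WF on its 0–100
scale — at the cost of a poorly conditioned design; the fit uses a pivoted
QR decomposition rather than normal equations for that reason.

**Rank structure.** Because the flour percentages are complementary, the
full family is always rank-deficient (e.g. the linear WF and SF columns
plus the constant span a 2-dimensional space), and with the study's three
blend levels any polynomial in WF beyond degree two collapses further.
`fit_ols` treats rank deficiency as an error naming the collinear columns;
the sequential ANOVA instead uses rank-tolerant projections and reports
each hierarchy block with its *rank increment* as degrees of freedom. Every
block F-statistic uses the full cubic model's residual mean square as
denominator, matching a decomposition with a single residual row. The
"Mean" row is the grand-mean component of the uncorrected total SS; the
conservation identity (blocks + residual = uncorrected total) is exact and
tested.

**Pruning.** The final model drops the constant, the linear flour terms,
all interactions and the SF square on structural grounds (complementarity),
keeping {x1, x1², x1³, x2², x2³, x3³} with no intercept. A significance
filter (two-sided coefficient t-tests at level `alpha`) runs after the
structural step but defaults to `alpha = 1` — i.e. off — because the
reference models retain terms that are individually non-significant; the
printed six-term structure can only arise from the structural rule.
Through-origin fits measure R² against the uncorrected total SS.

**Diagnostics.** Cook's distance D_i = r_i²·h_i / (p·s²·(1−h_i)²) with a
flag threshold of 1.0; a zero residual is defined to have D = 0, and unit
leverage yields infinity with a warning. Normal-probability pairs use the
(i − 0.5)/n plotting positions and internally studentized residuals, with
the Pearson correlation of the pairs as a straightness score.

## Neural-network track

**Architecture.** One hidden layer, at most 10 neurons, three inputs, one
linear output: y = A·f(B·X + bi) + bii. Two transfer functions are
supported: `neg_half_tanh`, f(z) = 2/(eᶻ+1) − 1 = −tanh(z/2) (the form the
reference models are printed with), and the conventional `tanh`. Both are
bounded in (−1, 1), so the pre-descaling output always lies in
bii ± Σ|A_k| — a property-tested invariant.

**Scaling.** A `ScalingSpec` maps each input linearly from its range to
[−1, 1] and optionally maps the output back from [−1, 1] to an observed
range (modes `raw`, `inputs_scaled`, `inputs_and_output_scaled`). Training
fits the scaling on the training data's min/max, mirroring standard
neural-toolbox practice; the output map is affine and unclipped, so network
outputs beyond ±1 descale beyond the observed range — which is how fitted
surfaces (and the reference study's own reported optima) can exceed every
observed viability. Optima should therefore be read against the observed
plateau.

**Training.** All trainers minimize the mean squared error in the working
(scaled) space over the flattened parameter vector [A, B row-major, bi,
bii], starting from uniform(−0.5, 0.5) weights drawn from the run seed, and
return the best-cost iterate plus the accepted-cost history:

* *Levenberg–Marquardt*: damped Gauss–Newton on the residual vector with the
  analytic network Jacobian (dy/dA_k = f(z_k), dy/dB_kj = A_k f′(z_k) x_j,
  dy/dbi_k = A_k f′(z_k), dy/dbii = 1, with f′ = (f²−1)/2 for the printed
  transfer and 1−f² for tanh; verified against central finite differences).
  λ starts at 1e-3, ×10 on rejected steps, ÷10 on accepted ones; accepted
  costs are non-increasing by construction.
* *BFGS* and *DFP*: inverse-Hessian updates with a strong-Wolfe line search
  (Armijo backtracking fallback), curvature-guarded.
* *Scaled conjugate gradient*: Møller's algorithm (σ = 1e-4, initial
  λ = 1e-6), no line search.
* *Fletcher–Reeves* and *Polak–Ribière (plus)* conjugate gradients with
  restarts every `#parameters` iterations and the same Wolfe search.

A "Fletcher–Powell" trainer is mapped to the conjugate-gradient Fletcher
variant by default (the naming convention of the neural toolbox family the
reference models come from); the Davidon–Fletcher–Powell quasi-Newton
reading is available as `quasi_newton_dfp`. Defaults: 1000 epochs, gradient
tolerance 1e-7, cost goal 0. No validation set, early stopping or
regularization — the split is train/test only.

**Split.** The systematic stratified split sorts rows ascending by
viability and sends every 4th row, starting at a seed-drawn offset in
{0..3}, to the test set: test values interleave the training range 1-in-4
and exactly four distinct splits exist. The test-set size is ⌈n/4⌉ when n
is a multiple of 4 (as in the study design) and varies by one row with the
offset otherwise.

**Evaluation.** MSE, Pearson R of predictions vs observations, and the
p-value of the observed-on-predicted simple-regression F-test; candidates
are ranked by ascending MSE with ties broken by descending R.

## Optimization

Surfaces are maximized on a regular lattice over time × WF with
SF = 100 − WF; the default 49 × 49 mesh (0.5 h and 10/48 % steps) is the
mesh on which the reference argmax coordinates (19 h / 97.7083 %,
21 h / 95.625 %) lie exactly. Ties break toward the smallest time, then the
smallest WF. `refine_optimum` re-grids ±1 coarse cell at a chosen
subdivision and never returns less than the coarse optimum. Extrapolation
outside the experimental domain is not offered.

## Reference models and the scaling resolution

The printed coefficient sets are transcribed digit-for-digit with three
documented corrections (a sign restored from the coefficient table, a
dangling copy-paste constant dropped, one table block re-assigned to the
co-culture case). The printed networks omit any normalization statement,
yet their reported optima (10.3076 and 12.2755 log10 CFU/mL) exceed every
observed viability, so a raw reading cannot be complete. The resolution
harness evaluates each printed network under six conventions — {raw, inputs
scaled to [−1,1] on time [0,24] / WF [90,100] / SF [0,10], inputs and
output scaled} × {printed transfer, tanh} — maximizing each on the default
lattice and scoring the (optimum, argmax) triple against the reported one.
For all three cultures the winner is the inputs-and-output-scaled tanh
convention (the common toolbox default), with the output descaled to
[7, case 24-h endpoint]; that convention is frozen in the fixtures. No
convention reproduces the reported optima to four decimals (residuals
≈0.2–1.0 log10 CFU/mL; argmaxes within one to a few lattice steps), which
the package records openly in `reference_report()` rather than papering
over — the printed weight matrices appear not to be the exact networks used
for the reported optimum search.

## Synthetic data

The generator emulates the study design: logistic growth in log10-CFU
space, v(t) = initial + (asymptote − initial)·(σ(t) − σ(0))/(1 − σ(0)) with
σ the logistic sigmoid — anchored exactly at the inoculation level at t = 0
and at the plateau as t → ∞; a small linear shift of the plateau with soy
content (−0.005 log per % SF, within the "slight" composition effect the
surfaces show); and i.i.d. Gaussian replicate noise on the log scale.
Presets per culture set plateaus to the observed 24-h endpoints
(9.61 / 9.54 / 9.67 log10 CFU/mL), noise to the reported half-widths
(0.04 / 0.11 / 0.10), and a longer lag for *L. casei* (6 h vs 3 h), whose
early growth was slower; inoculation is 7 log10 CFU/mL (a 10 % inoculum at
8 log10 CFU/mL). What the generator does *not* emulate: replicate-to-
replicate correlation, plate-count quantization, pH/substrate feedback, or
any mechanistic kinetics — so green tests demonstrate pipeline correctness
on data of the study's shape and noise scale, not biological validity.

## Numerical choices and limitations

Seeds are explicit everywhere; identical data + config + seed reproduce a
trained model bit for bit. Model files are versioned JSON; unparseable or
mismatched files raise rather than degrade. Default problem sizes keep the
full test battery in the tens of seconds: training tests use 3–8 neurons,
tens of epochs and ≤63-row datasets, which suffices because the properties
checked (Jacobian correctness, cost descent, teacher-net recovery) are
size-independent. Known limitations: the raw-scale cubic design is
ill-conditioned (mitigated by QR, not eliminated); trainers can stall in
flat regions on hard seeds (the cost-descent battery uses modest epoch
budgets and all five trainers pass it); and the fit statistics of the
original study (RMSE/R² per culture) cannot be checked without its
unpublished raw table — the suite contains conditional tests that activate
if a user supplies that table, plus always-on property substitutes.
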