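# Methods

This note documents the models, the numerical choices, and the study
conditions encoded in the synthetic-data generator, in the order the
pipeline uses them.

## Logic-based network model

Node activities are normalized to `[0, ymax]` with `ymax = 1` unless a
node is knocked out. Each reaction `r` targeting node `j` contributes an
activation `w_r · Π_k φ(y_k)` where the product runs over its operands,
`φ = f` for activating operands and `φ = 1 − f` for inhibitory (`!`)
ones, and `f` is the normalized Hill function

    f(x) = B x^n / (K^n + x^n),  B = (E^n − 1)/(2E^n − 1),  K^n = B − 1,

with `E = EC50`. The constants make `f(0) = 0`, `f(EC50) = ½`, `f(1) = 1`
for any `EC50 ∈ (0,1)` and `n > 0`; at the removable singularity
`EC50^n = ½` the limit `f(x) = x^n` is used. Multiple reactions on one
target OR-combine as `1 − Π(1 − a_r)`; the node then relaxes as
`dy/dt = (ymax·g − y)/τ`. These gate conventions are the single supported
dialect of the rule language; they are the standard continuous
generalization of Boolean AND/OR/NOT used by logic-based ODE tools.
Operand-free reactions (`=> A`) are input drives whose weight is the
scenario's time-varying control.

Default time constants are category-driven when a nodes table omits
them: `0.005·τ` for inputs and intracellular intermediates, `0.02·τ` for
gene-expression outputs, and `τ` for the cell-size output, where `τ` is
the species' organ-scale growth time constant — so all simulation time is
dimensionless `t/τ`, and conversion to hours happens only at the I/O
edge. Hill parameters are part of a model definition; a reaction row
without `n` or `EC50` is rejected rather than silently defaulted.

**Integration.** `scipy.integrate.solve_ivp` with LSODA (time constants
can span two orders of magnitude), default tolerances `rtol 1e-6 /
atol 1e-8`, tightened in oracle comparisons and loosened to `1e-4 / 1e-6`
inside Monte Carlo and likelihood loops, where the resulting ~1e-5
activity errors are orders of magnitude below the observational SDs
(≥ 0.05 fold). The steady-state criterion is `max|dy/dt| < 1e-6`
sustained over a trailing window of 0.1 t/τ; a constant-input steady
state can also be computed by damped fixed-point iteration on
`y = ymax·g(y)` (tolerance 1e-10), which matches the integrated steady
state on all bundled networks and is used for the pre-overload baseline
inside sampling loops, with automatic fallback to integration.

## Ventricular geometry and the strain input

The left ventricle is a thin-walled sphere: stretch
`λ = (V_ED/V0)^{1/3}`, Lagrangian strain `ε_f = (λ² − 1)/2` relative to
the unloaded (zero-pressure) state. Eccentric growth enlarges the
unloaded cavity; the default rule `V0fold = massfold^{3/2}` follows from
constant wall thickness (wall mass ∝ r0²) and is exposed as a pluggable
strategy (wall-thickness time courses are carried through I/O but unused
by default). Baseline end-diastolic stretch is sampled per iteration
from Normal(1.12, 0.03), truncated above 1.005 so the baseline strain
anchor stays positive; the mean is a literature-typical healthy canine
end-diastolic fiber stretch and the SD spans reported estimates.

Organ strain maps to the network's mechanical input weight by
`w(ε_f) = C_myo (e^{D_myo ε_f/ε_f0} − 1)`. `D_myo` is not a free
parameter: solving the baseline anchor `w(ε_f0) = w0` gives
`D_myo = ln(1 + w0/C_myo)`, so the map is exactly zero at zero strain and
exactly `w0` at baseline strain for any gain. For `ε_f < 0` the same
formula applies (strictly increasing, floored at `−C_myo(1 − e^{−D_myo
|ε_f|/ε_f0})`); scenario code clips network weights at zero, so negative
map outputs act as a silenced input. Within the gain range used here the
map is nearly linear (`C_myo·D_myo ≈ w0`), which makes `C_myo` only
weakly identifiable — its posterior is expected to stay close to its
prior, and the recovery tests treat that as the correct answer rather
than as information.

## Cross-species time normalization and stimulus curves

Mass-growth data are fitted per species with
`FC(t) = 1 + A(1 − e^{−t/τ})` by weighted least squares (weights
`1/sd²`; the reported SDs are the only replication information
available, and inverse-variance weighting is the natural estimator under
the per-dataset normal model). Dividing each species' time axis by its
fitted τ puts all data on one `t/τ` axis. A table carries a
`t_over_tau` column only after normalization, and re-normalizing is an
error — the column doubles as the idempotence flag.

Stimulus fold-change curves support four families, all anchored at
`FC(0) = 1` by construction: constant, linear `1 + a·t`, saturating
exponential `1 + A(1 − e^{−t/θ})`, and peak-decay
`1 + A (t/θ) e^{1 − t/θ}` (rises to `1 + A` at `t = θ`, relaxes back).
Fits return the linearized Gaussian parameter covariance; an exactly
interpolating fit gets a zero covariance instead of a singularity. Curve
sampling draws parameters from that Gaussian and rejects draws whose
curve is not strictly positive on the domain (concentration and volume
folds cannot cross zero). Stimuli are sampled independently of each
other per iteration; a correlation structure between hormones is a known
omission (see Limitations).

## Bayesian calibration

The likelihood of one parameter set compares predicted fold changes of
node activities (activity at the dataset's `t/τ`, relative to the
pre-overload baseline steady state) to observed mean ± SD fold changes
under a normal error model, one term per dataset row with equal weight —
with no replication counts available, each published dataset is one
observation. A soft preference keeps the baseline cell-size activity
near 0.5, the most responsive region of its sigmoid, implemented as a
Gaussian penalty with σ_b = 0.1 (weak enough to be overridden by data,
strong enough to exclude saturated baselines). Failed integrations give
−∞ (rejected). Each evaluation draws fresh stimulus curves, so the
sampler targets a curve-averaged likelihood.

The sampler is Metropolis–Hastings with one-parameter-at-a-time Gibbs
sweeps. Proposals are Gaussian steps with SD equal to `proposal_frac`
(default 5%, 15% at the short desk-scale chain lengths used in tests) of
each prior range, mixed with probability 0.1 with a uniform draw over
the parameter's bounds — the uniform component is a symmetric
independence proposal, so the Metropolis acceptance rule is unchanged,
and it lets short chains traverse nearly flat directions (such as the
strain-map gain). Because the likelihood is stochastic, the current
state's log-target is re-evaluated with a fresh curve draw at the top of
every sweep; without the refresh a chain freezes on states that drew
unusually favorable curves. Deterministic targets are unaffected.

Stage 1 samples under a uniform prior inside the bounds
(hormone input weights within the ranges where the cell-size output is
responsive; background weight in [0.01, 0.4]; map gain in [0.5, 20], a
wide weakly-informative range since no published bound exists). Stage 2
uses the stage-1 posterior as its prior, represented by a Gaussian KDE
(Silverman bandwidth) whose log-density adds to the stage-2 target.
Convergence is monitored every `check_every` iterations as the relative
change of block-wise parameter means (< 5% flagged converged); the
diagnostics are recorded on the returned ensemble.

After sampling, implausible solutions are filtered: *reversal* if the
cell-size trajectory falls below baseline by more than 1% of baseline at
any time (hypertrophy does not spontaneously reverse under sustained
overload), *runaway* if the terminal slope exceeds 0.5% of baseline per
unit `t/τ` at the horizon (mass plateaus chronically). Both thresholds
are configuration, not data. The baseline strain weight `w0` is fixed
per run and scanned over a grid; the scan reports mean log-likelihood
and the implausible fraction per value, the two quantities used to pick
the operating point.

## Scenario ensembles

Each Monte Carlo iteration draws one posterior row, computes the
baseline steady state under those weights, applies the scenario, and
integrates to the horizon (`t/τ = 5` for steady-state questions, 3 for
sensitivity). Volume overload drives every hormone input with
`w0 × FC(t)` from freshly sampled curves and the strain input through
the exponential map of a sampled strain trajectory. Infusions raise one
input weight to 1 (saturation) or multiply its baseline weight by a
concentration fold drawn from a normal truncated at ≥ 1; an exogenous
agonist with a null baseline weight scales the background weight
instead, so a fold dose remains meaningful. Blockade forces the target
receptor's `ymax` to zero. Hemodynamic side effects of agonists and
blockers (heart rate, blood pressure, contractility) are outside the
model.

Drug effects are estimated with common random numbers: both arms share
the posterior draw, curve draws and dose draws in each iteration, which
removes between-draw variance from the paired difference (the pairing
leaves the mean unchanged and shrinks its Monte Carlo error). Ensembles
report central percentile intervals (CI50 = [25th, 75th], CI90 = [5th,
95th], linear interpolation, ≥ 20 samples required), a classification per
output (increase/decrease if ≥ 75% of iterations moved that way —
inclusive at the boundary, exact zeros counting toward neither — else
mixed), coverage counts of experimental means inside CI50/CI90, and
Pearson correlations between inputs and outputs across iterations
(zero-variance columns yield missing entries).

## Synthetic study conditions

The generator emulates the structure of the experimental corpus, not its
measurement physics:

- **Species time constants** 1095 h (dog) and 283 h (rat) — the fitted
  mass-growth kinetics of the two experimental models; chronic mass fold
  1.36 with amplitude noise, end-diastolic volume fold 1.67 rising fast
  (θ ≈ 0.15 t/τ) while mass follows slowly (θ ≈ 1 t/τ), so strain rises
  acutely and then declines as growth catches up.
- **Observation tables**: per variable and time point, several "studies"
  report mean = truth + Normal(0, between-study SD 0.08) with
  within-study SD 0.15 — typical scatter for serum assays and blot
  densitometry; mass-fold datasets use 0.02 scatter (mass is measured
  far more precisely) with corpus-scale sizes (41 dog / 45 rat datasets)
  and geometric time spacing, since the early rise is what informs τ.
  A single fit on such a corpus still carries ~10% sampling SD on the
  dog:rat τ ratio; recovery tests therefore check statistical
  consistency (truth inside the fit's propagated CI), and the
  acceptance script pools five replicate corpora for a ~4% estimate.
- **Toy networks** (≤ 10 nodes): a chain (agonist → receptor → kinase →
  transcription factor → gene/cell-size outputs, with strain and
  background inputs OR-merged at the kinase and an orphan receptor with
  no path to the growth output), a crosstalk variant (AND-gated
  transcription factor, NOT-gated gene output), and a runaway-prone
  variant (positive feedback of cell size onto the kinase). Reaction
  parameters are chosen so the baseline cell-size activity sits near 0.5
  and hand-evaluated nested-Hill steady states are exact oracles. Truth
  weights (agonist 0.12, background 0.08, gain 5.86, strain baseline
  0.06) put the toy in a responsive, calibrated-like regime.

Passing tests on these conditions demonstrate that the machinery — gate
semantics, solver, sampler, filters, ensemble statistics — is correct
and that parameters generating the data are recovered; they do not
demonstrate that any particular biological network is right, and
full-scale conclusions require the published network tables, which this
package reads but does not distribute.

## Known limitations

- Hormone stimuli are sampled independently per iteration; real
  neurohormonal activation is correlated with overload severity, so
  predicted ensemble spread is likely overestimated. A correlation hook
  exists at the curve-set level but no default structure is shipped.
- The strain trajectory is imposed, not fed back from the growth the
  network predicts within the same iteration.
- The two-stage scheme reuses the data in both stages (the stage-1
  posterior becomes the stage-2 prior), which sharpens the final
  ensemble relative to a single-stage posterior; it is retained as the
  documented procedure of this pipeline.
- The thin-walled sphere ignores wall thickness dynamics and regional
  mechanics; with the constant-wall-thickness growth rule and the mean
  chronic folds (mass 1.36, volume 1.67), chronic stretch re-normalizes
  to within a few percent of baseline, and the fraction of sampled
  trajectories ending below baseline is ~40% — majority-below-baseline
  behavior requires a growth rule in which unloaded volume grows faster
  than mass^{3/2} (e.g., with measured wall thinning).
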