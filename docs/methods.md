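# Methods

## The model

`repairkinetics` models the fate of a ~172 kb circular minichromosome after
ionising radiation. A dose of ~50 Gy linearises essentially every copy
through one non-specifically positioned double-strand break (DSB) and
deposits a Poisson-distributed burden of single-strand breaks (SSBs, mean
~8.5 per molecule). Repair then moves molecules through four forms that
pulsed-field gel electrophoresis (PFGE) can distinguish (in part):

| compartment | form |
|---|---|
| `LSSB` | linear molecules still carrying SSBs |
| `L`    | full-length linear molecules, SSBs repaired |
| `CSSB` | nicked (relaxed) circles: DSB repaired, SSBs remain |
| `S`    | supercoiled, fully repaired circles |

Interconversion is first order in the *molecule* fractions — each rate
constant is the fraction of molecules transferred between compartments per
hour, not a per-break rate. Repairing "all SSBs" is one lumped first-order
step. With `k_sd` (LSSB→L), `k_ds` (LSSB→CSSB), `k_d` (L→S), `k_s` (CSSB→S),
and effective DSB-repair rates `kd* = k_d·hr_factor·s_inh`,
`kds* = k_ds·hr_factor·s_inh`:

```
dS/dt    =  kd*·L + k_s·CSSB
dL/dt    =  k_sd·LSSB − kd*·L
dLSSB/dt = −(k_sd + kds*)·LSSB
dCSSB/dt =  kds*·LSSB − k_s·CSSB
```

This transition topology is the unique one consistent with the verbal
definitions of the four rates and with the predicted 20-hour behaviour
(transient rise of nicked circles under normal repair; monotone
accumulation of clean linear DNA under DSB arrest). First-order kinetics is
deliberate: Michaelis–Menten alternatives need more parameters than the
two-band data can identify.

Scenario switches: `s_inh ∈ {0, 1}` is 0 when DSB repair is arrested by a
DNA-PKcs inhibitor (NU7441, wortmannin), zeroing `k_d` and `k_ds`;
`hr_factor ∈ (0, 1]` scales the same two rates to represent partial
impairment of the homologous-recombination arm (KU55933 and caffeine 0.70,
mirin 0.74, Rad51 depletion 0.80, from the observed ~30/26/20% reductions in
the decay rate of the linear band). PARP-1 (NU1025, 1,5-IQD) and
topoisomerase II (ICRF-193, F11782) inhibitors map to the identity — they
leave these kinetics unchanged.

Units are hours and per-hour throughout; only derived half-times
(`ln 2 / k`) are reported in minutes.

## Solving

The system is linear with constant coefficients and triangular structure,
so it is solved in closed form as an exponential cascade. The divided
differences `(e^{−xt} − e^{−yt})/(y − x)` are evaluated with `expm1` and a
`t·e^{−xt}` limit branch so coincident rates (e.g. the LSSB exit rate
equalling `kd*`) lose no accuracy. `S` is computed as the conservation
remainder, so mass balance holds to machine precision by construction. An
independent adaptive Runge-Kutta route (`scipy.integrate.solve_ivp`,
DOP853, rtol 1e-9, atol 1e-12) is provided and agrees with the closed form
to ≤ 1e-8; tests additionally cross-check both against `scipy.linalg.expm`.

## Observation model

PFGE quantitates two bands: the linear band (where `L` and `LSSB`
co-migrate at full genomic length) and the supercoiled band (`S`). Nicked
circles are not quantitated. The observation operator is therefore
`linear_total = L + LSSB`, `supercoiled = S`; `CSSB` is latent and only
constrained through mass balance. Fractions of total signal (0–1) are the
canonical unit end to end; raw intensity units are expected to be
normalised by the total signal upstream.

## Fitting

`StrandBreakRepairModel.fit` minimises the sum of squared residuals over
all replicate rows of all conditions jointly, sharing the rate constants
and (by default) the initial state across conditions — both arms come from
the same irradiated population, so one initial vector is the physically
motivated default (`share_init=False` unshares it). Replicates enter the
objective individually rather than as means; optional `1/SEM²`-style
weighting is available through a weight column.

Numerical choices:

* rates are optimised on the log scale (positivity by construction), box
  bounds `[1e-4, 50]` per hour;
* the initial state is parameterised by stick-breaking from `[0, 1]³` onto
  the simplex (LSSB, then L, then CSSB, with S the remainder). Unlike a
  softmax, this reaches the simplex boundary at finite parameter values —
  important because the post-irradiation state has `S ≈ CSSB ≈ 0`;
* the optimiser is `scipy.optimize.least_squares` (TRF, xtol = ftol =
  1e-14) with multistart: log-rates drawn uniformly on `[ln 0.01, ln 10]`,
  stick-breaking coordinates uniform on the unit box, all from one seeded
  generator, 100 starts by default; the best start is reported together
  with the full multistart trace;
* the tied model (`tie_rates=True`, the default) shares one parameter for
  `k_s = k_sd` and one for `k_d = k_ds` by construction, not by penalty.

Ties are the scientifically supported configuration: with two observed
bands the four-rate model fits no better and its estimates scatter across
optimiser starts.

## Identifiability diagnostics

`identifiability_scan` refits from many random starts, keeps the starts
whose SSR is within 1% of the best (plus an absolute floor of 1e-12 so a
near-zero optimum keeps a nonempty band), and reports the spread
(max − min) of each rate among them; a spread above 25% of the best-fit
value raises the `non_identifiable` flag. The 1% band and 25% threshold are
package conventions. `fit` runs the same dispersion check on its own starts
and flags degenerate data (e.g. all signal supercoiled at all times, which
leaves the rates unconstrained).

A finding worth recording: on *noise-free* synthetic two-condition data the
four-rate model is structurally identifiable — every start converges to the
generating values, because two exact band trajectories pin down all four
exponential amplitudes. The multistart scatter is a *practical*
identifiability failure: it appears at the assay's noise level (sd 0.03,
three replicates), where roughly 40% of noise realisations produce
dispersed or wildly displaced near-optimal fits (e.g. `k_d` escaping to the
bound). The tied model never flags in either regime. Tests therefore
exercise the scan on noisy datasets across several fixed seeds and require
the flag on at least one, with the tied model never flagging.

## Confidence intervals

Parametric bootstrap: the residual scale is estimated as the
root-mean-square residual of the fit (`sqrt(SSR/(n − p))`); `n_boot`
datasets are simulated from the fitted model with Gaussian noise at that
scale (truncated to the valid signal range), each is refitted from the
point estimate, and the 2.5/97.5 percentiles are reported. Intervals are
widened to contain the point estimate when a percentile falls inside it,
and `n_boot < 50` sets an interval-stability warning flag. Bootstrap refits
use a relaxed tolerance (1e-10), which is far below the percentile
resolution. A noise-free fit yields degenerate intervals equal to the
estimate.

## Endpoint comparison

Inhibitor effects at the 2 h endpoint are tested with the classical
pooled-variance unpaired two-sample t-test (`scipy.stats.ttest_ind`,
`equal_var=True`), reporting the difference of means and the two-sided
p-value; at least two replicates per group are required.

## Break and fragmentation simulation

Molecules are circles with continuous kb coordinates and an arbitrary
origin. Break counts come from configurable models (default: exactly one
DSB, Poisson(8.5) SSBs — the 50 Gy reference dose; dose scaling is linear
in the means); positions are i.i.d. uniform on the circle. S1 digestion of
a linearised molecule opens the circle at the DSB and cuts at every SSB, so
n SSBs yield n + 1 fragments summing exactly to the genome length; the mean
fragment length for a fixed burden n has expectation `genome/(n + 1)`.
`estimate_ssb_count` reports both inversion conventions — `genome/mean`
and `genome/mean − 1` — because the printed "8 to 9 breaks" bracket is
consistent with either; the midpoint of the integer bracket of
`genome/mean` (8.5 for 20 kb fragments) is the headline burden. No strand
is assigned to an SSB: the assay cannot resolve strand, and closely spaced
opposite-strand nicks forming de facto DSBs are not modelled. PFGE
mobility physics (impaled nicked circles, theta forms) is out of scope.

## Synthetic data generator

The generator emulates the statistical structure of the PFGE time courses:
five time points over 0–2 h (`{0, 0.5, 1, 1.5, 2}`), three independent
replicates, two arms (control and NU7441 DSB arrest), additive Gaussian
noise with sd 0.03 on the fraction scale, truncated at 0. The time grid and
noise level are package choices — the experiments span 2 h but the exact
sampled times and error magnitudes are not published numerically; 0.03 is
of the order of the plotted replicate scatter and is configurable. The
reference initial state `(S, L, LSSB, CSSB) = (0, 0.05, 0.95, 0)` encodes
near-quantitative linearisation with a small SSB-free linear fraction; it
is a fixture convention and fits re-estimate the initial state regardless.

What the generator does *not* emulate: gel-image quantitation artefacts,
background subtraction, correlated replicate errors, signal-dependent
noise, or dose–response beyond the reference dose. Passing recovery tests
on this generator therefore demonstrates the estimator's correctness and
stability under the stated noise model, not the fidelity of the published
rate values to re-measured gels — the underlying replicate quantitations
exist only as figure panels and are not reproduced here.

## Problem sizes in the test suite

The property suite uses sizes chosen to make sampling bounds sharp while
keeping the suite quick: 10⁴ molecules for fragmentation oracles (3-SE
bounds), 10⁵ for compartment-fraction convergence, 100 noisy datasets ×
100 bootstrap refits for interval coverage (≥ 85% required), and 100
multistarts for the headline self-consistency fit.

## Known limitations

* The Discussion-level half-times quoted for the minichromosome (~40 min
  for DSB repair, ~140 min for SSB repair) do not equal `ln 2 / k` at the
  fitted rates (56.2 and 198.0 min); how those figures were derived is not
  stated in the source, so the package reports `ln 2 / k` and documents the
  discrepancy rather than guessing the original procedure.
* Rates are assumed constant over the experiment (and over the 20 h
  extrapolation); no chromatin context, no repair saturation.
* The inhibitor `hr_factor` values are point estimates read from the
  reported percentage reductions; no uncertainty is attached to them.
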