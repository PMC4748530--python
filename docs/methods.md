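# Methods

This note documents the models implemented in `aromaflux`, the default
parameter choices and the numerical decisions behind them, and what the
synthetic-data generator does and does not emulate.

## Gas–liquid balance

An online GC samples the fermenter's exhaust gas and reports each volatile
compound's concentration `C_gas(t)` in mg per litre of CO₂. Three
quantities are derived per compound:

- `C_liq(t) = C_gas(t) / k_i(E, T)` — the liquid concentration, using the
  partition model `ln k_i = F1 + F2·E − ((F3 + F4·E)/R)(1000/T − 1000/T_ref)`.
  `E` is ethanol (g/L), derived from cumulative CO₂ when not measured,
  `T` is in kelvin and `T_ref` defaults to 293.15 K.
- `L(t) = ∫₀ᵗ C_gas·Q dτ` — cumulative losses, with `Q` the CO₂ flow rate
  in L CO₂/L must/h. The integral is evaluated by the trapezoidal rule on
  the observed grid: exact for piecewise-linear integrands, second-order
  for smooth ones, and well-defined on irregular sampling.
- `P(t) = C_liq(t) + L(t)` — total production, the cells' synthesis
  capacity independent of evaporation; `RL = L/P` at the end of
  fermentation is the relative loss.

The compound constants F1–F4 come from published calibrations whose unit
convention for F3/F4 is not fixed here; `R` (default 8.314) and `T_ref`
are configuration fields so that any published parameter set can be
matched exactly. `Q` and `E` are linearly interpolated onto each
compound's gas grid when the channels are sampled on different grids.

## Stoichiometry

Ethanol and consumed sugar are tied to cumulative CO₂ by hexose
fermentation stoichiometry (1 glucose → 2 CO₂ + 2 ethanol):
`sugar = co2 × 180/88`, `ethanol = co2 × 92/88` (g/g). Both factors are
configurable; consumed sugar is clipped at the initial sugar content. The
consumed-sugar axis, not clock time, is the standard x-axis for
cross-condition comparison of kinetic criteria, because it normalises out
differences in overall fermentation speed.

## Parametric kinetics (four-parameter Weibull)

Biomass growth is fitted with the ascending form
`f(x) = c + (d−c)[1 − exp(−exp(b(ln x − ln e)))]` and nitrogen-source
consumption with the descending form
`f(x) = c + (d−c)·exp(−exp(b(ln x − ln e)))`. Parameters: `c` lower
plateau, `d` upper plateau, `e` the curve's location (reported as the
inflection point), `b` the shape. Fitting is ordinary least squares
(`scipy.optimize.curve_fit`) with bounds, initialised from the data
(`d = max y`, `c = min y`, `e` at the half-range crossing, `b` from a
log–log linearisation of the inner double exponential) and up to five
restarts with jittered `e`; the convergence flag is reported honestly and
a non-converged fit still returns its best parameters.

Extracted criteria:

- `µmax = max_t f′(t)/f(t)` (h⁻¹), maximised on the observed window
  refined 10× — the ratio diverges as t → 0 when c → 0, so the window is
  never extended below the first observation.
- maximum biomass = the fitted plateau `d` (10⁶ cells/mL).
- the inflection point, reported at `x = e` and re-expressed in consumed
  sugar. (For the ascending form the true inflection of f is not exactly
  at `e` in general; `e` is reported as the curve's conventional location
  parameter.)
- `Point.AA0`, the consumed-sugar coordinate at which a nitrogen source is
  exhausted: smallest x with `f(x) ≤ c + θ(d−c)`, closed form
  `e·ln(1/θ)^(1/b)`, default θ = 0.01. "Null" is necessarily a threshold
  decision because the fitted floor c can be positive; when c exceeds θ·d
  in absolute terms the source is reported "not exhausted" (NaN) rather
  than a fabricated crossing.

## Nonparametric production modelling

Volatile total-production curves get no parametric form. Each P(t) is
smoothed by a degree-2 local polynomial with tricube weights; the
bandwidth (span fraction of the data) is selected by leave-one-out
cross-validation over the grid {0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.7} using
the closed-form LOO residual of linear smoothers, with a minimum span of
0.1 to prevent collapse to interpolation. The production rate is the
linear coefficient of the local polynomial — no finite differencing of
noisy data. The specific rate divides that rate by the population taken
from the *fitted* biomass Weibull (not raw counts); with biomass in
10⁶ cells/mL (≡ 10⁹ cells/L), `q = rate / biomass` carries units
mg/(10⁹ cells·h), which is stated in output headers because no standard
convention exists. Criteria: `Max` (maximal smoothed P), maximal rate
(max dP/dt), `SRmax` (max q) and `PointSRmax` (consumed sugar at the
argmax of q). Argmax ties break to the earliest grid point (observation
grid refined 10×) and maxima on the window boundary are flagged.

## Bioconversion yields

Plotting ester total production against its precursor alcohol's total
production removes time from the problem; within a metabolic phase the
trajectory is linear and its slope is the conversion yield (mg ester per
mg alcohol). The fit is *continuous* piecewise-linear
(`y = a + s₁x + Σ gⱼ(x − bⱼ)₊`): the trajectories are continuous by
construction, though an `independent` flag fits disconnected segments for
sensitivity checks. The phase count (1..max_phases, default 4) is selected
by BIC = n·ln(RSS/n) + 2k·ln(n); breakpoints are located by exhaustive
search over a ≤24-point quantile grid, refined by Nelder–Mead, with at
least 10 points per phase. The RSS is floored at numerical-noise scale
(10⁻⁷ of the data scale, RMS) so that exactly-linear data select the most
parsimonious model; ties break toward fewer phases. Per-phase R² is
computed against that phase's own mean.

Trajectory construction interpolates the ester channel onto the alcohol's
time grid over the overlapping range, trims the trailing plateau (once
alcohol production stops, dx ≈ 0 and any y-noise masquerades as a steep
phase) and keeps a strictly increasing alcohol axis. With `smooth="auto"`
the alcohol (x) channel is denoised by local regression when it is not
already monotone; the ester channel is left raw so its errors stay
independent — BIC assumes independent residuals, and smoothing y was
observed to induce spurious phase detections through correlated
residuals.

## Strain comparison

For each compound, per-condition ratios of evolved/ancestral final liquid
concentrations are summarised by their median with a percentile bootstrap
CI (default 95 %, 10 000 resamples, fixed seed) taken across conditions
(the design points, not replicates). A compound is overproduced when the
whole interval exceeds 1. Conditions with a zero ancestral final are
excluded with a warning — their ratio is undefined, and silently treating
it as 0 or ∞ would corrupt the median. The percentile bootstrap was chosen
because it is distribution-free and matches the "is 1 inside the
interval?" decision rule; level and replicate count are configurable.

## Synthetic-data generator

The generator emulates the measurement channels of an online-GC monitored
fermentation with fully known truth:

- CO₂: a logistic cumulative curve tied to sugar exhaustion (98 % of
  initial sugar fermented by default), emitted with its analytic rate so
  the (cumulative, rate) pair is derivative-consistent. Sugar and ethanol
  follow by stoichiometry.
- Biomass: ascending Weibull in time; default (b, c, d, e) =
  (2.5, 1.0, 150, 25) — 10⁶ cells/mL inoculum rising to 1.5×10⁸ cells/mL
  with inflection near 25 h.
- Nitrogen sources: descending Weibull in consumed sugar (default valine
  (3, 0, 100, 40) and ammonium (2.5, 0, 120, 30) mg/L).
- Volatiles: a smooth true total-production curve P_true(t) per compound —
  ascending Weibull, or, for esters, a continuous piecewise-linear
  bioconversion of the parent alcohol's P_true with known slopes. P_true
  is split into liquid and gas components by integrating
  `dL/dt = k_i·Q·(P_true − L)` with an implicit-trapezoid recursion **on
  the gas sampling grid**, i.e. the same quadrature the balance stage
  applies. The noiseless round trip is therefore exact by construction,
  which makes the balance tests sharp: any discrepancy is a defect, not
  discretisation slack.
- Noise: multiplicative Gaussian, `truth × (1 + ε)`, `ε ~ N(0, cv)`,
  truncated at zero, independent across time points. Default CVs mirror
  the instrument's duplicate reproducibility (3–5 % depending on
  compound; biomass 0.03, nitrogen sources 0.04). Channels the instrument
  computes rather than measures (CO₂, ethanol, sugar) are left noiseless.
- Sampling: gas channels hourly per compound (the real GC cycles through
  compounds; the exact period is configurable), kinetic channels every
  0.25 h, default duration 120 h.

Everything is deterministic given the scenario seed, down to the emitted
bytes. The truth block (all generating parameters) round-trips through a
JSON sidecar.

What the generator does **not** emulate: gas–liquid feedback (real
evaporation depletes the liquid; here C_liq_true is defined first and gas
values derived, which matches the analysis equations but is not a
transport model), GC cycle staggering across compounds, drift or
autocorrelated instrument error, temperature excursions, and stuck or
sluggish fermentations. Passing tests therefore demonstrate correctness
of the analysis under the stated error model, not robustness to every
failure mode of real monitoring data.

## Problem sizes and statistical checks

Recovery checks simulate at the documented noise levels and compare
against generating truth: conversion trajectories use 300 points over
0–160 mg/L alcohol with noise CV 2 % and 100 replicates; Weibull recovery
uses the generator's kinetic grid. The growth curve's lower plateau c is a
genuinely high-variance least-squares estimate (its asymptotic sd is
~20 % of its value at CV 3 % — verified against the Fisher covariance), so
its bias is averaged over 1000 replicates to keep the Monte-Carlo error of
the mean well below the reported magnitude; the other parameters resolve
to <0.1 %. Bootstrap coverage is assessed on lognormal ratios
(median 1.5, σ = 0.1, 16 conditions) over 100 replicates of 1000
resamples.

## Known limitations

- F1–F4 partition constants are not bundled for real compounds; users
  supply their own calibration CSV. All shipped values are synthetic.
- The segmented fit's exhaustive breakpoint grid caps at 24 candidates
  before refinement; extremely short phases (<10 points) are not
  searched.
- `µmax` depends on the fitted c: cultures with c fitted near 0 have
  formally unbounded f′/f as t → 0, which is why the maximisation window
  never extends below the data.
- The local-regression bandwidth grid is fixed; pathological sampling
  densities may need a custom `span_grid`.
- BIC phase selection assumes independent errors along the trajectory;
  strongly autocorrelated residuals (e.g. smoothed y-channels) inflate
  the detected phase count.
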