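# aromaflux

Quantitative analysis of volatile aroma production in wine-yeast
fermentations monitored by **online gas chromatography**, plus a synthetic
fermentation generator with known ground truth.

During alcoholic fermentation, yeast synthesises higher alcohols (propanol,
isobutanol, isoamyl alcohol), acetate esters (e.g. isoamyl acetate) and
ethyl esters. A fraction of each compound is stripped out of the must by the
CO₂ flow, so the concentration measured in the liquid underestimates what
the cells actually produced. `aromaflux` reconstructs the yeast's true
synthesis capacity from exhaust-gas measurements and models the kinetics of
growth, nitrogen consumption and aroma production:

* **Gas–liquid balance.** The liquid concentration is recovered from the
  gas-phase signal through a partition coefficient
  `ln kᵢ = F1 + F2·E − ((F3 + F4·E)/R)·(1000/T − 1000/T_ref)`
  (E = ethanol g/L, T = temperature in K); cumulative gaseous losses are
  `L(t) = ∫ C_gas·Q dt` (trapezoidal rule), total production is
  `P(t) = C_liq(t) + L(t)` and the relative loss is `RL = L/P` at the end
  of fermentation.
* **Weibull kinetics.** Biomass follows the ascending four-parameter
  Weibull `f(x) = c + (d−c)[1 − exp(−exp(b(ln x − ln e)))]`; nitrogen
  sources follow the descending form. Extracted criteria: µmax
  (max of f′/f, h⁻¹), inflection point and maximum biomass; maximal
  consumption rate and **Point.AA0**, the consumed-sugar coordinate at
  which a nitrogen source is exhausted (closed form
  `e·ln(1/θ)^(1/b)` for threshold fraction θ).
* **Nonparametric production modelling.** Each compound's P(t) is smoothed
  by degree-2 local regression (bandwidth by leave-one-out CV); dividing
  the rate by the fitted population gives the specific rate, summarised as
  **Max**, **SRmax** and **PointSRmax** (in consumed sugar, g/L).
* **Bioconversion yields.** Ester total production is regressed on its
  precursor alcohol's total production as a continuous piecewise-linear
  curve; the number of phases is selected by BIC and each phase's slope is
  the conversion yield (mg ester per mg alcohol).
* **Strain comparison.** Evolved/ancestral final-concentration ratios per
  condition, with percentile-bootstrap confidence intervals; a compound is
  called overproduced when the interval lies entirely above 1.

## Worked example

```python
import pandas as pd
import aromaflux as af

# a complete synthetic fermentation (200 g/L sugar, 330 mg N/L, 24 °C)
scenario = af.default_scenario(seed=1)
ds = af.simulate_fermentation(scenario)

co2 = pd.DataFrame({"time_h": ds.time, "co2_cum": ds.co2_cumulative,
                    "co2_rate": ds.co2_rate})
params = pd.DataFrame([{"compound": c, "F1": p.F1, "F2": p.F2,
                        "F3": p.F3, "F4": p.F4}
                       for c, p in scenario.partition_params.items()])
balances = af.run_balance(ds.gas_traces[["compound", "time_h", "C_gas"]],
                          params, co2)
b = balances["isoamyl acetate"]
print(f"total production {b.P[-1]:.2f} mg/L, "
      f"relative loss {100 * b.relative_loss:.1f} %")

traj = af.build_trajectory(balances["isoamyl alcohol"],
                           balances["isoamyl acetate"], smooth="auto")
res = af.segmented_yield_fit(traj)
print(f"{res.n_phases} phase(s), yield {res.yields[0]:.4f} mg/mg")
```

prints

```
total production 3.88 mg/L, relative loss 24.5 %
1 phase(s), yield 0.0236 mg/mg
```

About a quarter of the acetate ester is lost to the exhaust gas — the
liquid concentration alone would miss much of what the yeast synthesised.
The conversion trajectory is a single linear phase whose slope, 0.0236 mg
ester per mg alcohol, recovers the generating yield of 0.0241 within ~2 %
despite 4–5 % measurement noise.

The same stages are available from the shell:

```bash
aromaflux simulate --seed 1 --out data/
aromaflux run --timeseries data/timeseries.csv --params partition.csv \
    --pair "isoamyl alcohol:isoamyl acetate" --out results/
aromaflux compare --finals finals.csv --out ratios.csv
```

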