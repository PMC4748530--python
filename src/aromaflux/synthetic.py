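"""Synthetic wine-fermentation generator with known ground truth.

Emulates the measurement channels of an online-GC monitored fermentation:

* CO2 release — a logistic cumulative curve tied to sugar exhaustion,
  emitted together with its analytic rate (derivative-consistent pair);
* consumed sugar and ethanol — stoichiometric transforms of cumulative CO2
  (hexose fermentation: 1 glucose -> 2 CO2 + 2 ethanol, i.e. 180/88 g sugar
  and 92/88 g ethanol per g CO2);
* biomass — ascending four-parameter Weibull in time;
* nitrogen sources — descending Weibull in consumed sugar;
* volatile compounds — a smooth true total-production curve P_true(t)
  (ascending Weibull, or a piecewise-linear bioconversion of a parent
  alcohol for esters), split into liquid and gas-loss components that are
  exactly consistent with the gas-liquid balance equations: the cumulative
  loss obeys the same trapezoidal quadrature of C_gas*Q the balance stage
  uses, and C_gas = k_i(E, T) * C_liq at every sample.

Noise is multiplicative Gaussian, truth * (1 + eps) with eps ~ N(0, cv),
truncated at zero, independent across time points; default CVs mirror the
3-5 % duplicate relative SD of the monitoring system. Channels that the
instrument computes rather than measures (CO2, ethanol, sugar) are left
noiseless. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .balance import PartitionParams, partition_coefficient
from .curves import weibull_ascending, weibull_descending

SUGAR_PER_CO2 = 180.0 / 88.0
ETHANOL_PER_CO2 = 92.0 / 88.0
L_CO2_PER_G = 22.414 / 44.0  # ideal-gas volume of 1 g CO2 at 0 C


@dataclass
class ConversionPhases:
    """Piecewise-linear ester formation from a parent higher alcohol.

    ``yields`` has one slope per phase (mg ester per mg alcohol);
    ``breakpoints`` are the phase boundaries on the alcohol total-production
    axis (mg/L), strictly increasing, one fewer than the yields.
    """

    alcohol: str
    yields: list[float]
    breakpoints: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.yields) != len(self.breakpoints) + 1:
            raise ValueError("need len(yields) == len(breakpoints) + 1")
        if any(y <= 0 for y in self.yields):
            raise ValueError("conversion yields must be positive")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    def ester_production(self, alcohol_P: np.ndarray) -> np.ndarray:
        """Continuous piecewise-linear map starting at (0, 0)."""
        x = np.asarray(alcohol_P, dtype=float)
        y_at = [0.0]  # ordinate at each breakpoint, accumulated slope * width
        for i, b in enumerate(self.breakpoints):
            prev = 0.0 if i == 0 else self.breakpoints[i - 1]
            y_at.append(y_at[-1] + self.yields[i] * (b - prev))
        out = np.empty_like(x)
        for j, xv in enumerate(x):
            i = int(np.searchsorted(self.breakpoints, xv, side="right"))
            x0 = 0.0 if i == 0 else self.breakpoints[i - 1]
            out[j] = y_at[i] + self.yields[i] * (xv - x0)
        return out


@dataclass
class FermentationScenario:
    """Generating parameters for one synthetic fermentation."""

    strain_label: str = "ancestral"
    initial_sugar: float = 200.0  # g/L
    initial_nitrogen: float = 330.0  # mg N/L
    phytosterol: float = 8.0  # mg/L
    temperature_K: float = 297.15  # 24 C, constant by default
    duration_h: float = 120.0
    co2_midpoint_h: float = 40.0
    co2_rate_const: float = 0.09  # 1/h, logistic steepness
    co2_fraction_fermented: float = 0.98  # fraction of sugar consumed at t_end
    biomass_params: tuple[float, float, float, float] = (2.5, 1.0, 150.0, 25.0)
    aa_params: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    compound_production_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    partition_params: dict[str, PartitionParams] = field(default_factory=dict)
    conversion_phases: dict[str, ConversionPhases] = field(default_factory=dict)
    noise_cv: float | dict[str, float] = 0.0
    sampling_interval: float = 1.0  # h, online-GC cycle per compound
    kinetic_interval: float = 0.25  # h, CO2/biomass channels
    seed: int = 0

    def __post_init__(self):
        if self.initial_sugar <= 0:
            raise ValueError("initial_sugar must be positive")
        if self.sampling_interval <= 0 or self.kinetic_interval <= 0:
            raise ValueError("sampling intervals must be positive")
        cvs = self.noise_cv.values() if isinstance(self.noise_cv, dict) else [self.noise_cv]
        if any(cv < 0 for cv in cvs):
            raise ValueError("noise_cv must be nonnegative")
        b, c, d, e = self.biomass_params
        if not (d > c and e > 0):
            raise ValueError("biomass Weibull requires d > c and e > 0")
        for name, (b, c, d, e) in self.aa_params.items():
            if not (d > c >= 0 and e > 0):
                raise ValueError(f"aa {name!r}: descending Weibull requires d > c >= 0")
        for name in self.conversion_phases:
            parent = self.conversion_phases[name].alcohol
            if parent not in self.compound_production_params:
                raise ValueError(f"ester {name!r} references unknown alcohol {parent!r}")

    def cv_for(self, channel: str) -> float:
        if isinstance(self.noise_cv, dict):
            return float(self.noise_cv.get(channel, self.noise_cv.get("default", 0.0)))
        return float(self.noise_cv)


@dataclass
class SyntheticDataset:
    """Generated channels plus the embedded ground truth."""

    time: np.ndarray  # kinetic grid, h
    co2_cumulative: np.ndarray  # g/L
    co2_rate: np.ndarray  # L CO2/L must/h
    ethanol: np.ndarray  # g/L
    consumed_sugar: np.ndarray  # g/L
    biomass: np.ndarray  # 1e6 cells/mL, noisy
    biomass_true: np.ndarray
    temperature: np.ndarray  # K
    aa_concentrations: pd.DataFrame  # long: aa, time_h, value (noisy), true
    gas_traces: pd.DataFrame  # long: compound, time_h, C_gas (noisy), Q, E, T
    liquid_truth: pd.DataFrame  # long: compound, time_h, C_liq, L, P (noiseless)
    truth: FermentationScenario


def _co2_curve(scn: FermentationScenario, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative CO2 (g/L) and its rate (L CO2/L/h), logistic, zero at t=0."""
    co2_max = scn.initial_sugar * scn.co2_fraction_fermented / SUGAR_PER_CO2
    r, tm = scn.co2_rate_const, scn.co2_midpoint_h
    sig = 1.0 / (1.0 + np.exp(-r * (t - tm)))
    s_end = 1.0 / (1.0 + np.exp(-r * (scn.duration_h - tm)))
    s0 = 1.0 / (1.0 + np.exp(r * tm))
    amp = co2_max / (s_end - s0)
    cum = amp * (sig - s0)
    rate_g = amp * r * sig * (1.0 - sig)
    return cum, rate_g * L_CO2_PER_G


def _production_truth(scn: FermentationScenario, t: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for name, (b, c, d, e) in scn.compound_production_params.items():
        p = weibull_ascending(t, b, c, d, e)
        if not np.all(np.isfinite(p)):
            raise ValueError(f"non-finite production curve for {name!r}")
        out[name] = p
    for name, conv in scn.conversion_phases.items():
        out[name] = conv.ester_production(out[conv.alcohol])
    return out


def _split_gas_liquid(
    P: np.ndarray, k: np.ndarray, Q: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split P into (C_liq, L) so that L equals the trapezoidal quadrature of
    k*C_liq*Q on this grid (implicit-trapezoid recursion)."""
    n = t.size
    L = np.zeros(n)
    g = k * Q
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        num = L[i] + 0.5 * dt * (g[i] * (P[i] - L[i]) + g[i + 1] * P[i + 1])
        L[i + 1] = num / (1.0 + 0.5 * dt * g[i + 1])
    return P - L, L


def simulate_fermentation(scenario: FermentationScenario) -> SyntheticDataset:
    """Generate a complete synthetic dataset; deterministic for a fixed seed."""
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    t = np.arange(0.0, scn.duration_h + 1e-9, scn.kinetic_interval)
    co2, q = _co2_curve(scn, t)
    sugar = np.minimum(co2 * SUGAR_PER_CO2, scn.initial_sugar)
    ethanol = co2 * ETHANOL_PER_CO2
    b, c, d, e = scn.biomass_params
    biomass_true = weibull_ascending(t, b, c, d, e)
    if not np.all(np.isfinite(biomass_true)):
        raise ValueError("biomass Weibull produces non-finite values on the grid")
    biomass = _noisy(biomass_true, scn.cv_for("biomass"), rng)
    temp = np.full_like(t, scn.temperature_K)

    aa_rows = []
    for name, (ab, ac, ad, ae) in scn.aa_params.items():
        true = weibull_descending(sugar, ab, ac, ad, ae)
        noisy = _noisy(true, scn.cv_for(f"aa:{name}") or scn.cv_for("aa") or scn.cv_for(name), rng)
        aa_rows.append(
            pd.DataFrame({"aa": name, "time_h": t, "value": noisy, "true": true})
        )
    aa_frame = (
        pd.concat(aa_rows, ignore_index=True)
        if aa_rows
        else pd.DataFrame(columns=["aa", "time_h", "value", "true"])
    )

    # gas channels on their own (coarser) grid
    tg = np.arange(0.0, scn.duration_h + 1e-9, scn.sampling_interval)
    co2_g, q_g = _co2_curve(scn, tg)
    eth_g = co2_g * ETHANOL_PER_CO2
    temp_g = np.full_like(tg, scn.temperature_K)
    prod = _production_truth(scn, tg)
    gas_rows, liq_rows = [], []
    for name, P in prod.items():
        if name not in scn.partition_params:
            raise ValueError(f"no partition parameters for compound {name!r}")
        k = partition_coefficient(eth_g, temp_g, scn.partition_params[name])
        c_liq, loss = _split_gas_liquid(P, k, q_g, tg)
        c_gas_true = k * c_liq
        c_gas = _noisy(c_gas_true, scn.cv_for(name), rng)
        gas_rows.append(
            pd.DataFrame(
                {"compound": name, "time_h": tg, "C_gas": c_gas,
                 "Q": q_g, "E": eth_g, "T": temp_g}
            )
        )
        liq_rows.append(
            pd.DataFrame(
                {"compound": name, "time_h": tg, "C_liq": c_liq, "L": loss, "P": P}
            )
        )
    gas_frame = (
        pd.concat(gas_rows, ignore_index=True)
        if gas_rows
        else pd.DataFrame(columns=["compound", "time_h", "C_gas", "Q", "E", "T"])
    )
    liq_frame = (
        pd.concat(liq_rows, ignore_index=True)
        if liq_rows
        else pd.DataFrame(columns=["compound", "time_h", "C_liq", "L", "P"])
    )

    return SyntheticDataset(
        time=t,
        co2_cumulative=co2,
        co2_rate=q,
        ethanol=ethanol,
        consumed_sugar=sugar,
        biomass=biomass,
        biomass_true=biomass_true,
        temperature=temp,
        aa_concentrations=aa_frame,
        gas_traces=gas_frame,
        liquid_truth=liq_frame,
        truth=scn,
    )


def _noisy(true: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return true.copy()
    return np.maximum(true * (1.0 + rng.normal(0.0, cv, size=true.shape)), 0.0)


# ---------------------------------------------------------------------------
# presets and serialisation


def default_partition(compound: str, F1: float = -5.0, F2: float = 0.004,
                      F3: float = 5.0, F4: float = 0.02) -> PartitionParams:
    return PartitionParams(compound=compound, F1=F1, F2=F2, F3=F3, F4=F4)


def default_scenario(seed: int = 0, noise: bool = True) -> FermentationScenario:
    """Reference scenario: 200 g/L sugar, high-nitrogen must (330 mg N/L),
    8 mg/L phytosterols, 24 C, one higher alcohol with its acetate ester,
    valine and ammonium as nitrogen sources. Noise CVs follow the 3-5 %
    duplicate reproducibility of the monitoring system."""
    cv = (
        {"biomass": 0.03, "aa": 0.04, "isoamyl alcohol": 0.04, "isoamyl acetate": 0.05}
        if noise
        else 0.0
    )
    return FermentationScenario(
        strain_label="ancestral",
        initial_sugar=200.0,
        initial_nitrogen=330.0,
        phytosterol=8.0,
        aa_params={
            "valine": (3.0, 0.0, 100.0, 40.0),
            "ammonium": (2.5, 0.0, 120.0, 30.0),
        },
        compound_production_params={"isoamyl alcohol": (3.5, 0.0, 150.0, 50.0)},
        partition_params={
            "isoamyl alcohol": default_partition("isoamyl alcohol", F1=-6.0),
            "isoamyl acetate": default_partition("isoamyl acetate", F1=-4.5),
        },
        conversion_phases={
            "isoamyl acetate": ConversionPhases(
                alcohol="isoamyl alcohol", yields=[0.0241]
            )
        },
        noise_cv=cv,
        seed=seed,
    )


def scenario_to_dict(scn: FermentationScenario) -> dict:
    d = asdict(scn)
    d["partition_params"] = {k: asdict(v) for k, v in scn.partition_params.items()}
    d["conversion_phases"] = {k: asdict(v) for k, v in scn.conversion_phases.items()}
    return d


def scenario_from_dict(d: dict) -> FermentationScenario:
    d = dict(d)
    d["partition_params"] = {
        k: PartitionParams(**v) for k, v in d.get("partition_params", {}).items()
    }
    d["conversion_phases"] = {
        k: ConversionPhases(**v) for k, v in d.get("conversion_phases", {}).items()
    }
    d["aa_params"] = {k: tuple(v) for k, v in d.get("aa_params", {}).items()}
    d["compound_production_params"] = {
        k: tuple(v) for k, v in d.get("compound_production_params", {}).items()
    }
    d["biomass_params"] = tuple(d["biomass_params"])
    return FermentationScenario(**d)


def write_dataset(dataset: SyntheticDataset, path: str | Path) -> dict[str, Path]:
    """Write the dataset as tidy CSV files plus a JSON truth sidecar.

    Emits ``timeseries.csv`` (kinetic + nitrogen channels in long form),
    ``gas.csv`` (per-compound GC traces with co-channels),
    ``liquid_truth.csv`` and ``truth.json``. Numeric payloads round-trip
    exactly (full float repr).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    from .io import write_timeseries  # local import to avoid a cycle

    ts = dataset_to_tidy(dataset)
    files = {
        "timeseries": path / "timeseries.csv",
        "gas": path / "gas.csv",
        "liquid_truth": path / "liquid_truth.csv",
        "truth": path / "truth.json",
    }
    write_timeseries(ts, files["timeseries"])
    dataset.gas_traces.to_csv(files["gas"], index=False)
    dataset.liquid_truth.to_csv(files["liquid_truth"], index=False)
    files["truth"].write_text(json.dumps(scenario_to_dict(dataset.truth), indent=1))
    return files


def dataset_to_tidy(dataset: SyntheticDataset) -> pd.DataFrame:
    """Long (time_h, channel, value, unit) view of the kinetic channels."""
    blocks = [
        ("co2_cum", dataset.time, dataset.co2_cumulative, "g/L"),
        ("co2_rate", dataset.time, dataset.co2_rate, "L/L/h"),
        ("ethanol", dataset.time, dataset.ethanol, "g/L"),
        ("consumed_sugar", dataset.time, dataset.consumed_sugar, "g/L"),
        ("biomass", dataset.time, dataset.biomass, "1e6 cells/mL"),
        ("temperature", dataset.time, dataset.temperature, "K"),
    ]
    frames = [
        pd.DataFrame({"time_h": t, "channel": name, "value": v, "unit": unit})
        for name, t, v, unit in blocks
    ]
    for aa, sub in dataset.aa_concentrations.groupby("aa", sort=False):
        frames.append(
            pd.DataFrame(
                {"time_h": sub["time_h"], "channel": f"aa:{aa}",
                 "value": sub["value"], "unit": "mg/L"}
            )
        )
    for comp, sub in dataset.gas_traces.groupby("compound", sort=False):
        frames.append(
            pd.DataFrame(
                {"time_h": sub["time_h"], "channel": f"gas:{comp}",
                 "value": sub["C_gas"], "unit": "mg/L CO2"}
            )
        )
    return pd.concat(frames, ignore_index=True)


def read_truth(path: str | Path) -> FermentationScenario:
    return scenario_from_dict(json.loads(Path(path).read_text()))
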