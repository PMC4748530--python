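"""Gas-liquid mass balance of volatile compounds during fermentation.

An online GC measures each compound's concentration in the exhaust gas,
C_gas(t), in mg per litre of CO2. The balance converts that signal into

* the liquid-phase concentration C_liq(t) = C_gas(t) / k_i, using a
  partition coefficient k_i that depends on ethanol content and temperature,
* the cumulative gaseous loss L(t) = integral of C_gas * Q dt (Q = CO2 flow
  rate, L CO2 / L must / h), evaluated by the trapezoidal rule on the
  observed sampling grid,
* the total production P(t) = C_liq(t) + L(t), the yeast's synthesis
  capacity independent of evaporation, and
* the relative loss RL = L(t_end) / P(t_end).

The partition model is
    ln k_i = F1 + F2*E - ((F3 + F4*E)/R) * (1000/T - 1000/T_ref)
with E the ethanol concentration (g/L), T the absolute temperature, T_ref a
reference temperature (293.15 K by default) and F1..F4 compound-specific
constants. R defaults to 8.314; because published F3/F4 sets differ in unit
convention, R is a configurable field so any parameter table can be matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_DEFAULT = 8.314
T_REF_DEFAULT = 293.15


@dataclass(frozen=True)
class PartitionParams:
    """Constants of the ln k_i partition model for one compound."""

    compound: str
    F1: float
    F2: float
    F3: float
    F4: float
    R: float = R_DEFAULT
    T_ref: float = T_REF_DEFAULT

    def __post_init__(self):
        if not (self.T_ref > 0 and self.R > 0):
            raise ValueError("R and T_ref must be positive")


@dataclass
class GasTrace:
    """Online-GC trace of one compound with the co-channels the balance needs.

    time in h (strictly increasing), C_gas in mg/L CO2, Q in L CO2/L must/h,
    E in g/L ethanol, T in K. Scalar E or T are broadcast.
    """

    compound: str
    time: np.ndarray
    C_gas: np.ndarray
    Q: np.ndarray
    E: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing without duplicates")
        for name in ("C_gas", "Q", "E", "T"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim == 0:
                v = np.full(n, float(v))
            if v.size != n:
                raise ValueError(f"{name} length {v.size} != time length {n}")
            setattr(self, name, v)
        if np.any(self.T <= 0):
            raise ValueError("temperature must be positive (K)")


@dataclass
class VolatileBalance:
    """Per-compound output of the balance: k_i, C_liq, L, P on the trace grid."""

    compound: str
    time: np.ndarray
    k_i: np.ndarray
    C_gas: np.ndarray
    C_liq: np.ndarray
    L: np.ndarray
    P: np.ndarray

    @property
    def relative_loss(self) -> float:
        return relative_loss(float(self.L[-1]), float(self.C_liq[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.compound,
                "time_h": self.time,
                "k_i": self.k_i,
                "C_gas": self.C_gas,
                "C_liq": self.C_liq,
                "L": self.L,
                "P": self.P,
            }
        )


def partition_coefficient(E, T, params: PartitionParams):
    """Gas/liquid partition coefficient k_i(E, T); strictly positive.

    E in g/L ethanol, T in K. Vectorised over E and T.
    """
    E = np.asarray(E, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(T))):
        raise ValueError("non-finite ethanol or temperature input")
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (K)")
    lnk = params.F1 + params.F2 * E - ((params.F3 + params.F4 * E) / params.R) * (
        1000.0 / T - 1000.0 / params.T_ref
    )
    return np.exp(lnk)


def liquid_concentration(C_gas, k_i):
    """C_liq = C_gas / k_i (mg/L must). Requires k_i > 0."""
    C_gas = np.asarray(C_gas, dtype=float)
    k_i = np.asarray(k_i, dtype=float)
    if np.any(k_i <= 0):
        raise ValueError("partition coefficient must be positive")
    return C_gas / k_i


def gas_losses(trace: GasTrace) -> np.ndarray:
    """Cumulative loss L(t) = trapz of C_gas*Q over time; L(0) = 0.

    Exact whenever C_gas*Q is piecewise linear on the grid.
    """
    if trace.time.size < 2:
        raise ValueError("need at least two time points to integrate")
    integrand = trace.C_gas * trace.Q
    dt = np.diff(trace.time)
    increments = 0.5 * (integrand[:-1] + integrand[1:]) * dt
    return np.concatenate([[0.0], np.cumsum(increments)])


def total_production(C_liq, L):
    """P = C_liq + L, pointwise on a shared grid."""
    C_liq = np.asarray(C_liq, dtype=float)
    L = np.asarray(L, dtype=float)
    if C_liq.shape != L.shape:
        raise ValueError("C_liq and L are on different grids")
    return C_liq + L


def relative_loss(L_end: float, C_liq_end: float) -> float:
    """RL = L / (C_liq + L) at fermentation end, a fraction in [0, 1]."""
    denom = C_liq_end + L_end
    if denom == 0:
        raise ZeroDivisionError("relative loss undefined: no production at t_end")
    return L_end / denom


def balance_trace(trace: GasTrace, params: PartitionParams) -> VolatileBalance:
    """Run the full balance for a single compound trace."""
    k = partition_coefficient(trace.E, trace.T, params)
    c_liq = liquid_concentration(trace.C_gas, k)
    loss = gas_losses(trace)
    prod = total_production(c_liq, loss)
    return VolatileBalance(
        compound=trace.compound,
        time=trace.time,
        k_i=k,
        C_gas=trace.C_gas.copy(),
        C_liq=c_liq,
        L=loss,
        P=prod,
    )


def run_balance(
    gas: pd.DataFrame,
    partition_table: dict[str, PartitionParams] | pd.DataFrame,
    co2: pd.DataFrame,
    ethanol_factor: float = 92.0 / 88.0,
    temperature: float | pd.DataFrame = 297.15,
) -> dict[str, VolatileBalance]:
    """Balance every compound in a long gas table.

    Parameters
    ----------
    gas
        Long table with columns ``compound, time_h, C_gas``.
    partition_table
        Mapping compound -> PartitionParams, or a DataFrame with columns
        ``compound, F1, F2, F3, F4`` (optional ``R``, ``T_ref``).
    co2
        Table with columns ``time_h, co2_cum`` (g/L) and optionally
        ``co2_rate`` (L CO2/L/h). Ethanol is derived from co2_cum by
        ``ethanol_factor`` unless an ``ethanol`` column is present; the rate,
        if absent, is obtained by finite differences of co2_cum converted to
        gas volume (22.414/44 L per g CO2).
    temperature
        Constant K, or DataFrame with columns ``time_h, temperature``.

    Q, E and T are linearly interpolated onto each compound's gas grid.
    """
    params = _coerce_partition_table(partition_table)
    t_co2 = co2["time_h"].to_numpy(dtype=float)
    co2_cum = co2["co2_cum"].to_numpy(dtype=float)
    if "co2_rate" in co2.columns:
        q_co2 = co2["co2_rate"].to_numpy(dtype=float)
    else:
        q_co2 = np.gradient(co2_cum, t_co2) * (22.414 / 44.0)
    if "ethanol" in co2.columns:
        eth = co2["ethanol"].to_numpy(dtype=float)
    else:
        eth = co2_cum * ethanol_factor

    out: dict[str, VolatileBalance] = {}
    for compound, sub in gas.groupby("compound", sort=False):
        if compound not in params:
            raise KeyError(f"no partition parameters for compound {compound!r}")
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy(dtype=float)
        q = np.interp(t, t_co2, q_co2)
        e = np.interp(t, t_co2, eth)
        if isinstance(temperature, pd.DataFrame):
            temp = np.interp(
                t,
                temperature["time_h"].to_numpy(dtype=float),
                temperature["temperature"].to_numpy(dtype=float),
            )
        else:
            temp = np.full_like(t, float(temperature))
        trace = GasTrace(
            compound=str(compound),
            time=t,
            C_gas=sub["C_gas"].to_numpy(dtype=float),
            Q=q,
            E=e,
            T=temp,
        )
        out[str(compound)] = balance_trace(trace, params[compound])
    return out


def _coerce_partition_table(table) -> dict[str, PartitionParams]:
    if isinstance(table, dict):
        return table
    records = {}
    for _, row in table.iterrows():
        name = str(row["compound"])
        if name in records:
            raise ValueError(f"duplicate partition parameters for {name!r}")
        records[name] = PartitionParams(
            compound=name,
            F1=float(row["F1"]),
            F2=float(row["F2"]),
            F3=float(row["F3"]),
            F4=float(row["F4"]),
            R=float(row["R"]) if "R" in row and pd.notna(row.get("R")) else R_DEFAULT,
            T_ref=float(row["T_ref"]) if "T_ref" in row and pd.notna(row.get("T_ref")) else T_REF_DEFAULT,
        )
    return records


def balances_to_frame(balances: dict[str, VolatileBalance]) -> pd.DataFrame:
    """Stack per-compound balances into one long CSV-ready table."""
    return pd.concat([b.to_frame() for b in balances.values()], ignore_index=True)
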