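"""Kinetic modelling of fermentation channels and extraction of the
summary criteria used for strain/condition comparison.

Three channel families are modelled:

* biomass growth — ascending four-parameter Weibull in time; criteria are
  the maximum specific growth rate mu_max = max_t f'(t)/f(t) (1/h), the
  inflection point re-expressed in consumed sugar (g/L), and the maximum
  biomass (the fitted upper plateau d, in 1e6 cells/mL);
* nitrogen-source (amino acid / ammonium) consumption — descending Weibull
  in consumed sugar; criteria are the maximal consumption rate, the
  inflection point, and Point.AA0, the consumed-sugar coordinate at which
  the source is exhausted;
* volatile-compound total production — nonparametric local regression;
  criteria are the maximal production Max (mg/L), the maximal rate
  (mg/L/h), and the maximum specific rate SRmax with its consumed-sugar
  location PointSRmax.

Specific rates divide the production rate by the modelled population (the
fitted biomass Weibull, not raw counts). With biomass in 1e6 cells/mL
(= 1e9 cells/L), q = rate / biomass has units mg/(1e9 cells * h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .curves import (
    descending_threshold_crossing,
    weibull_ascending,
    weibull_ascending_deriv,
    weibull_descending,
    weibull_descending_deriv,
)
from .smoothing import SPAN_GRID_DEFAULT, LocalRegression, smooth_production

SUGAR_PER_CO2_DEFAULT = 180.0 / 88.0
AA0_THRESHOLD_DEFAULT = 0.01
GRID_REFINE = 10


@dataclass
class WeibullFit:
    """Least-squares Weibull fit (b, c, d, e) of one channel."""

    variant: str  # "ascending" | "descending"
    b: float
    c: float
    d: float
    e: float
    x_unit: str = ""
    residual_sd: float = float("nan")
    converged: bool = True

    def __call__(self, x) -> np.ndarray:
        f = weibull_ascending if self.variant == "ascending" else weibull_descending
        return f(x, self.b, self.c, self.d, self.e)

    def derivative(self, x) -> np.ndarray:
        f = (
            weibull_ascending_deriv
            if self.variant == "ascending"
            else weibull_descending_deriv
        )
        return f(x, self.b, self.c, self.d, self.e)


@dataclass
class BiomassCriteria:
    mu_max: float  # 1/h
    inflection_point: float  # g/L consumed sugar
    max_biomass: float  # 1e6 cells/mL


@dataclass
class AAConsumptionCriteria:
    maximal_rate: float  # magnitude of the steepest consumption
    inflection_point: float  # g/L consumed sugar
    point_aa0: float  # g/L consumed sugar; NaN when not exhausted
    exhausted: bool = True


@dataclass
class ProductionCriteria:
    compound: str
    max_production: float  # Max, mg/L
    max_rate: float  # mg/L/h
    srmax: float  # mg/(1e9 cells * h)
    point_srmax: float  # g/L consumed sugar
    inflection_point: float  # g/L consumed sugar
    at_boundary: bool = False


def sugar_axis_from_co2(co2_cumulative, factor: float = SUGAR_PER_CO2_DEFAULT,
                        initial_sugar: float | None = None) -> np.ndarray:
    """Consumed sugar (g/L) from cumulative CO2 (g/L).

    Hexose fermentation stoichiometry (1 glucose -> 2 CO2 + 2 ethanol)
    gives the default factor 180/88 g sugar per g CO2. Clipped to the
    initial sugar content when given.
    """
    co2 = np.asarray(co2_cumulative, dtype=float)
    if co2.size >= 2 and np.any(np.diff(co2) < -1e-9):
        raise ValueError("cumulative CO2 channel must be nondecreasing")
    sugar = factor * co2
    if initial_sugar is not None:
        sugar = np.minimum(sugar, initial_sugar)
    return sugar


def _initial_guess(x: np.ndarray, y: np.ndarray, variant: str) -> tuple[float, float, float, float]:
    c0 = float(np.min(y))
    d0 = float(np.max(y))
    if d0 <= c0:
        d0 = c0 + max(abs(c0), 1.0) * 1e-3
    half = c0 + 0.5 * (d0 - c0)
    yy = y if variant == "ascending" else y[::-1]
    xx = x if variant == "ascending" else x[::-1]
    cross = np.nonzero(yy >= half)[0]
    e0 = float(xx[cross[0]]) if cross.size else float(np.median(x))
    e0 = max(e0, float(np.min(x[x > 0], initial=1.0)))
    # shape from a log-log linearisation of the inner double-exponential
    z = np.clip((y - c0) / (d0 - c0), 1e-4, 1 - 1e-4)
    inner = -np.log(1.0 - z) if variant == "ascending" else -np.log(z)
    mask = (x > 0) & (inner > 1e-6)
    if mask.sum() >= 3:
        slope = np.polyfit(np.log(x[mask]), np.log(inner[mask]), 1)[0]
        b0 = float(np.clip(slope, 0.2, 20.0))
    else:
        b0 = 2.0
    return b0, c0, d0, e0


def _fit_weibull(x, y, variant: str, x_unit: str = "", n_restarts: int = 5) -> WeibullFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 6:
        raise ValueError("need at least 6 points to fit a four-parameter Weibull")
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    model = weibull_ascending if variant == "ascending" else weibull_descending
    b0, c0, d0, e0 = _initial_guess(x, y, variant)
    span = d0 - c0
    lo = [1e-3, c0 - 2 * span - 1.0, c0 - 1e-9, 1e-9]
    hi = [50.0, d0 + 1e-9, d0 + 2 * span + 1.0, float(np.max(x)) * 10.0]
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(n_restarts):
        e_try = e0 if attempt == 0 else float(e0 * rng.uniform(0.5, 1.8))
        p0 = [b0, c0, d0, np.clip(e_try, lo[3], hi[3])]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
                )
            rss = float(np.sum((model(x, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
            if rss <= max(1e-20, 1e-12 * float(np.sum(y**2))):
                break
        except (RuntimeError, ValueError):
            continue
    if best is None:
        # report the (non-converged) initial guess honestly
        return WeibullFit(variant, b0, c0, d0, e0, x_unit,
                          residual_sd=float("nan"), converged=False)
    popt, rss = best
    dof = max(x.size - 4, 1)
    return WeibullFit(
        variant,
        float(popt[0]),
        float(popt[1]),
        float(popt[2]),
        float(popt[3]),
        x_unit,
        residual_sd=float(np.sqrt(rss / dof)),
        converged=True,
    )


def fit_weibull_ascending(x, y, x_unit: str = "h") -> WeibullFit:
    """Fit f(x) = c + (d-c)[1 - exp(-exp(b(ln x - ln e)))] by least squares."""
    return _fit_weibull(x, y, "ascending", x_unit)


def fit_weibull_descending(x, y, x_unit: str = "g/L") -> WeibullFit:
    """Fit f(x) = c + (d-c) exp(-exp(b(ln x - ln e))) by least squares."""
    return _fit_weibull(x, y, "descending", x_unit)


def mu_max(fit: WeibullFit, time: np.ndarray, refine: int = GRID_REFINE) -> float:
    """Maximum of f'(t)/f(t) over the observed window on a refined grid.

    The ratio diverges as t -> 0 when the lower plateau c -> 0, so the
    search is restricted to the observed times.
    """
    time = np.asarray(time, dtype=float)
    t0 = max(float(time.min()), 1e-9)
    grid = np.linspace(t0, float(time.max()), time.size * refine)
    f = fit(grid)
    if np.any(f <= 0):
        warnings.warn("biomass curve nonpositive on the window; restricting grid")
        grid = grid[f > 0]
        f = f[f > 0]
    return float(np.max(fit.derivative(grid) / f))


def biomass_criteria(
    fit: WeibullFit, time, sugar, refine: int = GRID_REFINE
) -> BiomassCriteria:
    """mu_max, inflection (reported at x = e, re-expressed in consumed sugar)
    and maximum biomass (the plateau d) from an ascending fit in time."""
    time = np.asarray(time, dtype=float)
    sugar = np.asarray(sugar, dtype=float)
    return BiomassCriteria(
        mu_max=mu_max(fit, time, refine),
        inflection_point=float(np.interp(fit.e, time, sugar)),
        max_biomass=fit.d,
    )


def point_aa0(fit: WeibullFit, threshold_frac: float = AA0_THRESHOLD_DEFAULT) -> float:
    """Consumed-sugar coordinate at which the nitrogen source is exhausted.

    Smallest x with f(x) <= c + threshold_frac*(d-c); closed form
    x = e * ln(1/threshold_frac)**(1/b). When the fitted floor c exceeds
    threshold_frac*d in absolute terms the source never becomes null and
    NaN is returned (the "not exhausted" sentinel).
    """
    if fit.variant != "descending":
        raise ValueError("Point.AA0 is defined for descending fits")
    if fit.c > threshold_frac * fit.d:
        return float("nan")
    return descending_threshold_crossing(fit.b, fit.e, threshold_frac)


def aa_consumption_criteria(
    fit: WeibullFit,
    sugar,
    threshold_frac: float = AA0_THRESHOLD_DEFAULT,
    refine: int = GRID_REFINE,
) -> AAConsumptionCriteria:
    """Maximal consumption rate, inflection and Point.AA0 from a descending
    fit on the consumed-sugar axis."""
    sugar = np.asarray(sugar, dtype=float)
    grid = np.linspace(max(float(sugar.min()), 1e-9), float(sugar.max()), sugar.size * refine)
    rate = float(np.max(np.abs(fit.derivative(grid))))
    aa0 = point_aa0(fit, threshold_frac)
    return AAConsumptionCriteria(
        maximal_rate=rate,
        inflection_point=fit.e,
        point_aa0=aa0,
        exhausted=not np.isnan(aa0),
    )


def specific_rate(rate, population) -> np.ndarray:
    """q = rate / population, mg/(1e9 cells * h) for biomass in 1e6 cells/mL."""
    rate = np.asarray(rate, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        raise ValueError("modelled population must be positive on the window")
    return rate / population


def extract_production_criteria(
    compound: str,
    time,
    production,
    sugar,
    biomass_fit: WeibullFit,
    span_grid: tuple[float, ...] = SPAN_GRID_DEFAULT,
    refine: int = GRID_REFINE,
    smoother: LocalRegression | None = None,
) -> ProductionCriteria:
    """Smooth P(t) with local regression and extract Max, max rate, SRmax,
    PointSRmax and the inflection point (argmax of dP/dsugar).

    The evaluation grid is the observation grid refined ``refine`` times;
    argmax ties break toward the earliest grid point, and a maximum landing
    on the window boundary is flagged.
    """
    time = np.asarray(time, dtype=float)
    sugar = np.asarray(sugar, dtype=float)
    production = np.asarray(production, dtype=float)
    if smoother is None:
        smoother = smooth_production(time, production, span_grid)
    grid = np.linspace(float(time.min()), float(time.max()), time.size * refine)
    p_s = smoother.predict(grid)
    rate = smoother.derivative(grid)
    sugar_g = np.interp(grid, time, sugar)
    pop = biomass_fit(grid)
    q = specific_rate(rate, pop)

    i_q = int(np.argmax(q))
    at_boundary = i_q in (0, grid.size - 1)
    if at_boundary:
        warnings.warn(f"{compound}: specific-rate maximum at the window boundary")
    dsdt = np.gradient(sugar_g, grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        dpdx = np.where(dsdt > 1e-12, rate / dsdt, -np.inf)
    i_x = int(np.argmax(dpdx))
    return ProductionCriteria(
        compound=compound,
        max_production=float(np.max(p_s)),
        max_rate=float(np.max(rate)),
        srmax=float(q[i_q]),
        point_srmax=float(sugar_g[i_q]),
        inflection_point=float(sugar_g[i_x]),
        at_boundary=at_boundary,
    )
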