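"""Bioconversion-yield analysis: acetate-ester total production as a
piecewise-linear function of its precursor higher alcohol's total
production.

Plotting ester P(t) against alcohol P(t) removes time and expresses the
conversion as a trajectory in (mg alcohol, mg ester) space. Within a
metabolic phase that trajectory is close to linear and its slope is the
bioconversion yield (mg ester formed per mg alcohol formed). Phase changes
(e.g. after nutrient additions) show up as breakpoints.

The fit is continuous piecewise-linear: y = a + s1*x + sum_j g_j*(x-b_j)+,
with the number of phases (1..max_phases) selected by BIC and breakpoints
located by an exhaustive quantile-grid search refined by Nelder-Mead. An
``independent`` flag fits disconnected per-segment lines instead, for
sensitivity checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .balance import VolatileBalance

MAX_PHASES_DEFAULT = 4
MIN_POINTS_PER_PHASE = 10


@dataclass
class ConversionTrajectory:
    """Paired (alcohol P, ester P) trajectory on a common time grid."""

    alcohol_P: np.ndarray
    ester_P: np.ndarray
    time: np.ndarray
    compound_pair: str = ""

    def __post_init__(self):
        self.alcohol_P = np.asarray(self.alcohol_P, dtype=float)
        self.ester_P = np.asarray(self.ester_P, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if not (self.alcohol_P.size == self.ester_P.size == self.time.size):
            raise ValueError("trajectory channels must share one grid")


@dataclass
class BioconversionResult:
    """Breakpoints and per-phase conversion yields for one compound pair."""

    compound_pair: str
    n_phases: int
    breakpoints: list[float]
    yields: list[float]
    r2: list[float]
    model_score: float  # BIC of the selected model
    rss: float = float("nan")
    all_scores: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_phases != len(self.yields) or self.n_phases != len(self.breakpoints) + 1:
            raise ValueError("n_phases must equal len(yields) = len(breakpoints)+1")


def build_trajectory(
    balance_alcohol: VolatileBalance,
    balance_ester: VolatileBalance,
    smooth: bool | str = False,
) -> ConversionTrajectory:
    """Pair two P(t) channels onto the alcohol's time grid.

    The ester channel is linearly interpolated onto the alcohol grid over
    the overlapping time range; disjoint ranges are an error. With
    ``smooth=True`` the alcohol (x) channel is denoised with a local
    regression in time before pairing: measurement noise on the x axis
    would otherwise scramble the sort order the segmented fit relies on.
    The ester channel is left raw so its errors stay independent, which is
    what the BIC phase selection assumes. ``smooth="auto"`` smooths only
    when the raw alcohol axis is not already monotone (i.e. it is noisy).
    """
    t_lo = max(balance_alcohol.time[0], balance_ester.time[0])
    t_hi = min(balance_alcohol.time[-1], balance_ester.time[-1])
    if t_lo >= t_hi:
        raise ValueError(
            f"time ranges of {balance_alcohol.compound!r} and "
            f"{balance_ester.compound!r} do not overlap"
        )
    mask = (balance_alcohol.time >= t_lo) & (balance_alcohol.time <= t_hi)
    t = balance_alcohol.time[mask]
    if smooth == "auto":
        smooth = bool(np.any(np.diff(balance_alcohol.P[mask]) < 0))
    if smooth:
        from .smoothing import smooth_production

        sm_a = smooth_production(balance_alcohol.time, balance_alcohol.P)
        x = sm_a.predict(t)
        y = np.interp(t, balance_ester.time, balance_ester.P)
    else:
        x = balance_alcohol.P[mask]
        y = np.interp(t, balance_ester.time, balance_ester.P)
    # yields are defined while the precursor is still being produced: trim
    # the trailing plateau (where dx ~ 0 any y-noise looks like a steep
    # phase) and keep a strictly increasing alcohol axis
    imax = int(np.argmax(x))
    stop = int(np.argmax(x >= 0.995 * x[imax])) if x[imax] > 0 else imax
    stop = max(stop, 1)
    x, y, t = x[: stop + 1], y[: stop + 1], t[: stop + 1]
    keep = np.concatenate([[True], np.diff(np.maximum.accumulate(x)) > 0])
    x, y, t = x[keep], y[keep], t[keep]
    return ConversionTrajectory(
        alcohol_P=x,
        ester_P=y,
        time=t,
        compound_pair=f"{balance_alcohol.compound} -> {balance_ester.compound}",
    )


def _hinge_design(x: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x] + [np.maximum(0.0, x - b) for b in breaks]
    return np.column_stack(cols)


def _fit_fixed_breaks(x, y, breaks: np.ndarray) -> tuple[np.ndarray, float]:
    X = _hinge_design(x, breaks)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((X @ beta - y) ** 2))
    return beta, rss


def _fit_independent(x, y, breaks: np.ndarray) -> tuple[list[float], float]:
    edges = np.concatenate([[-np.inf], breaks, [np.inf]])
    slopes, rss = [], 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (x > lo) & (x <= hi) if np.isfinite(lo) else (x <= hi)
        coef = np.polyfit(x[m], y[m], 1)
        slopes.append(float(coef[0]))
        rss += float(np.sum((np.polyval(coef, x[m]) - y[m]) ** 2))
    return slopes, rss


def _valid_breaks(x_sorted: np.ndarray, breaks: np.ndarray, min_pts: int) -> bool:
    if breaks.size == 0:
        return True
    if np.any(np.diff(breaks) <= 0):
        return False
    if breaks[0] <= x_sorted[0] or breaks[-1] >= x_sorted[-1]:
        return False
    edges = np.concatenate([[-np.inf], breaks, [np.inf]])
    counts = np.histogram(x_sorted, bins=np.concatenate([[x_sorted[0] - 1], breaks, [x_sorted[-1] + 1]]))[0]
    return bool(np.all(counts >= min_pts)) and edges.size == counts.size + 1


def _search_breaks(x, y, k_breaks: int, min_pts: int, continuous: bool):
    """Exhaustive search over a quantile candidate grid, then local refine."""
    if k_breaks == 0:
        if continuous:
            _, rss = _fit_fixed_breaks(x, y, np.empty(0))
        else:
            _, rss = _fit_independent(x, y, np.empty(0))
        return np.empty(0), rss
    n_cand = min(24, x.size - 2 * min_pts)
    if n_cand < k_breaks:
        return None, np.inf
    cands = np.unique(np.quantile(x, np.linspace(0.05, 0.95, n_cand)))
    fit = (lambda br: _fit_fixed_breaks(x, y, br)[1]) if continuous else (
        lambda br: _fit_independent(x, y, br)[1]
    )
    best_br, best_rss = None, np.inf
    for combo in itertools.combinations(cands, k_breaks):
        br = np.asarray(combo)
        if not _valid_breaks(x, br, min_pts):
            continue
        rss = fit(br)
        if rss < best_rss:
            best_br, best_rss = br, rss
    if best_br is None:
        return None, np.inf

    def objective(br):
        br = np.sort(np.asarray(br))
        if not _valid_breaks(x, br, min_pts):
            return best_rss * 10 + 1.0
        return fit(br)

    res = minimize(objective, best_br, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 400})
    if res.fun < best_rss:
        best_br, best_rss = np.sort(res.x), float(res.fun)
    return best_br, best_rss


def _phase_r2(x, y, breaks, beta=None, slopes=None, continuous=True) -> list[float]:
    edges = np.concatenate([[-np.inf], np.asarray(breaks), [np.inf]])
    out = []
    if continuous:
        X = _hinge_design(x, np.asarray(breaks))
        yhat = X @ beta
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        m = (x > lo) & (x <= hi) if np.isfinite(lo) else (x <= hi)
        if not continuous:
            coef = np.polyfit(x[m], y[m], 1)
            seg_hat = np.polyval(coef, x[m])
        else:
            seg_hat = yhat[m]
        ss_res = float(np.sum((y[m] - seg_hat) ** 2))
        ss_tot = float(np.sum((y[m] - np.mean(y[m])) ** 2))
        out.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0)
    return out


def segmented_yield_fit(
    traj: ConversionTrajectory,
    max_phases: int = MAX_PHASES_DEFAULT,
    min_points_per_phase: int = MIN_POINTS_PER_PHASE,
    continuous: bool = True,
) -> BioconversionResult:
    """Piecewise-linear least squares in (alcohol_P, ester_P) space with the
    number of phases chosen by BIC.

    BIC = n*ln(RSS/n) + p*ln(n) with p = 2*k parameters for k phases
    (k+1 linear coefficients and k-1 breakpoints in the continuous model).
    RSS is floored at numerical-noise scale so that exactly-linear data
    select the most parsimonious model; ties break toward fewer phases.
    """
    if max_phases < 1:
        raise ValueError("max_phases must be >= 1")
    order = np.argsort(traj.alcohol_P, kind="stable")
    x = traj.alcohol_P[order]
    y = traj.ester_P[order]
    n = x.size
    if n < 2 * min_points_per_phase:
        raise ValueError("too few points for a segmented fit")
    scale = max(float(np.max(np.abs(y))), 1e-12)
    # fits this close to exact are numerically indistinguishable: flooring
    # the RSS lets the BIC penalty pick the most parsimonious of them
    rss_floor = n * (1e-7 * scale) ** 2

    results = {}
    for k in range(1, max_phases + 1):
        if n < k * min_points_per_phase:
            break
        br, rss = _search_breaks(x, y, k - 1, min_points_per_phase, continuous)
        if br is None:
            continue
        p = 2 * k
        bic = n * np.log(max(rss, rss_floor) / n) + p * np.log(n)
        results[k] = (br, rss, float(bic))
    if not results:
        raise ValueError("no candidate segmentation satisfied the constraints")
    best_k = min(results, key=lambda k: (round(results[k][2], 9), k))
    br, rss, bic = results[best_k]
    if br.size:
        # polish the selected model's breakpoints to full precision
        fit = (lambda b: _fit_fixed_breaks(x, y, b)[1]) if continuous else (
            lambda b: _fit_independent(x, y, b)[1]
        )

        def objective(b):
            b = np.sort(np.asarray(b))
            return fit(b) if _valid_breaks(x, b, min_points_per_phase) else rss * 10 + 1.0

        res = minimize(objective, br, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 0.0, "maxiter": 2000})
        if res.fun <= rss:
            br, rss = np.sort(res.x), float(res.fun)
    if continuous:
        beta, _ = _fit_fixed_breaks(x, y, br)
        slopes = list(np.cumsum(np.concatenate([[beta[1]], beta[2:]])))
        r2 = _phase_r2(x, y, br, beta=beta, continuous=True)
    else:
        slopes, _ = _fit_independent(x, y, br)
        r2 = _phase_r2(x, y, br, continuous=False)
    return BioconversionResult(
        compound_pair=traj.compound_pair,
        n_phases=best_k,
        breakpoints=[float(b) for b in br],
        yields=[float(s) for s in slopes],
        r2=[float(v) for v in r2],
        model_score=bic,
        rss=float(rss),
        all_scores={k: v[2] for k, v in results.items()},
    )


def yield_report(
    results: dict[tuple, BioconversionResult],
    key_names: tuple[str, ...] = ("strain", "medium", "phytosterol"),
) -> pd.DataFrame:
    """Long-format yield table: one row per (condition, pair, phase).

    ``results`` maps condition keys (tuples matching ``key_names``) to
    fitted BioconversionResult objects. Conditions with fewer phases than
    the table's maximum leave the later phase rows absent, mirroring blank
    cells in a wide layout.
    """
    rows = []
    for key, res in results.items():
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(key_names, key))
        for phase, (y, r) in enumerate(zip(res.yields, res.r2), start=1):
            rows.append(
                {
                    **meta,
                    "pair": res.compound_pair,
                    "n_phases": res.n_phases,
                    "phase": phase,
                    "yield": y,
                    "r2": r,
                }
            )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values([*key_names, "pair", "phase"]).reset_index(drop=True)
    return frame
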