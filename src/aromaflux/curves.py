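"""Four-parameter Weibull curves used for biomass growth, nitrogen-source
consumption and (in the simulator) true volatile-production trajectories.

Both variants share the parameterisation (b, c, d, e):

* ``b`` — shape (steepness on the log-x axis),
* ``c`` — lower plateau,
* ``d`` — upper plateau (``d > c``),
* ``e`` — location of the inflection on the x axis (time in h, or consumed
  sugar in g/L, depending on the channel).

Ascending form (growth):   f(x) = c + (d-c) * [1 - exp(-exp(b*(ln x - ln e)))]
Descending form (decay):   f(x) = c + (d-c) * exp(-exp(b*(ln x - ln e)))

At x = e the ascending curve passes through c + (d-c)*(1 - 1/e) and the
descending curve through c + (d-c)/e (with Euler's e), which the fitting
tests exploit as algebraic identities.
"""

from __future__ import annotations

import numpy as np


def _inner(x: np.ndarray, b: float, e: float) -> np.ndarray:
    # exp(b*(ln x - ln e)) = (x/e)**b, computed safely for x >= 0
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(x > 0, np.power(np.maximum(x, 1e-300) / e, b), 0.0 if b > 0 else np.inf)
    return u


def weibull_ascending(x, b: float, c: float, d: float, e: float) -> np.ndarray:
    """Ascending four-parameter Weibull, c at x→0+ rising to d."""
    u = _inner(x, b, e)
    return c + (d - c) * (1.0 - np.exp(-u))


def weibull_descending(x, b: float, c: float, d: float, e: float) -> np.ndarray:
    """Descending four-parameter Weibull, d at x→0+ decaying to c."""
    u = _inner(x, b, e)
    return c + (d - c) * np.exp(-u)


def weibull_ascending_deriv(x, b: float, c: float, d: float, e: float) -> np.ndarray:
    """Analytic df/dx of the ascending form: (d-c) * exp(-u) * b*u/x."""
    x = np.asarray(x, dtype=float)
    u = _inner(x, b, e)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x > 0, (d - c) * np.exp(-u) * b * u / np.maximum(x, 1e-300), 0.0)
    return out


def weibull_descending_deriv(x, b: float, c: float, d: float, e: float) -> np.ndarray:
    """Analytic df/dx of the descending form (negative for d > c, b > 0)."""
    return -weibull_ascending_deriv(x, b, c, d, e)


def descending_threshold_crossing(b: float, e: float, threshold_frac: float) -> float:
    """x at which the descending curve has decayed to within ``threshold_frac``
    of its total drop, i.e. f(x) = c + threshold_frac*(d-c).

    Closed form: x = e * (ln(1/threshold_frac))**(1/b).
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    return float(e * np.log(1.0 / threshold_frac) ** (1.0 / b))
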