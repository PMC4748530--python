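"""Local polynomial regression (LOESS-style) with analytic derivatives.

Volatile production curves P(t) are modelled nonparametrically: at each
evaluation point a degree-2 polynomial is fitted by weighted least squares
to the nearest ``span`` fraction of the data, with tricube weights. The
first derivative is the linear coefficient of the local polynomial, so rate
curves come out of the fit itself rather than from differencing.

The bandwidth (span) is selected by leave-one-out cross-validation over a
fixed grid, using the closed-form LOO residual of linear smoothers
r_i / (1 - l_ii). A minimum span prevents collapse to interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SPAN_GRID_DEFAULT = (0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.7)
MIN_SPAN = 0.1
_DEGREE = 2


@dataclass
class LocalRegression:
    """Fitted local-polynomial smoother; call predict/derivative on any grid."""

    x: np.ndarray
    y: np.ndarray
    span: float
    cv_score: float

    def _local_fit(self, x0: float) -> np.ndarray:
        x, y = self.x, self.y
        n = x.size
        k = max(_DEGREE + 2, int(np.ceil(self.span * n)))
        k = min(k, n)
        dist = np.abs(x - x0)
        idx = np.argpartition(dist, k - 1)[:k]
        h = dist[idx].max()
        if h == 0:
            h = 1.0
        w = (1.0 - np.minimum(dist[idx] / h, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-8)
        dx = x[idx] - x0
        X = np.vander(dx, _DEGREE + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        return beta

    def predict(self, grid) -> np.ndarray:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        return np.array([self._local_fit(x0)[0] for x0 in grid])

    def derivative(self, grid) -> np.ndarray:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        return np.array([self._local_fit(x0)[1] for x0 in grid])


def _loo_score(x: np.ndarray, y: np.ndarray, span: float) -> float:
    n = x.size
    k = max(_DEGREE + 2, int(np.ceil(span * n)))
    k = min(k, n)
    resid2 = 0.0
    for i in range(n):
        dist = np.abs(x - x[i])
        idx = np.argpartition(dist, k - 1)[:k]
        h = dist[idx].max()
        if h == 0:
            h = 1.0
        w = (1.0 - np.minimum(dist[idx] / h, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-8)
        dx = x[idx] - x[i]
        X = np.vander(dx, _DEGREE + 1, increasing=True)
        W = w[:, None]
        XtWX = X.T @ (W * X)
        try:
            A = np.linalg.solve(XtWX, X.T * w)
        except np.linalg.LinAlgError:
            return np.inf
        yhat = A[0] @ y[idx]
        # hat-diagonal entry for observation i within its own neighbourhood
        pos = int(np.nonzero(idx == i)[0][0])
        lii = A[0, pos]
        denom = max(1.0 - lii, 1e-3)
        resid2 += ((y[i] - yhat) / denom) ** 2
    return resid2 / n


def smooth_production(
    x,
    y,
    span_grid: tuple[float, ...] = SPAN_GRID_DEFAULT,
) -> LocalRegression:
    """Fit a degree-2 local regression, choosing the span by LOO-CV.

    Parameters
    ----------
    x, y
        Observation grid (consumed sugar in g/L, or hours) and production
        values (mg/L). At least 10 points.
    span_grid
        Candidate bandwidths as fractions of the data; values below the
        minimum span are discarded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for local regression")
    order = np.argsort(x)
    x, y = x[order], y[order]
    spans = [s for s in span_grid if s >= MIN_SPAN]
    if not spans:
        raise ValueError(f"all candidate spans below the minimum span {MIN_SPAN}")
    scores = [_loo_score(x, y, s) for s in spans]
    best = int(np.argmin(scores))
    return LocalRegression(x=x, y=y, span=spans[best], cv_score=float(scores[best]))
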