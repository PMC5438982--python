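"""Saturating intensity-preference curves.

The intensity series measures the Preference Index as a function of the
test-light intensity x (percent, 0–100, against a 100% reference light) and
summarizes each light pair with a Michaelis–Menten curve

    y = a + b·x / (c + x)

where ``a`` is the PI at x = 0 (pure phototaxis toward the reference),
``b`` the span, and ``c`` the half-saturation intensity.  The
*zero-preference intensity* x0 solves y = 0:

    x0 = −a·c / (a + b)

valid when the curve actually crosses zero inside (0, 100]; otherwise one
light is preferred over the whole tested range and x0 is reported as none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = ["MMFit", "fit_mm", "zero_preference", "mm_curve"]


def mm_curve(x, a, b, c):
    x = np.asarray(x, dtype=float)
    return a + b * x / (c + x)


@dataclass(frozen=True)
class MMFit:
    a: float
    b: float
    c: float
    x0: Optional[float]
    residual_sse: float
    n_points: int
    converged: bool

    def predict(self, x):
        return mm_curve(x, self.a, self.b, self.c)


def fit_mm(x, y, x0_range: tuple[float, float] = (0.0, 100.0)) -> MMFit:
    """Unweighted least-squares fit of y = a + b·x/(c+x) with c > 0.

    Initialized at a = y(min x), b = y(max x) − y(min x), c = midrange.
    A constant y returns the degenerate flat fit (b ≈ 0, no crossing)
    rather than an error; non-convergence is flagged, never silent.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct intensity levels")

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    y0, y1 = float(ys[0]), float(ys[-1])

    if np.allclose(ys, ys[0]):
        a = float(ys[0])
        fit = MMFit(a, 0.0, 1.0, None if a != 0 else 0.0, 0.0, len(x), True)
        return fit

    p0 = (y0, y1 - y0, max((xs[0] + xs[-1]) / 2.0, 1.0))
    converged = True
    try:
        popt, _ = curve_fit(
            mm_curve,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            maxfev=20000,
        )
    except RuntimeError:
        popt = np.asarray(p0)
        converged = False
    a, b, c = (float(v) for v in popt)
    sse = float(np.sum((mm_curve(x, a, b, c) - y) ** 2))
    x0 = _zero_crossing(a, b, c, x0_range) if converged else None
    return MMFit(a, b, c, x0, sse, len(x), converged)


def _zero_crossing(
    a: float, b: float, c: float, x0_range: tuple[float, float]
) -> Optional[float]:
    lo, hi = x0_range
    if a == 0.0:
        return 0.0  # the curve starts at zero preference
    if a + b == 0.0:
        return None  # asymptote never crosses zero
    if a * (a + b) >= 0.0:
        return None  # no sign change between x=0 and the asymptote
    x0 = -a * c / (a + b)
    if lo < x0 <= hi:
        return float(x0)
    return None


def zero_preference(fit: MMFit, x0_range: tuple[float, float] = (0.0, 100.0)):
    """Closed-form zero-preference intensity of a fitted curve (or None when
    one light is preferred over the whole tested range)."""
    return _zero_crossing(fit.a, fit.b, fit.c, x0_range)


def zero_preference_numeric(
    fit: MMFit, x0_range: tuple[float, float] = (0.0, 100.0)
) -> Optional[float]:
    """Bracketing root-finder on the fitted curve; cross-check for the
    closed form (agreement to ~1e-9 is asserted in the test suite)."""
    lo, hi = max(x0_range[0], 1e-12), x0_range[1]
    f = lambda x: fit.predict(x)
    if fit.a == 0.0:
        return 0.0
    if f(lo) * f(hi) > 0:
        return None
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-15))


def intensity_series_table(trial_metrics):
    """Expand intensity-series trial tags ("REFTEST:pct:sN:pN") into tidy
    pair / test_intensity_pct columns for curve fitting."""
    import pandas as pd

    df = trial_metrics[trial_metrics["tag"].str.contains(":", na=False)].copy()
    if df.empty:
        raise ValueError("no intensity-series trials in the metrics table")
    parts = df["tag"].str.split(":", expand=True)
    df["pair"] = parts[0]
    df["test_intensity_pct"] = parts[1].astype(float)
    return df


def fit_preference_curves(exp3_metrics, sign: float = 1.0):
    """Fit one MM curve per (reference, test) pair from a tidy intensity-
    series metrics table (columns: pair, test_intensity_pct, pi).

    The PI is pooled (mean) per intensity level over the reciprocal
    presentations and both series directions; ``sign`` flips the PI
    orientation if a caller prefers the opposite convention.
    Returns a DataFrame with one row per pair: a, b, c, x0, sse, n.
    """
    import pandas as pd

    rows = []
    for pair, grp in exp3_metrics.groupby("pair"):
        means = grp.groupby("test_intensity_pct")["pi"].mean().sort_index()
        fit = fit_mm(means.index.to_numpy(), sign * means.to_numpy())
        rows.append(
            {
                "pair": pair,
                "a": fit.a,
                "b": fit.b,
                "c": fit.c,
                "x0": fit.x0,
                "sse": fit.residual_sse,
                "n": fit.n_points,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
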