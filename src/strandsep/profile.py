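"""Profile-likelihood confidence analysis for the global fit.

For one parameter at a time, a grid of trial values is clamped and every
other floating parameter re-optimized; the rise of the re-optimized SSR
above its minimum traces out the profile.  Confidence bounds are where
the profile crosses the F-statistic threshold

    SSR_crit = SSR_min * (1 + F(level; 1, N - P) / (N - P))

with N data points and P floating parameters — the standard large-sample
bound for a single nonlinear-regression parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

__all__ = [
    "ConfidenceProfile",
    "profile_parameter",
    "profile_objective_function",
    "ssr_threshold",
    "ci_table",
    "format_interval",
]


def ssr_threshold(ssr_min: float, n_obs: int, n_floats: int, level: float = 0.95) -> float:
    dof = n_obs - n_floats
    if dof <= 0:
        raise ValueError("need more data points than floating parameters")
    return ssr_min * (1.0 + f_dist.ppf(level, 1, dof) / dof)


@dataclass(frozen=True)
class ConfidenceProfile:
    """One parameter's profile: grid, re-optimized SSR and 95% bounds."""

    name: str
    values: np.ndarray
    ssr: np.ndarray
    best: float
    ssr_min: float
    threshold: float
    lower: float
    upper: float
    lower_open: bool = False
    upper_open: bool = False

    @property
    def ssr_ratio(self) -> np.ndarray:
        return self.ssr / self.ssr_min

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"param_value": self.values, "ssr": self.ssr, "ssr_ratio": self.ssr_ratio}
        )


def _crossing(v_in, s_in, v_out, s_out, threshold, refine=None, tol=0.005):
    """Locate the threshold crossing between an inside and an outside point.

    Interpolates SSR linearly in log-parameter; if a ``refine`` callable
    (value -> SSR) is supplied, bisects until the bracket is within
    ``tol`` of the parameter value.
    """
    lo_v, lo_s, hi_v, hi_s = v_in, s_in, v_out, s_out
    if refine is not None:
        while abs(hi_v - lo_v) > tol * abs(lo_v):
            mid = float(np.sqrt(lo_v * hi_v))
            s_mid = refine(mid)
            if s_mid < threshold:
                lo_v, lo_s = mid, s_mid
            else:
                hi_v, hi_s = mid, s_mid
    # linear interpolation of SSR in log(value)
    if hi_s == lo_s:
        return float(np.sqrt(lo_v * hi_v))
    w = (threshold - lo_s) / (hi_s - lo_s)
    return float(np.exp(np.log(lo_v) + w * (np.log(hi_v) - np.log(lo_v))))


def profile_parameter(
    model,
    result,
    name: str,
    *,
    n_per_side: int = 21,
    span: float = 4.0,
    level: float = 0.95,
    refine: bool = True,
    refine_tol: float = 0.005,
    grid: Optional[Sequence[float]] = None,
) -> ConfidenceProfile:
    """Profile one floating parameter of a fitted model.

    Walks outward from the best fit on each side (warm-starting each
    re-optimization from its neighbor) over ``n_per_side`` log-spaced
    points spanning a factor of ``span``, then refines the threshold
    crossings by bisection.  A side whose profile never reaches the
    threshold is flagged open.
    """
    if name not in result.float_names:
        raise ValueError(
            f"cannot profile {name!r}: not a floating parameter of this fit"
        )
    best = float(result.values[name])
    ssr_min = result.ssr
    threshold = ssr_threshold(ssr_min, model.n_obs, result.n_floats, level)

    warm0 = dict(result.values)

    def reopt(value, warm):
        sub = model.fit(start_values=warm, clamp={name: float(value)}, multistart=1)
        return sub.ssr, dict(sub.values)

    if grid is not None:
        g = np.asarray(sorted(float(v) for v in grid))
        below = g[g < best][::-1]
        above = g[g > best]
    else:
        below = np.geomspace(best, best / span, n_per_side + 1)[1:]
        above = np.geomspace(best, best * span, n_per_side + 1)[1:]

    def walk(side_values):
        out_v, out_s = [], []
        warm = warm0
        for v in side_values:
            s, warm = reopt(v, warm)
            out_v.append(v)
            out_s.append(s)
            if s > threshold:
                break
        return out_v, out_s

    lo_v, lo_s = walk(below)
    hi_v, hi_s = walk(above)

    def refiner(warm_cache):
        def fn(value):
            s, w = reopt(value, warm_cache[0])
            warm_cache[0] = w
            return s
        return fn

    def side_bound(vs, ss, open_default):
        if not vs:
            return open_default, True
        inside_v, inside_s = best, ssr_min
        for v, s in zip(vs, ss):
            if s > threshold:
                ref = refiner([dict(warm0)]) if refine else None
                return _crossing(inside_v, inside_s, v, s, threshold,
                                 refine=ref, tol=refine_tol), False
            inside_v, inside_s = v, s
        return vs[-1], True

    lower, lower_open = side_bound(lo_v, lo_s, below[-1] if len(below) else best)
    upper, upper_open = side_bound(hi_v, hi_s, above[-1] if len(above) else best)

    values = np.array(list(reversed(lo_v)) + [best] + hi_v)
    ssr = np.array(list(reversed(lo_s)) + [ssr_min] + hi_s)
    return ConfidenceProfile(
        name=name, values=values, ssr=ssr, best=best, ssr_min=ssr_min,
        threshold=threshold, lower=float(min(lower, best)),
        upper=float(max(upper, best)),
        lower_open=lower_open, upper_open=upper_open,
    )


def profile_objective_function(
    fun: Callable[[np.ndarray], np.ndarray],
    x_best: np.ndarray,
    index: int,
    grid: Sequence[float],
) -> np.ndarray:
    """Generic 1-D profile of a residual function.

    For each grid value, clamps ``x[index]`` and re-optimizes the
    remaining components by least squares (warm-started from the best
    fit).  Returns the re-optimized SSR at each grid point.  This is the
    same construction `profile_parameter` applies to the kinetic model
    and is used as an independent check against closed-form intervals.
    """
    x_best = np.asarray(x_best, float)
    free = [i for i in range(x_best.size) if i != index]
    out = np.empty(len(grid))
    for j, v in enumerate(grid):
        if free:
            def sub(z):
                x = x_best.copy()
                x[index] = v
                x[free] = z
                return fun(x)
            sol = least_squares(sub, x_best[free], xtol=1e-14, ftol=1e-14)
            out[j] = 2 * sol.cost
        else:
            x = x_best.copy()
            x[index] = v
            r = fun(x)
            out[j] = float(r @ r)
    return out


def format_interval(best: float, lower=None, upper=None,
                    lower_open=False, upper_open=False) -> str:
    """Render a value with its interval in 'best (lower–upper)' style."""
    def fmt(v):
        return f"{v:.3g}"
    if lower is None or upper is None:
        return f"{fmt(best)} (n.d.)"
    lo = f"<{fmt(lower)}" if lower_open else fmt(lower)
    hi = f">{fmt(upper)}" if upper_open else fmt(upper)
    return f"{fmt(best)} ({lo}–{hi})"


def ci_table(profiles: Sequence[ConfidenceProfile], best_values=None) -> pd.DataFrame:
    """Per-parameter (best, lower, upper) table with rendered intervals."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "parameter": p.name,
                "best": p.best,
                "lower": p.lower,
                "upper": p.upper,
                "lower_open": p.lower_open,
                "upper_open": p.upper_open,
                "formatted": format_interval(
                    p.best, p.lower, p.upper, p.lower_open, p.upper_open
                ),
            }
        )
    cols = ["parameter", "best", "lower", "upper",
            "lower_open", "upper_open", "formatted"]
    return pd.DataFrame(rows, columns=cols)
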