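"""Exponential pre-fits used to characterize traces and seed the global fit.

Stopped-flow fluorescence traces are summarized by a rising
double-exponential, y = a0 + a1*(1 - exp(-b1 t)) + a2*(1 - exp(-b2 t)),
and single-turnover product curves by a one-phase approach to plateau,
y = plateau - amplitude*exp(-b t).  Both fits are multistarted over a
log-spaced grid of rate guesses; for each trial rate pair the amplitudes
enter linearly and are solved exactly, which makes the procedure
deterministic and insensitive to starting values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["ExpFitResult", "fit_double_exponential", "fit_one_phase_decay", "PrefitError"]


class PrefitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ExpFitResult:
    """Result of an exponential fit.

    ``phases`` is a tuple of (amplitude, rate) pairs ordered fast to slow.
    For one-phase decay fits ``offset`` is the plateau, the single phase
    amplitude is the (signed) approach amplitude, and ``initial_value``
    is plateau - amplitude.  ``ill_conditioned`` flags near-degenerate
    rates (b1/b2 < 1.5).
    """

    offset: float
    phases: tuple
    rms: float
    ill_conditioned: bool = False

    @property
    def rates(self) -> tuple:
        return tuple(b for _, b in self.phases)

    @property
    def amplitudes(self) -> tuple:
        return tuple(a for a, _ in self.phases)

    @property
    def initial_value(self) -> float:
        return self.offset - sum(self.amplitudes)


def _extract(trace):
    # accept a Trace or a bare (t, y) pair
    if hasattr(trace, "signal"):
        return np.asarray(trace.times, float), np.asarray(trace.signal, float)
    t, y = trace
    return np.asarray(t, float), np.asarray(y, float)


def _rate_grid(span: float, n: int = 5) -> np.ndarray:
    return np.geomspace(0.1 / span, 100.0 / span, n)


def _linear_amplitudes(t, y, rates):
    """Solve the linear subproblem: offset + amplitudes at fixed rates."""
    cols = [np.ones_like(t)] + [1.0 - np.exp(-b * t) for b in rates]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(np.sqrt(np.mean(resid**2)))


def fit_double_exponential(trace) -> ExpFitResult:
    """Fit y = a0 + a1*(1 - e^(-b1 t)) + a2*(1 - e^(-b2 t)), b1 >= b2."""
    t, y = _extract(trace)
    if t.size < 7:
        raise PrefitError("double-exponential fit needs at least 7 points")
    span = t[-1] - t[0]
    if span <= 0:
        raise PrefitError("trace must span positive time")

    grid = _rate_grid(span)
    best = None
    for b1 in grid:
        for b2 in grid:
            if b1 < b2:
                continue
            coef, rms = _linear_amplitudes(t, y, (b1, b2))
            if best is None or rms < best[1]:
                best = ((coef, (b1, b2)), rms)
    (coef0, rates0), _ = best

    scale = max(np.ptp(y), 1e-12)

    def resid(p):
        a0, a1, a2 = p[0], p[1], p[2]
        b1, b2 = np.exp(p[3]), np.exp(p[4])
        return a0 + a1 * (1 - np.exp(-b1 * t)) + a2 * (1 - np.exp(-b2 * t)) - y

    p0 = [coef0[0], coef0[1], coef0[2], np.log(rates0[0]), np.log(rates0[1])]
    sol = least_squares(resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise PrefitError(f"double-exponential fit failed: {sol.message}")
    a0, a1, a2 = sol.x[:3]
    b1, b2 = np.exp(sol.x[3]), np.exp(sol.x[4])
    phases = sorted([(a1, b1), (a2, b2)], key=lambda ab: -ab[1])
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    ill = phases[1][1] > 0 and phases[0][1] / phases[1][1] < 1.5
    return ExpFitResult(float(a0), tuple(phases), rms, ill_conditioned=bool(ill))


def fit_one_phase_decay(trace) -> ExpFitResult:
    """Fit y = plateau - amplitude * e^(-b t) (single approach to plateau)."""
    t, y = _extract(trace)
    if t.size < 4:
        raise PrefitError("one-phase fit needs at least 4 points")
    span = t[-1] - t[0]
    if span <= 0:
        raise PrefitError("trace must span positive time")

    best = None
    for b in _rate_grid(span, n=25):
        coef, rms = _linear_amplitudes(t, y, (b,))
        if best is None or rms < best[1]:
            best = ((coef, b), rms)
    (coef0, b0), _ = best

    def resid(p):
        a0, a1 = p[0], p[1]
        return a0 + a1 * (1 - np.exp(-np.exp(p[2]) * t)) - y

    sol = least_squares(resid, [coef0[0], coef0[1], np.log(b0)],
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise PrefitError(f"one-phase fit failed: {sol.message}")
    a0, a1 = sol.x[:2]
    b = float(np.exp(sol.x[2]))
    # y = a0 + a1*(1 - e^-bt) = (a0 + a1) - a1 e^-bt: plateau a0+a1, amplitude a1
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return ExpFitResult(float(a0 + a1), ((float(a1), b),), rms)
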