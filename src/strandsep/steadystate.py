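"""Steady-state constants derived from the microscopic rate constants.

For the four-step mechanism E + S <=> FS <=> GS^I <=> GSp <=> E + Sp the
King-Altman treatment (with rapid-equilibrium binding governed by k1/k1r)
gives closed forms for kcat, Km and the specificity constant kcat/Km:

    D        = k2*(k3 + k3r + k4) + k2r*(k3r + k4) + k3*k4
    kcat     = k2*k3*k4 / D
    Km       = [k1r*(k2r*k3r + k2r*k4 + k3*k4) + k2*k3*k4] / (k1 * D)
    kcat/Km  = k1*k2*k3*k4 / [k1r*(k2r*k3r + k2r*k4 + k3*k4) + k2*k3*k4]

Note the k2r*(k3r + k4) grouping in D: it is required for the algebraic
identity kcat/Km == kcat / Km (exact when k3r = 0), which the module
asserts in its tests.  A simulation-based oracle (`verify_against_simulation`)
confirms the closed forms against multi-turnover initial velocities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .mechanism import RateConstants, SpeciesState, integrate

__all__ = [
    "SteadyStateParams",
    "steady_state_params",
    "verify_against_simulation",
    "fold_changes",
]


@dataclass(frozen=True)
class SteadyStateParams:
    """Turnover number (1/s), Michaelis constant (uM), specificity (1/(uM*s))."""

    kcat: float
    Km: float
    kcat_over_Km: float


def steady_state_params(rates: RateConstants) -> SteadyStateParams:
    """Closed-form steady-state parameters for a rate-constant set."""
    k1, k1r, k2, k2r, k3, k3r, k4 = (
        rates.k1, rates.k1r, rates.k2, rates.k2r, rates.k3, rates.k3r, rates.k4,
    )
    D = k2 * (k3 + k3r + k4) + k2r * (k3r + k4) + k3 * k4
    spec_den = k1r * (k2r * k3r + k2r * k4 + k3 * k4) + k2 * k3 * k4
    if D <= 0 or spec_den <= 0 or k1 <= 0:
        raise ZeroDivisionError("steady-state parameters undefined: zero denominator")
    kcat = k2 * k3 * k4 / D
    Km = spec_den / (k1 * D)
    spec = k1 * k2 * k3 * k4 / spec_den
    return SteadyStateParams(kcat=float(kcat), Km=float(Km), kcat_over_Km=float(spec))


def _initial_velocity(rates: RateConstants, E0: float, S0: float, v_guess: float):
    """Steady-state velocity (uM/s) from the linear phase of a simulation.

    Integrates past the pre-steady-state transient to ~2% substrate
    depletion and takes the slope of total product over the second half
    of the window, rejecting windows whose late phase is visibly curved.
    """
    t_end = 0.02 * S0 / v_guess
    times = np.linspace(0.0, t_end, 80)[1:]
    traj = integrate(rates, SpeciesState(E=E0, S=S0), times)
    t, p = traj.times, traj.product_total
    half = t >= 0.5 * t_end
    slope, _ = np.polyfit(t[half], p[half], 1)
    c2, c1, _ = np.polyfit(t[half], p[half], 2)
    if abs(c2) * (0.5 * t_end) > 0.05 * abs(slope):
        raise RuntimeError("late phase not linear; velocity not at steady state")
    return float(slope)


def verify_against_simulation(
    rates: RateConstants,
    S_grid: Optional[Sequence[float]] = None,
    enzyme_fraction: float = 0.01,
) -> dict:
    """Cross-check the closed forms against simulated initial velocities.

    Runs multi-turnover simulations (enzyme at ``enzyme_fraction`` of the
    smallest substrate concentration) across a substrate grid spanning
    0.1-10 x Km, fits the hyperbolic rate law v = Vmax*S/(Km+S), and
    reports the simulated kcat and Km with their relative deviation from
    the closed forms.
    """
    closed = steady_state_params(rates)
    if S_grid is None:
        S_grid = np.geomspace(0.1 * closed.Km, 10.0 * closed.Km, 7)
    S_grid = np.asarray(S_grid, float)
    E0 = enzyme_fraction * float(S_grid.min())
    v = np.array([
        _initial_velocity(rates, E0, S, closed.kcat * E0 * S / (closed.Km + S))
        for S in S_grid
    ])

    def mm(S, Vmax, Km):
        return Vmax * S / (Km + S)

    p0 = (1.2 * v.max(), float(np.median(S_grid)))
    popt, _ = curve_fit(mm, S_grid, v, p0=p0, maxfev=20000)
    kcat_sim = float(popt[0] / E0)
    Km_sim = float(popt[1])
    dev = max(
        abs(kcat_sim - closed.kcat) / closed.kcat,
        abs(Km_sim - closed.Km) / closed.Km,
    )
    return {
        "kcat_sim": kcat_sim,
        "Km_sim": Km_sim,
        "kcat_closed": closed.kcat,
        "Km_closed": closed.Km,
        "max_rel_deviation": float(dev),
    }


def fold_changes(reference: RateConstants, variant: RateConstants) -> dict:
    """Reference/variant ratios for k2, k2r, k3 and the equilibria K1, K2.

    Entries whose variant value is zero are reported as NaN (undefined).
    """
    out = {}
    for name in ("k2", "k2r", "k3"):
        ref, var = getattr(reference, name), getattr(variant, name)
        out[name] = ref / var if var > 0 else float("nan")
    for name in ("K1", "K2"):
        try:
            ref = getattr(reference, name)
            var = getattr(variant, name)
            out[name] = ref / var if var > 0 else float("nan")
        except ZeroDivisionError:
            out[name] = float("nan")
    return out
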