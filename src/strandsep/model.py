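"""Global fitting of the strand-separation mechanism to multiple experiments.

`GlobalKineticModel` bundles a set of traces (tryptophan fluorescence,
pyrrolocytosine fluorescence and radiochemical product time courses) with
the mechanism's rate constants and observable coefficients, and fits every
floating parameter simultaneously by weighted nonlinear least squares.
`fit()` returns a `GlobalFitResults` object carrying the estimates,
residuals and diagnostics; profile-likelihood confidence intervals and
steady-state constants hang off the results object.

The optimizer is trust-region-reflective least squares run, by default, on
log-transformed rate constants and output scales (which enforces
positivity without penalties), with a seeded multistart around the initial
guess.  Simulated species trajectories are cached per rate-constant
vector, so finite-difference steps in the (linear) observable coefficients
cost no additional ODE solves.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .mechanism import (
    RATE_NAMES,
    IntegrationError,
    RateConstants,
    SpeciesState,
    integrate,
)
from .observables import COEFF_NAMES, ObservableCoefficients, Trace, signal

__all__ = [
    "GlobalKineticModel",
    "GlobalFitResults",
    "estimate_noise_sd",
    "initial_rate_guess",
    "linear_coefficient_seed",
]

log = logging.getLogger(__name__)

#: Default box bounds (natural scale) for floating parameters by class.
DEFAULT_RATE_BOUNDS = (1e-7, 1e6)
DEFAULT_SCALE_BOUNDS = (0.8, 1.25)
DEFAULT_COEFF_BOUNDS = (0.0, 1e3)
DEFAULT_OUTPUT_SCALE_BOUNDS = (1e-6, 1e6)

_PENALTY = 1e4


def estimate_noise_sd(times: np.ndarray, y: np.ndarray) -> float:
    """Per-trace noise SD from the residual of a smoothing filter.

    A Savitzky-Golay detrend separates the (smooth) kinetic signal from
    point-to-point scatter; the residual RMS estimates sigma.
    """
    n = y.size
    if n < 7:
        d = np.diff(y)
        return float(np.sqrt(np.mean(d**2) / 2.0)) if d.size else 0.0
    window = min(n if n % 2 else n - 1, max(7, 2 * (n // 20) + 1))
    smooth = savgol_filter(y, window, polyorder=3)
    return float(np.sqrt(np.mean((y - smooth) ** 2)))


@dataclass
class _FloatSpec:
    name: str
    kind: str          # 'rate' | 'coeff' | 'scale'
    log: bool
    lo: float
    hi: float
    index: int = 0     # trace index for scale factors


class GlobalKineticModel:
    """A global kinetic fitting problem over a collection of traces.

    Parameters
    ----------
    traces : sequence of Trace
        The experiments; each carries its own design (observable kind,
        concentrations, dead time).
    rates : RateConstants
        Initial values with lock flags.  Locked constants are held
        bit-identical through the fit.
    coeffs : ObservableCoefficients, optional
        Initial observable coefficients with lock flags.
    weights : 'auto' | 'unit' | sequence of float
        Per-trace 1/sigma weighting.  'auto' estimates sigma per trace
        (replicate SD where available, smoothing-filter residual
        otherwise); 'unit' uses sigma = 1 everywhere.
    scale_factors : 'locked' | 'float'
        Whether per-trace fluorescence normalization factors float
        (bounded near unity).  They default to locked at 1 because with a
        floating shared output scale only the products are identified.
    transform : 'log' | 'linear'
        Parameterization of positive rate constants and output scales
        during optimization.
    """

    def __init__(
        self,
        traces: Sequence[Trace],
        rates: RateConstants,
        coeffs: Optional[ObservableCoefficients] = None,
        *,
        weights="auto",
        scale_factors: str = "locked",
        transform: str = "log",
        bounds: Optional[Mapping[str, tuple]] = None,
        rtol: float = 1e-8,
        atol: float = 1e-12,
    ):
        self.traces = list(traces)
        if not self.traces:
            raise ValueError("at least one trace is required")
        self.rates0 = rates
        self.coeffs0 = coeffs if coeffs is not None else ObservableCoefficients()
        if scale_factors not in ("locked", "float"):
            raise ValueError("scale_factors must be 'locked' or 'float'")
        if transform not in ("log", "linear"):
            raise ValueError("transform must be 'log' or 'linear'")
        self.scale_mode = scale_factors
        self.transform = transform
        self.rtol, self.atol = rtol, atol
        self._bounds = dict(bounds or {})
        self._sigmas = self._build_sigmas(weights)
        self._floats = self._build_floats()
        self._cache: OrderedDict = OrderedDict()
        self._cache_max = 64
        self.n_obs = int(sum(tr.times.size for tr in self.traces))

    # ------------------------------------------------------------------
    # problem assembly
    def _build_sigmas(self, weights):
        sigmas = []
        if weights == "unit":
            return [np.ones_like(tr.signal) for tr in self.traces]
        if weights == "auto":
            for tr in self.traces:
                amp = max(tr.amplitude, 1e-12)
                if tr.sd is not None and np.all(tr.sd > 0):
                    s = np.maximum(tr.sd, 1e-4 * amp)
                else:
                    est = estimate_noise_sd(tr.times, tr.signal)
                    s = np.full_like(tr.signal, max(est, 1e-3 * amp))
                sigmas.append(s)
            return sigmas
        if len(weights) != len(self.traces):
            raise ValueError("one weight per trace required")
        for w, tr in zip(weights, self.traces):
            if w <= 0:
                raise ValueError("weights must be positive")
            sigmas.append(np.full_like(tr.signal, 1.0 / w))
        return sigmas

    def _bounds_for(self, name, kind):
        if name in self._bounds:
            return self._bounds[name]
        if kind == "rate":
            return DEFAULT_RATE_BOUNDS
        if kind == "scale":
            return DEFAULT_SCALE_BOUNDS
        if name in ("a1", "a3"):
            return DEFAULT_OUTPUT_SCALE_BOUNDS
        return DEFAULT_COEFF_BOUNDS

    def _build_floats(self):
        floats = []
        use_log = self.transform == "log"
        for n in self.rates0.floating():
            lo, hi = self._bounds_for(n, "rate")
            floats.append(_FloatSpec(n, "rate", use_log, lo, hi))
        used_kinds = {tr.design.kind for tr in self.traces}
        for n in self.coeffs0.floating():
            if n.startswith(("a1", "pydc")) and "pydc" not in used_kinds:
                continue
            if n.startswith(("a3", "trp")) and "trp" not in used_kinds:
                continue
            if n == "bkg2" and "radio" not in used_kinds:
                continue
            lo, hi = self._bounds_for(n, "coeff")
            floats.append(_FloatSpec(n, "coeff", use_log and n in ("a1", "a3"), lo, hi))
        if self.scale_mode == "float":
            for i, tr in enumerate(self.traces):
                if tr.design.kind in ("pydc", "trp"):
                    lo, hi = self._bounds_for(f"scale_{i}", "scale")
                    floats.append(_FloatSpec(f"scale_{i}", "scale", False, lo, hi, index=i))
        return floats

    @property
    def float_names(self) -> tuple:
        return tuple(f.name for f in self._floats)

    @property
    def n_floats(self) -> int:
        return len(self._floats)

    def _initial_values(self) -> dict:
        vals = {}
        for f in self._floats:
            if f.kind == "rate":
                vals[f.name] = getattr(self.rates0, f.name)
            elif f.kind == "coeff":
                vals[f.name] = getattr(self.coeffs0, f.name)
            else:
                vals[f.name] = 1.0
        return vals

    # ------------------------------------------------------------------
    # parameter packing
    def _active(self, clamp):
        clamp = clamp or {}
        unknown = set(clamp) - set(self.float_names)
        if unknown:
            raise ValueError(
                f"cannot clamp {sorted(unknown)}: not floating parameters "
                f"(floating: {list(self.float_names)})"
            )
        return [f for f in self._floats if f.name not in clamp]

    def _pack(self, values: Mapping[str, float], clamp=None) -> np.ndarray:
        x = []
        for f in self._active(clamp):
            v = float(values[f.name])
            x.append(np.log(v) if f.log else v)
        return np.array(x)

    def _unpack(self, x: np.ndarray, clamp=None) -> dict:
        vals = dict(clamp or {})
        for f, xi in zip(self._active(clamp), x):
            vals[f.name] = float(np.exp(xi)) if f.log else float(xi)
        return vals

    def _pack_bounds(self, clamp=None):
        lo, hi = [], []
        for f in self._active(clamp):
            if f.log:
                lo.append(np.log(max(f.lo, 1e-300)))
                hi.append(np.log(f.hi))
            else:
                lo.append(f.lo)
                hi.append(f.hi)
        return np.array(lo), np.array(hi)

    def _assemble(self, values: Mapping[str, float]):
        rate_upd = {n: values[n] for n in self.float_names
                    if n in RATE_NAMES and n in values}
        coeff_upd = {n: values[n] for n in self.float_names
                     if n in COEFF_NAMES and n in values}
        rates = self.rates0.replace(**rate_upd) if rate_upd else self.rates0
        coeffs = self.coeffs0.replace(**coeff_upd) if coeff_upd else self.coeffs0
        scales = np.ones(len(self.traces))
        for f in self._floats:
            if f.kind == "scale" and f.name in values:
                scales[f.index] = values[f.name]
        return rates, coeffs, scales

    # ------------------------------------------------------------------
    # simulation with trajectory caching
    def _trajectories(self, rates: RateConstants):
        key = tuple(rates.values())
        hit = self._cache.get(key)
        if hit is not None:
            self._cache.move_to_end(key)
            return hit
        trajs = []
        for tr in self.traces:
            d = tr.design
            init = SpeciesState(E=d.E_total, S=d.S_total)
            trajs.append(integrate(rates, init, d.model_times,
                                   rtol=self.rtol, atol=self.atol))
        self._cache[key] = trajs
        if len(self._cache) > self._cache_max:
            self._cache.popitem(last=False)
        return trajs

    def predict(self, values: Optional[Mapping[str, float]] = None):
        """Model signal for every trace at the given (or initial) values."""
        vals = dict(self._initial_values())
        if values:
            vals.update(values)
        rates, coeffs, scales = self._assemble(vals)
        trajs = self._trajectories(rates)
        return [signal(tj, tr.design.kind, coeffs, sc)
                for tj, tr, sc in zip(trajs, self.traces, scales)]

    def objective(self, x: np.ndarray, clamp=None) -> np.ndarray:
        """Weighted residual vector at a packed parameter point.

        Integration failures return a flat penalty vector (and a warning)
        so the optimizer can back away rather than abort.
        """
        vals = self._unpack(np.asarray(x, float), clamp)
        rates, coeffs, scales = self._assemble(vals)
        try:
            trajs = self._trajectories(rates)
        except IntegrationError as err:
            log.debug("integration failed during fit: %s", err)
            return np.full(self.n_obs, _PENALTY)
        out = []
        for tj, tr, sg, sc in zip(trajs, self.traces, self._sigmas, scales):
            y = signal(tj, tr.design.kind, coeffs, sc)
            out.append((y - tr.signal) / sg)
        return np.concatenate(out)

    def ssr(self, values: Mapping[str, float]) -> float:
        r = self.objective(self._pack(values))
        return float(r @ r)

    def _unweighted_ssr(self, values) -> float:
        preds = self.predict(values)
        return float(sum(np.sum((p - tr.signal) ** 2)
                         for p, tr in zip(preds, self.traces)))

    @property
    def data_scale(self) -> float:
        """Sum of squared data values, the natural SSR normalizer."""
        return float(sum(np.sum(tr.signal**2) for tr in self.traces))

    # ------------------------------------------------------------------
    def fit(
        self,
        start_values: Optional[Mapping[str, float]] = None,
        *,
        multistart: int = 8,
        seed: Optional[int] = None,
        clamp: Optional[Mapping[str, float]] = None,
        ftol: float = 1e-10,
        xtol: float = 1e-12,
        max_nfev: Optional[int] = None,
    ) -> "GlobalFitResults":
        """Minimize the weighted SSR over all floating parameters.

        The first start is the initial guess itself; the remaining
        ``multistart - 1`` starts perturb every floating rate constant by
        a seeded random factor of up to 3 either way and re-seed the
        (linear) observable coefficients at those rates.  The best
        converged start is returned; locked parameters are untouched.
        """
        active = self._active(clamp)
        if not active:
            raise ValueError("nothing to fit: every parameter is locked or clamped")
        vals0 = self._initial_values()
        if start_values:
            vals0.update({k: v for k, v in start_values.items() if k in vals0})
        lo, hi = self._pack_bounds(clamp)
        x0 = np.clip(self._pack(vals0, clamp), lo, hi)

        rng = np.random.default_rng(seed)
        coeff_floats = [f for f in active if f.kind == "coeff"]
        starts = [x0]
        for _ in range(max(0, multistart - 1)):
            vd = dict(vals0)
            for f in active:
                if f.kind == "rate":
                    vd[f.name] *= float(np.exp(rng.uniform(-np.log(3.0), np.log(3.0))))
            if coeff_floats:
                try:
                    rates_p, _, _ = self._assemble({**vd, **(clamp or {})})
                    cs = linear_coefficient_seed(
                        self.traces, rates_p, self.coeffs0, self.rtol, self.atol
                    )
                    for f in coeff_floats:
                        v = getattr(cs, f.name)
                        vd[f.name] = max(v, 1e-6) if f.log else v
                except IntegrationError:
                    pass
            starts.append(np.clip(self._pack(vd, clamp), lo, hi))

        best = None
        diagnostics = []
        for i, xs in enumerate(starts):
            try:
                # finite-difference step well above the ODE-solver noise floor
                sol = least_squares(
                    self.objective, xs, bounds=(lo, hi), method="trf",
                    ftol=ftol, xtol=xtol, gtol=1e-12, diff_step=1e-4,
                    max_nfev=max_nfev, kwargs={"clamp": clamp},
                )
                diagnostics.append(
                    {"start": i, "cost": 2 * sol.cost, "nfev": sol.nfev,
                     "status": sol.status, "message": sol.message}
                )
                # status 0 (nfev budget exhausted) still yields a usable point
                if sol.status >= 0 and (best is None or sol.cost < best.cost):
                    best = sol
            except Exception as err:  # keep other starts alive
                diagnostics.append({"start": i, "error": str(err)})
                log.warning("start %d failed: %s", i, err)
        if best is None:
            raise RuntimeError(f"all {len(starts)} starts failed: {diagnostics}")

        vals = self._unpack(best.x, clamp)
        rates, coeffs, scales = self._assemble(vals)
        ssr = float(2 * best.cost)
        resid = best.fun
        per_trace = []
        off = 0
        for tr in self.traces:
            n = tr.times.size
            per_trace.append(resid[off:off + n].copy())
            off += n
        return GlobalFitResults(
            model=self,
            rates=rates,
            coeffs=coeffs,
            scale_factors=scales,
            values=vals,
            ssr=ssr,
            ssr_unweighted=self._unweighted_ssr(vals),
            residuals=per_trace,
            float_names=tuple(f.name for f in active),
            clamp=dict(clamp or {}),
            diagnostics=diagnostics,
            nfev=int(sum(d.get("nfev", 0) for d in diagnostics)),
        )


@dataclass
class GlobalFitResults:
    """Estimates and diagnostics from a global fit.

    ``float_names`` records the parameter ordering used by the optimizer;
    ``values`` maps every fitted (and clamped) parameter to its value.
    """

    model: GlobalKineticModel
    rates: RateConstants
    coeffs: ObservableCoefficients
    scale_factors: np.ndarray
    values: dict
    ssr: float
    ssr_unweighted: float
    residuals: list
    float_names: tuple
    clamp: dict = field(default_factory=dict)
    diagnostics: list = field(default_factory=list)
    nfev: int = 0

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def n_floats(self) -> int:
        return len(self.float_names)

    def predicted(self):
        return self.model.predict(self.values)

    def profile(self, name: str, **kwargs):
        """Profile-likelihood confidence interval for one parameter."""
        from .profile import profile_parameter
        return profile_parameter(self.model, self, name, **kwargs)

    def steady_state(self):
        from .steadystate import steady_state_params
        return steady_state_params(self.rates)

    def ci_table(self, profiles=()):
        from .profile import ci_table
        return ci_table(profiles, best_values=self.values)

    def summary(self) -> str:
        lines = ["Global kinetic fit", "=" * 48]
        lines.append(f"traces: {len(self.model.traces)}   points: {self.n_obs}   "
                     f"floating: {self.n_floats}")
        lines.append(f"weighted SSR: {self.ssr:.6g}   "
                     f"unweighted SSR: {self.ssr_unweighted:.6g}")
        lines.append("-" * 48)
        lines.append("rate constants (1/s; k1, k4r in 1/(uM*s)):")
        for n in RATE_NAMES:
            tag = "locked" if n in self.rates.locked else "fitted"
            lines.append(f"  {n:<4} = {getattr(self.rates, n):<12.6g} [{tag}]")
        lines.append(f"  K1 = {self.rates.K1:.4g} 1/uM   K2 = {self.rates.K2:.4g}")
        lines.append("observable coefficients:")
        for n in COEFF_NAMES:
            tag = "locked" if n in self.coeffs.locked else "fitted"
            lines.append(f"  {n:<9} = {getattr(self.coeffs, n):<12.6g} [{tag}]")
        if self.model.scale_mode == "float":
            sf = ", ".join(f"{s:.4f}" for s in self.scale_factors)
            lines.append(f"per-trace scale factors: {sf}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.to_dict(),
            "locked_rates": sorted(self.rates.locked),
            "coefficients": self.coeffs.to_dict(),
            "locked_coefficients": sorted(self.coeffs.locked),
            "scale_factors": [float(s) for s in self.scale_factors],
            "ssr": self.ssr,
            "ssr_unweighted": self.ssr_unweighted,
            "float_names": list(self.float_names),
            "values": {k: float(v) for k, v in self.values.items()},
            "n_obs": self.n_obs,
            "nfev": self.nfev,
        }

    def plot(self, axes=None):
        """Overlay data and fitted curves, one panel per observable kind."""
        import matplotlib.pyplot as plt

        kinds = []
        for tr in self.model.traces:
            if tr.design.kind not in kinds:
                kinds.append(tr.design.kind)
        if axes is None:
            _, axes = plt.subplots(1, len(kinds), figsize=(4.2 * len(kinds), 3.2))
            axes = np.atleast_1d(axes)
        preds = self.predicted()
        for ax, kind in zip(np.ravel(axes), kinds):
            for tr, p in zip(self.model.traces, preds):
                if tr.design.kind != kind:
                    continue
                ax.plot(tr.times, tr.signal, ".", ms=2, alpha=0.4)
                ax.plot(tr.times, p, "-", lw=1.2)
            ax.set_xlabel("time (s)")
            ax.set_ylabel("product (uM)" if kind == "radio" else "fluorescence (a.u.)")
            ax.set_title(kind)
            if kind != "radio":
                ax.set_xscale("log")
        return axes


# ----------------------------------------------------------------------
# fit seeding helpers
def initial_rate_guess(traces: Sequence[Trace], template: RateConstants) -> RateConstants:
    """Seed rate constants from single-trace exponential pre-fits.

    The fast phase of the highest-enzyme pyrrolocytosine trace
    approximates the strand-separation relaxation k2 + k2r.  The observed
    rate of the radiochemical product curve approximates k3 times the
    substrate occupancy, so the pre-fit rate is divided by the occupancy
    implied by the (template or pre-fit) binding constants; at
    sub-saturating enzyme this correction is large.  Constants that
    cannot be read off a pre-fit keep the template values.
    """
    from .prefit import PrefitError, fit_double_exponential, fit_one_phase_decay

    upd = {}
    pydc = [tr for tr in traces if tr.design.kind == "pydc"]
    if pydc:
        tr = max(pydc, key=lambda t: t.design.E_total)
        try:
            fast = fit_double_exponential(tr).rates[0]
            if np.isfinite(fast) and fast > 0:
                upd["k2"] = 2.0 * fast / 3.0
                upd["k2r"] = fast / 3.0
        except PrefitError:
            pass
    radio = [tr for tr in traces if tr.design.kind == "radio"]
    if radio:
        try:
            rate = fit_one_phase_decay(radio[0]).rates[0]
            if np.isfinite(rate) and rate > 0:
                K1 = template.K1 if template.k1r > 0 else 1.0
                k2 = upd.get("k2", template.k2)
                k2r = upd.get("k2r", template.k2r)
                K2 = k2 / k2r if k2r > 0 else 1.0
                E = radio[0].design.E_total
                occ = K1 * (1.0 + K2) * E / (1.0 + K1 * (1.0 + K2) * E)
                upd["k3"] = float(np.clip(rate / max(occ, 0.05), rate, 20 * rate))
        except PrefitError:
            pass
    upd = {k: v for k, v in upd.items() if k not in template.locked}
    return template.replace(**upd) if upd else template


def linear_coefficient_seed(
    traces: Sequence[Trace],
    rates: RateConstants,
    coeffs: Optional[ObservableCoefficients] = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> ObservableCoefficients:
    """Least-squares seed for the observable coefficients at fixed rates.

    Every fluorescence signal is linear in (a1, a1*e, a1*f, a1*h) and
    (a3, a3*k, a3*m, a3*n) respectively, so for a given rate-constant
    vector the coefficient subproblem has a closed-form solution; the
    ratios recover the per-species factors.  Used to initialize the
    global fit.
    """
    coeffs = coeffs if coeffs is not None else ObservableCoefficients()
    upd = {}
    for kind, names in (
        ("pydc", ("a1", "pydc_gsi", "pydc_gsp", "pydc_sp")),
        ("trp", ("a3", "trp_fs", "trp_gsi", "trp_gsp")),
    ):
        sel = [tr for tr in traces if tr.design.kind == kind]
        if not sel:
            continue
        blocks, ys = [], []
        for tr in sel:
            d = tr.design
            tj = integrate(rates, SpeciesState(E=d.E_total, S=d.S_total),
                           d.model_times, rtol=rtol, atol=atol)
            s = tj.states
            if kind == "pydc":
                base, comps = s[:, 1] + s[:, 2], (s[:, 3], s[:, 4], s[:, 5])
            else:
                base, comps = s[:, 0], (s[:, 2], s[:, 3], s[:, 4])
            blocks.append(np.column_stack([base, *comps]))
            ys.append(tr.signal)
        A = np.vstack(blocks)
        y = np.concatenate(ys)
        p, *_ = np.linalg.lstsq(A, y, rcond=None)
        if p[0] > 1e-9:
            upd[names[0]] = float(p[0])
            for nm, pi in zip(names[1:], p[1:]):
                upd[nm] = float(max(pi / p[0], 0.0))
    upd = {k: v for k, v in upd.items() if k not in coeffs.locked}
    return coeffs.replace(**upd) if upd else coeffs
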