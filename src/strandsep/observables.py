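"""Experimental observables: fluorescence and radiochemical signal models.

Three signal classes report on the mechanism:

* ``pydc``  — pyrrolocytosine fluorescence of the DNA, reporting strand
  separation:  a1 * (S + FS + e*GS^I + f*GSp + h*Sp)
* ``trp``   — intrinsic tryptophan fluorescence of the enzyme, reporting
  binding and conformational change:  a3 * (E + k*FS + m*GS^I + n*GSp)
* ``radio`` — radiochemical product quantification:  GSp + Sp + bkg2

Fluorescence amplitudes are arbitrary; the absolute scale is carried by
the output factors a1/a3 and optional per-trace scale factors.
Stopped-flow traces miss the first ~2.5 ms after mixing; the model is
evaluated at observed time + dead time so the first recorded point
corresponds to that reaction age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .mechanism import Trajectory

__all__ = [
    "ObservableCoefficients",
    "ExperimentDesign",
    "Trace",
    "signal",
    "apply_dead_time",
    "OBSERVABLE_KINDS",
    "COEFF_NAMES",
]

OBSERVABLE_KINDS = ("trp", "pydc", "radio")

#: Fitting-parameter names exposed by ObservableCoefficients, in canonical
#: order.  The pydc species factors are written e/f/h and the trp factors
#: k/m/n in the kinetics literature.
COEFF_NAMES = (
    "a1", "pydc_gsi", "pydc_gsp", "pydc_sp",
    "a3", "trp_fs", "trp_gsi", "trp_gsp",
    "bkg2",
)


@dataclass(frozen=True)
class ObservableCoefficients:
    """Fluorescence factors and radiochemical background.

    ``a1``/``a3`` are overall output scales (must be positive); the
    per-species factors are dimensionless relative fluorescence yields;
    ``bkg2`` is a radiochemical background in uM product equivalents.
    """

    a1: float = 1.0
    pydc_gsi: float = 1.0   # e
    pydc_gsp: float = 1.0   # f
    pydc_sp: float = 1.0    # h
    a3: float = 1.0
    trp_fs: float = 1.0     # k
    trp_gsi: float = 1.0    # m
    trp_gsp: float = 1.0    # n
    bkg2: float = 0.0
    locked: frozenset = field(default=frozenset({"bkg2"}))

    def __post_init__(self):
        if self.a1 <= 0 or self.a3 <= 0:
            raise ValueError("output scales a1 and a3 must be > 0")
        for name in COEFF_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"coefficient {name} must be >= 0")
        unknown = set(self.locked) - set(COEFF_NAMES)
        if unknown:
            raise ValueError(f"unknown coefficients in locks: {sorted(unknown)}")
        object.__setattr__(self, "locked", frozenset(self.locked))

    def replace(self, **kwargs) -> "ObservableCoefficients":
        return replace(self, **kwargs)

    def floating(self) -> tuple:
        return tuple(n for n in COEFF_NAMES if n not in self.locked)

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in COEFF_NAMES}


@dataclass(frozen=True)
class ExperimentDesign:
    """Post-mix composition and acquisition settings of one experiment."""

    kind: str                      # trp | pydc | radio
    E_total: float                 # uM enzyme (functional units)
    S_total: float                 # uM duplex DNA
    times: np.ndarray              # observed (instrument) times, s
    dead_time: float = 0.0         # s
    replicates: int = 3
    trace_id: str = ""

    def __post_init__(self):
        if self.kind not in OBSERVABLE_KINDS:
            raise ValueError(f"unknown observable kind {self.kind!r}")
        if self.E_total <= 0 or self.S_total <= 0:
            raise ValueError("concentrations must be > 0")
        if self.dead_time < 0:
            raise ValueError("dead time must be >= 0")
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a non-empty increasing 1-D grid")
        object.__setattr__(self, "times", t)

    @property
    def model_times(self) -> np.ndarray:
        """Reaction-age grid at which the model is evaluated."""
        return apply_dead_time(self.times, self.dead_time)


@dataclass
class Trace:
    """A measured or synthetic signal series attached to its design."""

    design: ExperimentDesign
    times: np.ndarray
    signal: np.ndarray
    sd: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape:
                raise ValueError("sd must match the signal length")

    @property
    def amplitude(self) -> float:
        return float(np.ptp(self.signal))


def apply_dead_time(observed_times, dead_time: float) -> np.ndarray:
    """Shift instrument times to reaction ages (additive, order preserving)."""
    if dead_time < 0:
        raise ValueError("dead time must be >= 0")
    return np.asarray(observed_times, dtype=float) + dead_time


def signal(
    trajectory: Trajectory,
    kind: str,
    coeffs: ObservableCoefficients,
    scale: float = 1.0,
) -> np.ndarray:
    """Evaluate an observable on a trajectory's own time grid.

    ``scale`` is the per-trace normalization factor (default 1).
    """
    s = trajectory.states
    E, S, FS, GSI, GSp, Sp = (s[:, i] for i in range(6))
    if kind == "pydc":
        y = coeffs.a1 * (
            S + FS + coeffs.pydc_gsi * GSI + coeffs.pydc_gsp * GSp + coeffs.pydc_sp * Sp
        )
    elif kind == "trp":
        y = coeffs.a3 * (
            E + coeffs.trp_fs * FS + coeffs.trp_gsi * GSI + coeffs.trp_gsp * GSp
        )
    elif kind == "radio":
        y = GSp + Sp + coeffs.bkg2
    else:
        raise ValueError(f"unknown observable kind {kind!r}")
    return scale * y
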