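"""Trace-file and configuration I/O plus result reporting.

Trace dialect: comma-separated text, '.' decimal, a `#`-prefixed header
block carrying the design metadata, then a column header and data rows:

    # observable=pydc
    # E_total_uM=2.5
    # S_total_uM=1.0
    # dead_time_s=0.0025
    # trace_id=pydc_E2.5
    time_s,signal[,sd]
    0.0005,1.0023
    ...

Parameter configs are YAML mappings of name -> {value, locked, bounds}.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .mechanism import RATE_NAMES, RateConstants, Trajectory
from .observables import (
    COEFF_NAMES,
    OBSERVABLE_KINDS,
    ExperimentDesign,
    ObservableCoefficients,
    Trace,
)

__all__ = [
    "read_trace",
    "write_trace",
    "write_trajectory",
    "read_rate_config",
    "write_rate_config",
    "read_coeff_config",
    "TraceParseError",
    "report",
]

_REQUIRED_HEADERS = ("observable", "E_total_uM", "S_total_uM", "dead_time_s")


class TraceParseError(ValueError):
    pass


def write_trace(path, trace: Trace) -> None:
    d = trace.design
    with open(path, "w") as fh:
        fh.write(f"# observable={d.kind}\n")
        fh.write(f"# E_total_uM={d.E_total:.10g}\n")
        fh.write(f"# S_total_uM={d.S_total:.10g}\n")
        fh.write(f"# dead_time_s={d.dead_time:.10g}\n")
        fh.write(f"# trace_id={d.trace_id}\n")
        cols = "time_s,signal" + (",sd" if trace.sd is not None else "")
        fh.write(cols + "\n")
        for i, (t, y) in enumerate(zip(trace.times, trace.signal)):
            row = f"{t:.10g},{y:.10g}"
            if trace.sd is not None:
                row += f",{trace.sd[i]:.10g}"
            fh.write(row + "\n")


def read_trace(path) -> Trace:
    """Parse a trace file; raises TraceParseError naming the bad line."""
    path = Path(path)
    meta = {}
    rows = []
    columns = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise TraceParseError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    )
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            elif columns is None:
                columns = [c.strip() for c in line.split(",")]
                if columns[:2] != ["time_s", "signal"]:
                    raise TraceParseError(
                        f"{path}:{lineno}: expected columns time_s,signal[,sd], "
                        f"got {line!r}"
                    )
            else:
                parts = line.split(",")
                if len(parts) != len(columns):
                    raise TraceParseError(
                        f"{path}:{lineno}: expected {len(columns)} fields, "
                        f"got {len(parts)}"
                    )
                try:
                    rows.append([float(p) for p in parts])
                except ValueError:
                    raise TraceParseError(
                        f"{path}:{lineno}: non-numeric value in {line!r}"
                    ) from None
    for key in _REQUIRED_HEADERS:
        if key not in meta:
            raise TraceParseError(f"{path}: missing required header '# {key}='")
    kind = meta["observable"]
    if kind not in OBSERVABLE_KINDS:
        raise TraceParseError(f"{path}: unknown observable {kind!r}")
    if not rows:
        raise TraceParseError(f"{path}: no data rows")
    data = np.array(rows)
    design = ExperimentDesign(
        kind=kind,
        E_total=float(meta["E_total_uM"]),
        S_total=float(meta["S_total_uM"]),
        times=data[:, 0],
        dead_time=float(meta["dead_time_s"]),
        trace_id=meta.get("trace_id", path.stem),
    )
    sd = data[:, 2] if data.shape[1] > 2 else None
    return Trace(design, data[:, 0], data[:, 1], sd=sd)


def write_trajectory(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        fh.write("time_s,E,S,FS,GSI,GSp,Sp\n")
        for t, row in zip(traj.times, traj.states):
            fh.write(",".join(f"{v:.10g}" for v in (t, *row)) + "\n")


def read_rate_config(source) -> RateConstants:
    """Build RateConstants from a YAML mapping (path, text or dict)."""
    cfg = _load_yaml(source)
    unknown = set(cfg) - set(RATE_NAMES)
    if unknown:
        raise ValueError(f"unknown rate constants in config: {sorted(unknown)}")
    values, locked = {}, set()
    for name, entry in cfg.items():
        if isinstance(entry, dict):
            values[name] = float(entry["value"])
            if entry.get("locked", False):
                locked.add(name)
        else:
            values[name] = float(entry)
    return RateConstants(**values, locked=frozenset(locked))


def write_rate_config(path, rates: RateConstants) -> None:
    doc = {
        n: {"value": float(getattr(rates, n)), "locked": n in rates.locked}
        for n in RATE_NAMES
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_coeff_config(source) -> ObservableCoefficients:
    cfg = _load_yaml(source)
    unknown = set(cfg) - set(COEFF_NAMES)
    if unknown:
        raise ValueError(f"unknown coefficients in config: {sorted(unknown)}")
    values, locked = {}, set()
    for name, entry in cfg.items():
        if isinstance(entry, dict):
            values[name] = float(entry["value"])
            if entry.get("locked", False):
                locked.add(name)
        else:
            values[name] = float(entry)
    return ObservableCoefficients(**values, locked=frozenset(locked))


def _load_yaml(source):
    if isinstance(source, dict):
        return source
    p = Path(source)
    if p.exists():
        with open(p) as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(source)


def report(fit_result, profiles=(), steady=None) -> tuple[str, dict]:
    """Human-readable report plus its JSON-serializable twin.

    Renders a rate-constant table with per-parameter 95% intervals (or
    'n.d.' where no profile was run) and, if supplied, the steady-state
    constants derived from the fitted rates.
    """
    from .profile import format_interval

    by_name = {p.name: p for p in profiles}
    rows = []
    for n in RATE_NAMES:
        best = getattr(fit_result.rates, n)
        p = by_name.get(n)
        if n in fit_result.rates.locked:
            interval = "locked"
        elif p is None:
            interval = "n.d."
        else:
            interval = format_interval(p.best, p.lower, p.upper,
                                       p.lower_open, p.upper_open)
        rows.append({"parameter": n, "best": best, "interval_95": interval})
    rate_table = pd.DataFrame(rows)

    lines = [fit_result.summary(), "", "95% confidence intervals", "-" * 48]
    lines.append(rate_table.to_string(index=False))
    payload = {
        "fit": fit_result.to_dict(),
        "intervals": {
            r["parameter"]: r["interval_95"] for r in rows
        },
    }
    if steady is not None:
        lines += [
            "",
            "steady-state constants",
            "-" * 48,
            f"kcat        = {steady.kcat:.4g} 1/s",
            f"Km          = {steady.Km:.4g} uM",
            f"kcat/Km     = {steady.kcat_over_Km:.4g} 1/(uM*s)",
        ]
        payload["steady_state"] = {
            "kcat": steady.kcat, "Km": steady.Km,
            "kcat_over_Km": steady.kcat_over_Km,
        }
    text = "\n".join(lines)
    json.dumps(payload)  # guarantee serializability
    return text, payload
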