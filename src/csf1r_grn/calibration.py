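"""Calibration utilities: qPCR-style datasets, least-squares fitting, and
qualitative trajectory classification.

The measured quantity is mRNA relative to a reference gene (beta-actin),
sampled at a handful of time points with a few replicates. Conditions map
onto simulation protocols:

=====================  ==========================================
``basal``              no LPS, from the basal state
``lps``                LPS = 1 step at t = 0
``washout``            LPS = 1 for 36 h, then none
``kd:<COMP>:<frac>``   no LPS, component's synthesis scaled to the
                       residual fraction (siRNA emulation)
=====================  ==========================================

Fitting operates on log-parameters (rates are positive and span orders
of magnitude) with bounded multi-start least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import build_model
from .network import NetworkDefinition
from .params import ParameterSet
from .simulate import ExperimentProtocol, run

__all__ = [
    "QpcrDataset",
    "FitResult",
    "condition_protocol",
    "objective",
    "fit",
    "classify_trajectory",
    "qualitative_fit_report",
    "EXPECTED_LPS_CLASSES",
]

COLUMNS = ["condition", "component", "time_h", "replicate", "value"]

#: trajectory classes reported for the LPS response in the source experiments
EXPECTED_LPS_CLASSES = {
    "STAT1": "fast-rise",
    "STAT3": "fast-rise",
    "CSF1": "delayed-rise",
    "IRF8": "delayed-rise",
    "TNFR1": "delayed-rise",
    "NFKB": "transient-rise",
    "IL6R": "transient-dip",
    "CEBPA": "transient-dip",
}


@dataclass
class QpcrDataset:
    """Tidy replicate-level table of reference-gene-relative mRNA values."""

    records: pd.DataFrame
    normalization: str = "2^-dCt"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing column(s): {missing}")
        if (self.records["value"] < 0).any():
            raise ValueError("qPCR-style values must be non-negative")

    def conditions(self) -> list[str]:
        return sorted(self.records["condition"].unique())

    def means(self) -> pd.DataFrame:
        """Replicate means (and SD) per condition/component/time."""
        g = self.records.groupby(["condition", "component", "time_h"])["value"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"std": "sd", "count": "n"})

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "QpcrDataset":
        return cls(pd.read_csv(path), **kw)


def condition_protocol(condition: str, horizon_h: float) -> ExperimentProtocol:
    if condition == "basal":
        return ExperimentProtocol.basal(horizon_h)
    if condition == "lps":
        return ExperimentProtocol.lps_step(horizon_h)
    if condition == "washout":
        return ExperimentProtocol.washout(min(36.0, horizon_h), horizon_h)
    if condition.startswith("kd:"):
        _, comp, frac = condition.split(":")
        residual = 1.0 - float(frac)
        return ExperimentProtocol.lps_step(horizon_h, lps=0.0,
                                           synthesis_scale={comp: residual})
    raise ValueError(f"condition {condition!r} is not expressible as a protocol")


def _residuals(net, params, data: QpcrDataset, weighting: str, model_cache: dict):
    means = data.means()
    res = []
    key = tuple(sorted(params.to_dict().items()))
    model = model_cache.get(key)
    if model is None:
        model = build_model(net, params)
        model_cache.clear()
        model_cache[key] = model
    for cond, sub in means.groupby("condition"):
        times = np.unique(sub["time_h"].to_numpy(dtype=float))
        proto = condition_protocol(cond, float(times.max()) if times.max() > 0 else 1.0)
        tc = run(net, params, proto, grid=times, model=model)
        frame = tc.mrna_frame()
        for _, row in sub.iterrows():
            sim = float(frame.loc[row["time_h"], row["component"]])
            r = sim - row["mean"]
            if weighting == "1/sd2":
                sd = row["sd"] if np.isfinite(row["sd"]) and row["sd"] > 0 else 1.0
                r = r / sd
            elif weighting == "1/mean2":
                m = max(abs(row["mean"]), 1e-6)
                r = r / m
            elif weighting != "none":
                raise ValueError(f"unknown weighting {weighting!r}")
            res.append((row["component"], r))
    return res


def objective(net: NetworkDefinition, params: ParameterSet, data: QpcrDataset,
              weighting: str = "none") -> float:
    """Weighted sum of squared residuals against replicate means."""
    res = _residuals(net, params, data, weighting, {})
    return float(sum(r * r for _, r in res))


@dataclass
class FitResult:
    params: ParameterSet
    objective: float
    start_objective: float
    per_component_sse: pd.Series
    free: list[str]
    bounds: dict[str, tuple[float, float]]
    seed: int
    restarts: list[dict] = field(default_factory=list)


def fit(net: NetworkDefinition, start: ParameterSet, data: QpcrDataset,
        free: Sequence[str], bounds: dict[str, tuple[float, float]] | None = None,
        restarts: int = 3, seed: int = 0, weighting: str = "none",
        max_nfev: int = 200) -> FitResult:
    """Bounded multi-start least squares over log-parameters.

    ``free`` lists the symbols to optimise; all others stay at ``start``.
    Default bounds span start/30 to start*30. Restart 0 begins at ``start``;
    the rest at log-uniform random points inside the bounds.
    """
    free = list(free)
    unknown = [f for f in free if f not in start]
    if unknown:
        raise KeyError(f"free parameters not in ParameterSet: {unknown}")
    bounds = dict(bounds or {})
    for f in free:
        if f not in bounds:
            bounds[f] = (start[f] / 30.0, start[f] * 30.0)
        lo, hi = bounds[f]
        if lo <= 0 or hi <= lo:
            raise ValueError(f"bounds for {f} must be positive with hi > lo")
    cache: dict = {}

    start_obj = objective(net, start, data, weighting)
    if not free:
        sse = _per_component_sse(net, start, data, weighting)
        return FitResult(start, start_obj, start_obj, sse, free, bounds, seed)

    lo = np.log([bounds[f][0] for f in free])
    hi = np.log([bounds[f][1] for f in free])

    def residual_vec(logx):
        p = start.replace(**{f: float(np.exp(v)) for f, v in zip(free, logx)})
        return np.array([r for _, r in _residuals(net, p, data, weighting, cache)])

    rng = np.random.default_rng(seed)
    x_start = np.clip(np.log([start[f] for f in free]), lo, hi)
    outcomes = []
    for k in range(max(restarts, 1)):
        x0 = x_start if k == 0 else rng.uniform(lo, hi)
        try:
            sol = least_squares(residual_vec, x0, bounds=(lo, hi), max_nfev=max_nfev)
            outcomes.append({"x0": np.exp(x0), "x": np.exp(sol.x),
                             "cost": 2 * sol.cost, "success": bool(sol.success)})
        except Exception as exc:  # keep going; report the failure
            outcomes.append({"x0": np.exp(x0), "x": None, "cost": np.inf,
                             "success": False, "error": str(exc)})
    ok = [o for o in outcomes if o["x"] is not None]
    if not ok:
        raise RuntimeError("all fit restarts failed")
    best = min(ok, key=lambda o: o["cost"])
    fitted = start.replace(**{f: float(v) for f, v in zip(free, best["x"])})
    sse = _per_component_sse(net, fitted, data, weighting)
    return FitResult(fitted, float(best["cost"]), start_obj, sse, free, bounds,
                     seed, outcomes)


def _per_component_sse(net, params, data, weighting) -> pd.Series:
    res = _residuals(net, params, data, weighting, {})
    acc: dict[str, float] = {}
    for comp, r in res:
        acc[comp] = acc.get(comp, 0.0) + r * r
    return pd.Series(acc).sort_index()


# ---------------------------------------------------------------------------
# qualitative trajectory shapes

def classify_trajectory(times: np.ndarray, values: np.ndarray,
                        flat_fraction: float = 0.1) -> str:
    """Label a trajectory {fast-rise, delayed-rise, transient-rise,
    transient-dip, sustained-fall, flat}.

    "Fast" reaches half its net change before a quarter of the horizon;
    "transient" means the endpoint has returned to within half of the peak
    excursion from baseline; amplitudes under ``flat_fraction`` of baseline
    are flat.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    base, end = v[0], v[-1]
    up = float(v.max() - base)
    down = float(base - v.min())
    scale = max(abs(base), 1e-12)
    if max(up, down) < flat_fraction * scale:
        return "flat"
    horizon = t[-1] - t[0]
    if up >= down:  # rising
        if abs(end - base) <= 0.5 * up:
            return "transient-rise"
        thr = base + 0.5 * (end - base)
        t_half = t[np.argmax(v >= thr)]
        return "fast-rise" if t_half - t[0] <= 0.25 * horizon else "delayed-rise"
    if abs(end - base) <= 0.5 * down:
        return "transient-dip"
    return "sustained-fall"


def qualitative_fit_report(net: NetworkDefinition, params: ParameterSet,
                           horizon_h: float = 48.0, lps: float = 1.0,
                           model=None) -> pd.DataFrame:
    """Classify every component's simulated LPS response and compare with
    the experimentally described classes (where one was stated)."""
    grid = np.linspace(0.0, horizon_h, 193)
    tc = run(net, params, ExperimentProtocol.lps_step(horizon_h, lps=lps),
             grid=grid, model=model)
    frame = tc.mrna_frame()
    rows = []
    for comp in frame.columns:
        cls = classify_trajectory(grid, frame[comp].to_numpy())
        expected = EXPECTED_LPS_CLASSES.get(comp)
        rows.append({"component": comp, "simulated": cls, "expected": expected,
                     "match": (cls == expected) if expected else None})
    return pd.DataFrame(rows).set_index("component")
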