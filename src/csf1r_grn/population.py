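"""Heterogeneous cell-population ensembles.

Cell-to-cell variability is modelled as extrinsic parameter noise: each
cell carries its own kinetic constants, drawn once per cell uniformly in
``[p(1-a), p(1+a)]`` around every basal value, and keeps them for the
whole simulation. Hill exponents are treated as structural (shared by
all cells); every rate, threshold and scale parameter varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ModelInputs, basal_state, build_model
from .network import NetworkDefinition
from .params import ParameterSet
from .simulate import ExperimentProtocol, IntegrationError, activated_state, run, settle
from . import bifurcation as _bif

__all__ = [
    "PopulationSpec",
    "PopulationResult",
    "draw_population",
    "population_timecourse",
    "population_steady_states",
    "separatrix_threshold",
]

#: parameters never varied across cells (structural exponents)
STRUCTURAL_PREFIXES = ("n",)  # matches n<id>, na<id>
DEGRADATION_FLOOR = 1e-4      # 1/h; keeps half-lives finite for extreme draws


@dataclass(frozen=True)
class PopulationSpec:
    n_cells: int = 500
    variation: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.variation < 1.0:
            raise ValueError("variation fraction must be in [0, 1)")


@dataclass
class PopulationResult:
    spec: PopulationSpec
    factors: pd.DataFrame          # cell x parameter multiplicative draws
    readout: str
    endpoints: np.ndarray          # per-cell readout (NaN when integration failed)
    reference: float               # unperturbed-model readout
    trajectories: pd.DataFrame | None = None
    failed_cells: list[int] = field(default_factory=list)

    @property
    def summary(self) -> dict:
        ok = self.endpoints[~np.isnan(self.endpoints)]
        n = ok.size
        sd = float(np.std(ok, ddof=1)) if n > 1 else 0.0
        return {"n": int(n), "mean": float(np.mean(ok)), "sd": sd,
                "sem": sd / np.sqrt(n) if n else float("nan")}


def _is_structural(symbol: str) -> bool:
    return symbol[0] == "n" and symbol[1:].replace("a", "", 1).isdigit()


def draw_population(params: ParameterSet, spec: PopulationSpec) -> list[ParameterSet]:
    """One ParameterSet per cell, reproducible from ``spec.seed``."""
    cells, _ = draw_population_with_factors(params, spec)
    return cells


def draw_population_with_factors(params: ParameterSet, spec: PopulationSpec):
    rng = np.random.default_rng(spec.seed)
    varied = [k for k in params if not _is_structural(k)]
    a = spec.variation
    mat = rng.uniform(1.0 - a, 1.0 + a, size=(spec.n_cells, len(varied)))
    cells = []
    for i in range(spec.n_cells):
        factors = dict(zip(varied, mat[i]))
        ps = params.scaled(factors)
        floored = {k: max(v, DEGRADATION_FLOOR)
                   for k, v in ps.to_dict().items() if k.startswith(("kd_", "kdp_"))}
        cells.append(ps.replace(**floored))
    fdf = pd.DataFrame(mat, columns=varied)
    fdf.index.name = "cell_id"
    return cells, fdf


def population_timecourse(net: NetworkDefinition, params: ParameterSet,
                          spec: PopulationSpec,
                          protocol: ExperimentProtocol | None = None,
                          readout: str = "STAT1_mrna",
                          grid: Sequence[float] | None = None,
                          keep_trajectories: bool = False) -> PopulationResult:
    """Integrate every cell independently through one protocol.

    All cells start from the same packaged basal state (the heterogeneity
    is parametric, not in initial conditions); the unperturbed reference
    trajectory is computed alongside.
    """
    protocol = protocol or ExperimentProtocol.lps_step(48.0)
    cells, fdf = draw_population_with_factors(params, spec)
    ref_model = build_model(net, params)
    ref = run(net, params, protocol, grid=grid, model=ref_model)
    y0 = basal_state(ref_model)
    endpoints = np.full(spec.n_cells, np.nan)
    traj = {} if keep_trajectories else None
    failed = []
    proto_fixed = ExperimentProtocol(protocol.segments, initial_state=y0)
    for i, cp in enumerate(cells):
        try:
            tc = run(net, cp, proto_fixed, grid=grid)
        except IntegrationError:
            failed.append(i)
            continue
        endpoints[i] = tc.final(readout)
        if keep_trajectories:
            traj[i] = tc.values[:, tc.labels.index(readout)]
    tdf = None
    if keep_trajectories:
        tdf = pd.DataFrame(traj, index=ref.times)
        tdf["reference"] = ref.values[:, ref.labels.index(readout)]
    return PopulationResult(spec, fdf, readout, endpoints, ref.final(readout),
                            tdf, failed)


def separatrix_threshold(net: NetworkDefinition, params: ParameterSet, lps: float,
                         readout: str = "STAT1_mrna", model=None) -> float:
    """Basin-boundary proxy: the unstable steady state's readout at this LPS.

    Falls back to the midpoint of the two outer stable states (or the
    single state's value) when no unstable state is found.
    """
    model = model or build_model(net, params)
    comp = readout.replace("_mrna", "")
    states = _bif.find_steady_states(net, params, lps, n_starts=24, seed=7, model=model)
    unstable = [s for s in states if not s.stable]
    if unstable:
        return float(np.median([s.mrna(model, comp) for s in unstable]))
    vals = sorted(s.mrna(model, comp) for s in states)
    if len(vals) >= 2:
        return 0.5 * (vals[0] + vals[-1])
    # monostable (past the fold): anchor the low side at the basal state
    low = float(basal_state(model)[model.mrna_index(comp)])
    return 0.5 * (low + vals[0]) if vals else float("nan")


def population_steady_states(net: NetworkDefinition, params: ParameterSet,
                             spec: PopulationSpec, lps_grid: Sequence[float],
                             initial_condition: str = "low",
                             dwell_h: float = 200.0) -> pd.DataFrame:
    """Endpoint readouts per cell per LPS after a long relaxation.

    ``initial_condition`` 'low' starts every cell from the packaged basal
    state, 'high' from the unperturbed model's LPS-activated state. The same
    population (same draws) is reused across the LPS grid. Returns a tidy
    frame with per-cell endpoints plus the fraction of cells above the
    unperturbed model's separatrix value at each dose.
    """
    if initial_condition not in ("low", "high"):
        raise ValueError("initial_condition must be 'low' or 'high'")
    cells, _ = draw_population_with_factors(params, spec)
    ref_model = build_model(net, params)
    readout = "STAT1_mrna"
    y0 = basal_state(ref_model) if initial_condition == "low" else activated_state(ref_model)
    rows = []
    for lam in lps_grid:
        thr = separatrix_threshold(net, params, lam, readout, model=ref_model)
        for i, cp in enumerate(cells):
            m = build_model(net, cp)
            try:
                y = settle(m, ModelInputs(lps=lam), y0, horizon_h=dwell_h)
            except IntegrationError:
                rows.append({"lps": lam, "cell_id": i, "value": np.nan,
                             "above_separatrix": np.nan, "threshold": thr})
                continue
            v = float(y[m.mrna_index("STAT1")])
            rows.append({"lps": lam, "cell_id": i, "value": v,
                         "above_separatrix": bool(v > thr) if np.isfinite(thr) else np.nan,
                         "threshold": thr})
    return pd.DataFrame(rows)
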