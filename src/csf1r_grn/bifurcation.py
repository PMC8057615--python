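"""Steady-state structure of the model as a function of LPS.

The network is bistable at low LPS: a basal and an activated
("GRN-activated") stable state coexist, separated by an unstable saddle.
The basal branch terminates in a saddle-node at a positive LPS dose; the
activated branch persists down to LPS = 0 and folds back only at
negative (non-physical) LPS, which is what makes the switch
irreversible. Negative LPS values are permitted here solely so that
continuation can map that fold; outputs flag them as non-physical.

Stability is classified from the eigenvalues of a finite-difference
Jacobian; branches are traced by pseudo-arclength continuation with the
state scaled per variable (protein pools run ~3000x the mRNA scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import KineticModel, ModelInputs, build_model
from .network import NetworkDefinition
from .params import ParameterSet
from .simulate import resting_state, settle

__all__ = [
    "SteadyState",
    "BifurcationDiagram",
    "find_steady_states",
    "continue_branch",
    "hysteresis_sweep",
]

RESIDUAL_TOL = 1e-9
DEDUP_RTOL = 1e-4


@dataclass
class SteadyState:
    state: np.ndarray
    lps: float
    stability: str                # "stable" | "unstable"
    leading_eig: float            # largest real part of the Jacobian spectrum
    residual: float

    @property
    def stable(self) -> bool:
        return self.stability == "stable"

    @property
    def physical(self) -> bool:
        return self.lps >= 0.0

    def mrna(self, model: KineticModel, component: str) -> float:
        return float(self.state[model.mrna_index(component)])


@dataclass
class BifurcationDiagram:
    branches: list[list[SteadyState]]
    fold_points: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def to_frame(self, model: KineticModel) -> pd.DataFrame:
        rows = []
        for bi, branch in enumerate(self.branches):
            for ss in branch:
                row = {"branch_id": bi, "lps": ss.lps, "stability": ss.stability,
                       "physical": ss.physical}
                row.update({lab: v for lab, v in zip(model.state_labels, ss.state)})
                rows.append(row)
        return pd.DataFrame(rows)


def _scales(model: KineticModel) -> np.ndarray:
    s = np.ones(model.n_state)
    s[model.n_comp:] = model.ratio
    return s


def _classify(model: KineticModel, y: np.ndarray, inputs: ModelInputs) -> tuple[str, float]:
    eigs = np.linalg.eigvals(model.jacobian(y, inputs))
    lead = float(np.max(eigs.real))
    return ("stable" if lead < 0 else "unstable"), lead


def _solve_state(model: KineticModel, y0: np.ndarray, inputs: ModelInputs):
    s = _scales(model)

    def fun(z):
        return model.rhs(0.0, z * s, inputs)

    sol = root(fun, np.asarray(y0) / s, method="hybr", tol=1e-12)
    if not sol.success:
        return None
    y = sol.x * s
    if np.min(y) < -1e-6 * np.max(np.abs(y)):
        return None
    y = np.clip(y, 0.0, None)
    resid = float(np.max(np.abs(model.rhs(0.0, y, inputs)) / np.maximum(np.abs(y), 1.0)))
    if resid > RESIDUAL_TOL:
        return None
    return y


def find_steady_states(net: NetworkDefinition, params: ParameterSet, lps: float,
                       n_starts: int = 30, seed: int = 0,
                       synthesis_scale: Mapping[str, float] | None = None,
                       model: KineticModel | None = None) -> list[SteadyState]:
    """Multi-start root finding, de-duplicated and stability-classified.

    Starts include the basal and LPS-activated presets plus random states
    with mRNA drawn uniformly in [0, 20] (the protein pools scaled along).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    model = model or build_model(net, params)
    inputs = ModelInputs(lps=lps, synthesis_scale=dict(synthesis_scale or {}))
    rng = np.random.default_rng(seed)
    rest = resting_state(model)
    starts = [rest]
    starts.append(settle(model, ModelInputs(lps=max(lps, 1.0),
                                            synthesis_scale=dict(synthesis_scale or {})),
                         rest, horizon_h=200.0))
    while len(starts) < n_starts:
        m = rng.uniform(0.0, 20.0, size=model.n_comp)
        y = np.empty(model.n_state)
        y[:model.n_comp] = m
        for j, c in enumerate(model.active):
            tot = model.ratio * m[model.mrna_index(c)]
            fa = rng.uniform(0.0, 1.0)
            y[model.n_comp + 2 * j] = (1 - fa) * tot
            y[model.n_comp + 1 + 2 * j] = fa * tot
        starts.append(y)
    s = _scales(model)
    found: list[np.ndarray] = []

    def try_start(y0):
        y = _solve_state(model, y0, inputs)
        if y is None:
            return
        if any(np.linalg.norm((y - f) / s) / (1 + np.linalg.norm(f / s)) < DEDUP_RTOL
               for f in found):
            return
        found.append(y)

    for y0 in starts:
        try_start(y0)
    # refinement: saddles sit between attractors, and Newton converges to
    # them from a band of blend points on the joining line — scan it densely
    have_saddle = any(_classify(model, y, inputs)[0] == "unstable" for y in found)
    if len(found) >= 2 and not have_saddle:
        base = sorted(found, key=lambda y: float(np.linalg.norm(y[:model.n_comp])))
        for a, b in zip(list(base), list(base[1:])):
            for w in np.linspace(0.04, 0.96, 24):
                try_start((1 - w) * a + w * b)
    out = []
    for y in found:
        stab, lead = _classify(model, y, inputs)
        resid = float(np.max(np.abs(model.rhs(0.0, y, inputs)) / np.maximum(np.abs(y), 1.0)))
        out.append(SteadyState(y, lps, stab, lead, resid))
    out.sort(key=lambda ss: float(np.linalg.norm(ss.state[:model.n_comp])))
    return out


def continue_branch(net: NetworkDefinition, params: ParameterSet, start: SteadyState,
                    lps_range: tuple[float, float], direction: int = +1,
                    step: float = 0.02, max_step: float = 0.05, min_step: float = 1e-6,
                    max_points: int = 2000,
                    synthesis_scale: Mapping[str, float] | None = None,
                    model: KineticModel | None = None) -> BifurcationDiagram:
    """Pseudo-arclength continuation of one steady-state branch.

    Traverses folds (where d(lps)/d(arclength) changes sign, recorded as
    saddle-node points) and stops at the edge of ``lps_range``, after
    ``max_points``, or on step collapse.
    """
    model = model or build_model(net, params)
    s = _scales(model)
    extra = dict(synthesis_scale or {})
    n = model.n_state

    def F(z, lam):
        return model.rhs(0.0, z * s, ModelInputs(lps=lam, synthesis_scale=extra))

    def jac(z, lam, f0):
        J = np.empty((n, n + 1))
        hz = 1e-7 * np.maximum(np.abs(z), 1e-3)
        for k in range(n):
            zp = z.copy(); zp[k] += hz[k]
            zm = z.copy(); zm[k] -= hz[k]
            J[:, k] = (F(zp, lam) - F(zm, lam)) / (2 * hz[k])
        hl = 1e-7 * max(abs(lam), 1e-2)
        J[:, n] = (F(z, lam + hl) - F(z, lam - hl)) / (2 * hl)
        return J

    z = start.state / s
    lam = start.lps
    # initial tangent: dz/dlam from J_z dz = -F_lam
    J = jac(z, lam, None)
    dz = np.linalg.lstsq(J[:, :n], -J[:, n], rcond=None)[0]
    t = np.concatenate([dz, [1.0]])
    t /= np.linalg.norm(t)
    if t[n] != 0:
        t *= np.sign(direction) * np.sign(t[n])
    elif direction < 0:
        t = -t

    def record(z, lam) -> SteadyState:
        y = np.clip(z * s, 0.0, None)
        inputs = ModelInputs(lps=lam, synthesis_scale=extra)
        stab, lead = _classify(model, y, inputs)
        resid = float(np.max(np.abs(model.rhs(0.0, y, inputs)) / np.maximum(np.abs(y), 1.0)))
        return SteadyState(y, float(lam), stab, lead, resid)

    branch = [record(z, lam)]
    folds: list[tuple[float, np.ndarray]] = []
    h = step
    lo, hi = lps_range
    while len(branch) < max_points:
        u0 = np.concatenate([z, [lam]])
        pred = u0 + h * t
        u = pred.copy()
        ok = False
        for _ in range(12):
            f = F(u[:n], u[n])
            g = t @ (u - pred)
            if np.max(np.abs(f)) < 1e-10 and abs(g) < 1e-12:
                ok = True
                break
            J = jac(u[:n], u[n], f)
            A = np.vstack([J, t])
            rhs_vec = np.concatenate([f, [g]])
            try:
                du = np.linalg.solve(A, -rhs_vec)
            except np.linalg.LinAlgError:
                break
            u = u + du
            if np.max(np.abs(du)) < 1e-12:
                f = F(u[:n], u[n])
                ok = np.max(np.abs(f)) < 1e-8
                break
        if not ok:
            h *= 0.5
            if h < min_step:
                break
            continue
        # new tangent from secant, normalized
        t_new = u - u0
        nrm = np.linalg.norm(t_new)
        if nrm == 0:
            break
        t_new /= nrm
        if t[n] * t_new[n] < 0 and abs(t_new[n]) > 1e-8:
            folds.append((float(u[n]), np.clip(u[:n] * s, 0.0, None)))
        t = t_new
        z, lam = u[:n], float(u[n])
        branch.append(record(z, lam))
        h = min(h * 1.3, max_step)
        if lam < lo - 1e-9 or lam > hi + 1e-9:
            break
    return BifurcationDiagram([branch], folds)


def hysteresis_sweep(net: NetworkDefinition, params: ParameterSet,
                     lps_values: Sequence[float] | None = None, dwell_h: float = 200.0,
                     synthesis_scale: Mapping[str, float] | None = None,
                     model: KineticModel | None = None) -> pd.DataFrame:
    """Quasi-static up-then-down LPS scan from the basal state.

    At each dose the system relaxes for ``dwell_h`` hours from the previous
    endpoint; the up-sweep jumps to the activated state past the fold and the
    down-sweep stays on it (irreversibility).
    """
    model = model or build_model(net, params)
    if lps_values is None:
        lps_values = np.round(np.arange(0.0, 1.01, 0.1), 10)
    lps_values = list(lps_values)
    extra = dict(synthesis_scale or {})
    y = resting_state(model)
    rows = []
    for sweep, seq in (("up", lps_values), ("down", list(reversed(lps_values)))):
        for lam in seq:
            y = settle(model, ModelInputs(lps=lam, synthesis_scale=extra), y,
                       horizon_h=dwell_h)
            row = {"sweep": sweep, "lps": lam}
            row.update({lab: v for lab, v in zip(model.state_labels, y)})
            rows.append(row)
    return pd.DataFrame(rows)
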