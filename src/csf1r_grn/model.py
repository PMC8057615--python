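"""ODE right-hand side of the CSF1R network kinetic model.

The model tracks 21 state variables: the mRNA level of each of the 11
network components, plus inactive and active protein pools for the five
components that are regulated post-translationally (STAT1, STAT3, CSF1R,
NFKB, CEBPA). mRNA is expressed in reference-gene-relative units, time
in hours, and the LPS input is dimensionless with 1 equal to the
experimental dose.

Functional forms
----------------
Transcription of component ``c`` (with knockdown/overexpression factor
``s_c`` and regulator activities ``A``)::

    dM_c/dt = s_c * ( b_c + sum_e w_e * A_e^n_e / (K_e^n_e + A_e^n_e) )
                  * prod_i K_i^n_i / (K_i^n_i + A_i^n_i)
              - kd_c * M_c

where the sum runs over transcriptional activation edges into ``c`` and
the product over transcriptional inhibition edges. Edges whose source is
LPS contribute linearly (``w_e * lps``) so that continuation can follow
branches through negative LPS smoothly; the inhibitory LPS edge uses an
even Hill exponent for the same reason.

The activity of a regulator is its active protein pool if it has one,
and ``protein_mrna_ratio * mRNA`` (a proxy for total protein) otherwise;
the external input LPS enters as the dimensionless dose itself.

Each post-translationally regulated protein obeys::

    dPi/dt = ratio*kdp_c * M_c - v_c*Pi + ki_c*Pa - kdp_c*Pi
    dPa/dt = v_c*Pi - ki_c*Pa - kdp_c*Pa
    v_c    = ba_c + sum_e wa_e * A_e^na_e / (Ka_e^na_e + A_e^na_e)

so activation and inactivation shuttle protein between the inactive and
active pools while synthesis (at ``protein_mrna_ratio * kdp`` per unit
mRNA, which pins total protein at ``ratio`` times mRNA in steady state)
feeds the inactive pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Mapping

import numpy as np

from .network import LPS, NetworkDefinition
from .params import ParameterSet, half_life  # re-exported for convenience

__all__ = [
    "ModelInputs",
    "KineticModel",
    "build_model",
    "build_rhs",
    "apply_fold_change",
    "half_life",
    "basal_state",
    "ModelConstructionError",
]



class ModelConstructionError(ValueError):
    """A regulation lacks its kinetic constants, or a symbol is orphaned."""


@dataclass(frozen=True)
class ModelInputs:
    """Time-constant experimental inputs: LPS dose and synthesis scalings."""

    lps: float = 0.0
    synthesis_scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for comp, fac in self.synthesis_scale.items():
            if fac <= 0:
                raise ValueError(f"synthesis_scale[{comp}] must be > 0, got {fac}")


def apply_fold_change(inputs: ModelInputs, component: str, factor: float) -> ModelInputs:
    """Multiply ``component``'s mRNA synthesis scale by ``factor``."""
    if factor <= 0:
        raise ValueError(f"fold-change factor must be > 0, got {factor}")
    scale = dict(inputs.synthesis_scale)
    scale[component] = scale.get(component, 1.0) * factor
    if np.isclose(scale[component], 1.0):
        del scale[component]
    return replace(inputs, synthesis_scale=scale)


def _hill(a: float, K: float, n: float) -> float:
    if a <= 0.0:
        return 0.0
    an = a ** n
    return an / (K ** n + an)


def _rhs_core(y, lps, s, b, kd,
              ta_t, ta_s, ta_w, ta_K, ta_n,
              ti_t, ti_s, ti_K, ti_n,
              tl_w, li_t, li_K, li_n,
              act_comp, kdp, ki, ba, ratio,
              pt_p, pt_s, pt_wa, pt_Ka, pt_na, pl_wa):
    nc = b.shape[0]
    n_act = act_comp.shape[0]
    # regulator activities per component
    A = np.empty(nc)
    for i in range(nc):
        A[i] = ratio * y[i]
    for j in range(n_act):
        A[act_comp[j]] = y[nc + 1 + 2 * j]
    # transcription
    prod = b.copy()
    for e in range(ta_t.shape[0]):
        prod[ta_t[e]] += ta_w[e] * _hill(A[ta_s[e]], ta_K[e], ta_n[e])
    for i in range(nc):
        prod[i] += tl_w[i] * lps
    inh = np.ones(nc)
    for e in range(ti_t.shape[0]):
        inh[ti_t[e]] *= 1.0 - _hill(A[ti_s[e]], ti_K[e], ti_n[e])
    for e in range(li_t.shape[0]):
        inh[li_t[e]] *= li_K[e] ** li_n[e] / (li_K[e] ** li_n[e] + lps ** li_n[e])
    dy = np.empty(y.shape[0])
    for i in range(nc):
        dy[i] = s[i] * prod[i] * inh[i] - kd[i] * y[i]
    # post-translational activation rates and protein pools
    for j in range(n_act):
        v = ba[j] + pl_wa[j] * lps
        for e in range(pt_p.shape[0]):
            if pt_p[e] == j:
                v += pt_wa[e] * _hill(A[pt_s[e]], pt_Ka[e], pt_na[e])
        c = act_comp[j]
        pi = y[nc + 2 * j]
        pa = y[nc + 1 + 2 * j]
        syn = ratio * kdp[j] * y[c]
        flux = v * pi - ki[j] * pa
        dy[nc + 2 * j] = syn - flux - kdp[j] * pi
        dy[nc + 1 + 2 * j] = flux - kdp[j] * pa
    return dy


try:  # pragma: no cover - exercised implicitly
    import numba

    _hill = numba.njit(_hill)
    _rhs_core_jit = numba.njit(_rhs_core)
except Exception:  # pragma: no cover
    _rhs_core_jit = _rhs_core


class KineticModel:
    """Compiled derivative function plus index metadata for one network."""

    def __init__(self, net: NetworkDefinition, params: ParameterSet):
        self.net = net
        self.params = params
        self.names = net.names
        self.active = [c.name for c in net.components if c.has_active_form]
        self.index = {n: i for i, n in enumerate(self.names)}
        self.n_comp = len(self.names)
        self.n_state = self.n_comp + 2 * len(self.active)
        self._compile()

    # -- state layout ------------------------------------------------
    def mrna_index(self, component: str) -> int:
        return self.index[component]

    def protein_indices(self, component: str) -> tuple[int, int]:
        """(inactive, active) positions of a post-translationally regulated protein."""
        j = self.active.index(component)
        return self.n_comp + 2 * j, self.n_comp + 1 + 2 * j

    @property
    def state_labels(self) -> list[str]:
        labels = [f"{n}_mrna" for n in self.names]
        for n in self.active:
            labels += [f"{n}_prot_inactive", f"{n}_prot_active"]
        return labels

    # -- compilation -------------------------------------------------
    def _compile(self) -> None:
        net, p = self.net, self.params
        used: set[str] = {"protein_mrna_ratio"}

        def get(sym: str, edge: int) -> float:
            try:
                v = p[sym]
            except KeyError:
                raise ModelConstructionError(
                    f"regulation {edge}: missing parameter {sym!r}"
                ) from None
            used.add(sym)
            return v

        idx = self.index
        act_idx = {n: j for j, n in enumerate(self.active)}
        ta, ti, li, pt = [], [], [], []
        tl_w = np.zeros(self.n_comp)
        pl_wa = np.zeros(len(self.active))
        for r in net.regulations:
            if r.level == "transcriptional":
                t = idx[r.target]
                if r.source == LPS:
                    if r.sign == "activation":
                        tl_w[t] += get(f"w{r.id}", r.id)
                    else:
                        li.append((t, get(f"K{r.id}", r.id), get(f"n{r.id}", r.id)))
                elif r.sign == "activation":
                    ta.append((t, idx[r.source], get(f"w{r.id}", r.id),
                               get(f"K{r.id}", r.id), get(f"n{r.id}", r.id)))
                else:
                    ti.append((t, idx[r.source],
                               get(f"K{r.id}", r.id), get(f"n{r.id}", r.id)))
            else:  # post-translational
                j = act_idx[r.target]
                if r.source == LPS:
                    pl_wa[j] += get(f"wa{r.id}", r.id)
                else:
                    pt.append((j, idx[r.source], get(f"wa{r.id}", r.id),
                               get(f"Ka{r.id}", r.id), get(f"na{r.id}", r.id)))

        def cols(rows, types):
            if not rows:
                return [np.empty(0, dtype=t) for t in types]
            return [np.array(col, dtype=t) for col, t in zip(zip(*rows), types)]

        self._ta = cols(ta, (np.int64, np.int64, float, float, float))
        self._ti = cols(ti, (np.int64, np.int64, float, float))
        self._li = cols(li, (np.int64, float, float))
        self._pt = cols(pt, (np.int64, np.int64, float, float, float))
        self._tl_w = tl_w
        self._pl_wa = pl_wa

        self._b = np.array([get(f"b_{n}", 0) for n in self.names])
        self._kd = np.array([get(f"kd_{n}", 0) for n in self.names])
        self._act_comp = np.array([idx[n] for n in self.active], dtype=np.int64)
        self._kdp = np.array([get(f"kdp_{n}", 0) for n in self.active])
        self._ki = np.array([get(f"ki_{n}", 0) for n in self.active])
        self._ba = np.array([get(f"ba_{n}", 0) for n in self.active])
        self.ratio = p["protein_mrna_ratio"]

        orphans = sorted(set(p) - used)
        if orphans:
            raise ModelConstructionError(
                f"parameter symbol(s) not used by any model term: {orphans}"
            )

    # -- evaluation --------------------------------------------------
    def synthesis_vector(self, inputs: ModelInputs) -> np.ndarray:
        s = np.ones(self.n_comp)
        for comp, fac in inputs.synthesis_scale.items():
            s[self.index[comp]] = fac
        return s

    def rhs(self, t: float, y: np.ndarray, inputs: ModelInputs) -> np.ndarray:
        """Time-autonomous derivative; ``t`` is accepted for solver APIs."""
        return _rhs_core_jit(
            np.asarray(y, dtype=float), float(inputs.lps),
            self.synthesis_vector(inputs), self._b, self._kd,
            *self._ta, *self._ti, self._tl_w, *self._li,
            self._act_comp, self._kdp, self._ki, self._ba, float(self.ratio),
            *self._pt, self._pl_wa,
        )

    def rhs_for(self, inputs: ModelInputs) -> Callable[[float, np.ndarray], np.ndarray]:
        """Closure suitable for scipy's ``solve_ivp``; inputs are frozen."""
        s = self.synthesis_vector(inputs)
        lps = float(inputs.lps)
        args = (self._b, self._kd, *self._ta, *self._ti, self._tl_w, *self._li,
                self._act_comp, self._kdp, self._ki, self._ba, float(self.ratio),
                *self._pt, self._pl_wa)
        core = _rhs_core_jit

        def fun(t: float, y: np.ndarray) -> np.ndarray:
            return core(y, lps, s, *args)

        return fun

    def jacobian(self, y: np.ndarray, inputs: ModelInputs,
                 rel_step: float = 1e-6) -> np.ndarray:
        """Central-difference Jacobian, step scaled to state magnitude."""
        fun = self.rhs_for(inputs)
        y = np.asarray(y, dtype=float)
        n = y.size
        J = np.empty((n, n))
        scale = np.maximum(np.abs(y), 1e-3)
        for k in range(n):
            h = rel_step * scale[k]
            yp, ym = y.copy(), y.copy()
            yp[k] += h
            ym[k] -= h
            J[:, k] = (fun(0.0, yp) - fun(0.0, ym)) / (2 * h)
        return J

    def effective_protein(self, state: np.ndarray, component: str) -> float:
        """Regulatory activity: active pool, or ratio x mRNA proxy."""
        if component not in self.index:
            raise KeyError(f"unknown component {component!r}")
        if component in self.active:
            return float(state[self.protein_indices(component)[1]])
        return float(self.ratio * state[self.mrna_index(component)])


def build_model(net: NetworkDefinition, params: ParameterSet) -> KineticModel:
    return KineticModel(net, params)


def build_rhs(net: NetworkDefinition, params: ParameterSet):
    """Bare derivative function ``f(t, state, inputs) -> dstate/dt``."""
    return KineticModel(net, params).rhs


def basal_state(model: KineticModel | None = None) -> np.ndarray:
    """Packaged unstimulated initial conditions (the basal steady state)."""
    doc = json.loads(
        resources.files("csf1r_grn.data").joinpath("initial_conditions.json").read_text()
    )
    if model is None:
        return np.array(doc["state"], dtype=float)
    y = np.array(doc["state"], dtype=float)
    if doc["labels"] != model.state_labels:
        raise ValueError("packaged initial conditions do not match this model layout")
    return y
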