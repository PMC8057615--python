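"""Kinetic model construction, parameter conventions, and ODE invariants."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from csf1r_grn import (
    ModelConstructionError, ModelInputs, apply_fold_change, build_model,
)
from csf1r_grn.params import ParameterSet, half_life

HALF_LIVES_H = {
    "CSF1": 5.2, "STAT1": 7.0, "STAT3": 6.0, "IRF8": 4.1, "PU1": 12.0,
    "NFKB": 5.3, "CEBPA": 7.0, "IL6R": 8.0, "TNFR1": 10.0, "CSF1R": 12.0,
    "CSF3R": 10.0,
}


class TestParameterConventions:
    def test_protein_mrna_ratio_is_3000(self, params):
        assert params["protein_mrna_ratio"] == 3000.0

    @pytest.mark.parametrize("comp,expected", [("IRF8", 4.1), ("CSF1", 5.2)])
    def test_shortest_half_lives(self, params, comp, expected):
        assert half_life(params, comp) == pytest.approx(expected, abs=0.05)

    def test_half_life_consistency_all_components(self, params):
        for comp, hl in HALF_LIVES_H.items():
            assert half_life(params, comp) == pytest.approx(hl, rel=1e-3)
            assert half_life(params, comp) == pytest.approx(
                math.log(2) / params[f"kd_{comp}"])

    def test_irf8_and_csf1_are_the_shortest(self, params):
        hls = sorted(HALF_LIVES_H, key=lambda c: HALF_LIVES_H[c])
        assert hls[:2] == ["IRF8", "CSF1"]

    def test_closed_form_half_life(self, toy_one_gene):
        _, toy_params = toy_one_gene
        p = toy_params.replace(kd_GENE=math.log(2.0))
        assert half_life(p, "GENE") == pytest.approx(1.0)

    def test_unknown_component_raises(self, params):
        with pytest.raises(KeyError):
            half_life(params, "ACTB")


class TestConstruction:
    def test_missing_edge_parameter_names_edge(self, net, params):
        broken = {k: v for k, v in params.to_dict().items() if k != "w5"}
        with pytest.raises(ModelConstructionError, match="regulation 5"):
            build_model(net, ParameterSet(broken))

    def test_orphan_symbol_rejected(self, net, params):
        extra = dict(params.to_dict())
        extra["mystery_rate"] = 1.0
        with pytest.raises(ModelConstructionError, match="mystery_rate"):
            build_model(net, ParameterSet(extra))

    def test_every_symbol_is_used(self, net, params):
        # audit passes by construction: build succeeds on the full set
        model = build_model(net, params)
        assert model.n_state == 11 + 2 * 5

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet({"kd_X": -1.0})


class TestDerivatives:
    def test_basal_state_is_quasi_steady(self, model, y0):
        d = model.rhs(0.0, y0, ModelInputs(lps=0.0))
        assert np.max(np.abs(d)) < 1e-4
        # the settled state over 500 h is its own oracle
        sol = solve_ivp(model.rhs_for(ModelInputs(lps=0.0)), (0, 500), y0,
                        method="LSODA", rtol=1e-8, atol=1e-10)
        assert np.allclose(sol.y[:11, -1], y0[:11], rtol=1e-3)

    def test_pure_decay_when_synthesis_off(self, net, params):
        # with transcription zeroed, every mRNA and every total protein
        # pool can only decay (the active/inactive pools still exchange)
        zeroed = {k: (0.0 if k.startswith(("b_", "w")) else v)
                  for k, v in params.to_dict().items()}
        model = build_model(net, ParameterSet(zeroed))
        rng = np.random.default_rng(0)
        y = np.empty(model.n_state)
        y[:11] = rng.uniform(0, 10, size=11)
        y[11:] = rng.uniform(0, 5000, size=10)
        d = model.rhs(0.0, y, ModelInputs(lps=1.0))
        assert np.all(d[:11] <= 1e-12)
        for comp in model.active:
            ip, ia = model.protein_indices(comp)
            # total protein loses ratio*kdp*M synthesis, keeps kdp degradation
            m = y[model.mrna_index(comp)]
            kdp = params[f"kdp_{comp}"]
            expected = model.ratio * kdp * m - kdp * (y[ip] + y[ia])
            assert d[ip] + d[ia] == pytest.approx(expected, rel=1e-9)

    def test_stat1_activation_increases_with_lps(self, model, y0):
        _, ia = model.protein_indices("STAT1")
        d0 = model.rhs(0.0, y0, ModelInputs(lps=0.0))[ia]
        d1 = model.rhs(0.0, y0, ModelInputs(lps=1.0))[ia]
        assert d1 > d0

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("lps", [0.0, 1.0])
    def test_non_negativity_from_random_states(self, net, params, model, seed, lps):
        rng = np.random.default_rng(seed)
        y = np.empty(model.n_state)
        y[:11] = rng.uniform(0, 20, 11)
        y[11:] = rng.uniform(0, 6e4, 10)
        sol = solve_ivp(model.rhs_for(ModelInputs(lps=lps)), (0, 48), y,
                        method="LSODA", rtol=1e-8, atol=1e-10)
        assert sol.success
        assert sol.y.min() > -1e-6


class TestEffectiveProtein:
    def test_proxy_scales_mrna(self, model, y0):
        y = y0.copy()
        y[model.mrna_index("PU1")] = 2.0
        assert model.effective_protein(y, "PU1") == pytest.approx(6000.0)
        y[model.mrna_index("PU1")] = 0.0
        assert model.effective_protein(y, "PU1") == 0.0

    def test_active_form_ignores_mrna(self, model, y0):
        y = y0.copy()
        _, ia = model.protein_indices("STAT1")
        y[ia] = 5.0
        y[model.mrna_index("STAT1")] = 99.0
        assert model.effective_protein(y, "STAT1") == 5.0

    def test_unknown_component(self, model, y0):
        with pytest.raises(KeyError):
            model.effective_protein(y0, "GAPDH")


class TestFoldChange:
    def test_identity(self):
        inputs = ModelInputs(lps=0.5)
        assert apply_fold_change(inputs, "STAT1", 1.0) == inputs

    def test_inverse_composition(self):
        inputs = ModelInputs()
        out = apply_fold_change(apply_fold_change(inputs, "STAT1", 10.0),
                                "STAT1", 0.1)
        assert out == inputs

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            apply_fold_change(ModelInputs(), "STAT1", 0.0)

    def test_halved_synthesis_halves_linear_steady_state(self, toy_one_gene):
        # one-gene linear model: production x 0.5 => steady state x 0.5
        toy_net, toy_params = toy_one_gene
        model = build_model(toy_net, toy_params)
        inputs = apply_fold_change(ModelInputs(lps=0.0), "GENE", 0.5)
        sol = solve_ivp(model.rhs_for(inputs), (0, 400), np.array([2.0]),
                        method="LSODA", rtol=1e-10, atol=1e-12)
        expected = 0.5 * toy_params["b_GENE"] / toy_params["kd_GENE"]
        assert sol.y[0, -1] == pytest.approx(expected, rel=1e-6)
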