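"""Protocol integration: exactness at boundaries, composability, and the
washout / knockdown / screen experiment wrappers."""

import numpy as np
import pytest

from csf1r_grn import ModelInputs, build_model
from csf1r_grn.simulate import (
    ExperimentProtocol, Segment, expression_screen, knockdown_prediction, run,
    washout_experiment,
)


class TestProtocols:
    def test_must_start_at_zero(self):
        with pytest.raises(ValueError):
            ExperimentProtocol([Segment(1.0, 2.0)])

    def test_segments_must_be_contiguous(self):
        with pytest.raises(ValueError):
            ExperimentProtocol([Segment(0.0, 10.0), Segment(12.0, 20.0)])

    def test_washout_factory(self):
        proto = ExperimentProtocol.washout(36.0, 48.0)
        assert [s.lps for s in proto.segments] == [1.0, 0.0]
        assert proto.span == 48.0


class TestRun:
    def test_basal_protocol_stays_within_5pct(self, net, params, model):
        tc = run(net, params, ExperimentProtocol.basal(48.0), model=model)
        frame = tc.mrna_frame()
        assert ((frame - 1.0).abs() < 0.05).all().all()

    def test_zero_duration_returns_initial_state(self, net, params, model, y0):
        proto = ExperimentProtocol([Segment(0.0, 0.0, lps=1.0)])
        tc = run(net, params, proto, grid=[0.0], model=model)
        assert tc.values.shape[0] == 1
        np.testing.assert_allclose(tc.values[0], y0)

    def test_restart_composability(self, net, params, model):
        grid = np.arange(0.0, 48.1, 2.0)
        whole = run(net, params, ExperimentProtocol.lps_step(48.0), grid=grid,
                    model=model)
        first = run(net, params, ExperimentProtocol.lps_step(20.0),
                    grid=np.arange(0, 20.1, 2.0), model=model)
        resumed_proto = ExperimentProtocol(
            [Segment(0.0, 28.0, lps=1.0)], initial_state=first.values[-1])
        second = run(net, params, resumed_proto, grid=np.arange(0, 28.1, 2.0),
                     model=model)
        np.testing.assert_allclose(second.values[-1], whole.values[-1],
                                   rtol=1e-6, atol=1e-8)

    def test_tolerance_refinement_changes_little(self, net, params, model):
        tc1 = run(net, params, ExperimentProtocol.lps_step(48.0), grid=[0, 48],
                  model=model)
        tc2 = run(net, params, ExperimentProtocol.lps_step(48.0), grid=[0, 48],
                  model=model, rtol=5e-9, atol=5e-11)
        m1, m2 = tc1.values[-1, :11], tc2.values[-1, :11]
        assert np.max(np.abs(m1 - m2) / np.abs(m1)) < 1e-3

    def test_grid_outside_span_rejected(self, net, params, model):
        with pytest.raises(ValueError):
            run(net, params, ExperimentProtocol.basal(10.0), grid=[0, 20],
                model=model)

    def test_lps_discontinuity_is_sharp(self, net, params, model):
        # derivative of NFKB mRNA flips with the input, not smoothed over
        proto = ExperimentProtocol.washout(36.0, 48.0)
        grid = np.concatenate([np.arange(0, 36.01, 1.0), [36.25, 36.5, 37.0, 48.0]])
        tc = run(net, params, proto, grid=grid, model=model)
        stat1a = tc.values[:, tc.labels.index("STAT1_prot_active")]
        i36 = list(tc.times).index(36.0)
        assert stat1a[i36 + 1] < stat1a[i36]  # activation collapses after removal


class TestWashout:
    def test_equal_times_gives_identical_arms(self, net, params, model):
        kept, removed, rel = washout_experiment(net, params, 48.0, 48.0,
                                                model=model)
        np.testing.assert_allclose(kept.values[-1], removed.values[-1], rtol=1e-9)
        assert max(rel.values()) < 1e-9

    def test_toy_removed_arm_decays_with_half_life(self, toy_one_gene):
        toy_net, toy_params = toy_one_gene
        model = build_model(toy_net, toy_params)
        proto = ExperimentProtocol(
            [Segment(0.0, 36.0, lps=1.0), Segment(36.0, 48.0, lps=0.0)],
            initial_state=np.array([2.0]))
        grid = np.arange(0.0, 48.1, 0.5)
        tc = run(toy_net, toy_params, proto, grid=grid, model=model)
        kd, b, w = (toy_params[k] for k in ("kd_GENE", "b_GENE", "w1"))
        m_inf = (b + w) / kd
        m_on = m_inf + (2.0 - m_inf) * np.exp(-kd * 36.0)  # state at washout
        m_base = b / kd
        t = grid[grid >= 36.0] - 36.0
        expected = m_base + (m_on - m_base) * np.exp(-kd * t)
        np.testing.assert_allclose(tc.values[grid >= 36.0, 0], expected, rtol=1e-4)

    def test_persistence_of_activated_state(self, net, params, model):
        _, _, rel = washout_experiment(net, params, 36.0, 48.0, model=model)
        assert rel["IRF8"] < 0.2
        assert rel["CSF1"] < 0.2


class TestKnockdown:
    def test_vanishing_knockdown_leaves_network_unchanged(self, net, params, model):
        ratios = knockdown_prediction(net, params, "STAT1", 0.02,
                                      horizon_h=48.0, model=model)
        others = ratios.drop("STAT1")
        assert np.allclose(others, 1.0, atol=5e-3)
        assert ratios["STAT1"] == pytest.approx(0.98, abs=1e-3)

    def test_target_hits_requested_residual(self, net, params, model):
        ratios = knockdown_prediction(net, params, "STAT3", 0.4, horizon_h=48.0,
                                      model=model)
        assert ratios["STAT3"] == pytest.approx(0.6, abs=1e-3)

    def test_invalid_fraction_rejected(self, net, params, model):
        with pytest.raises(ValueError):
            knockdown_prediction(net, params, "STAT1", 1.5, model=model)


class TestScreen:
    def test_unit_folds_give_unit_matrix(self, net, params, model):
        ratios, influence = expression_screen(net, params, fold_low=1.0,
                                              fold_high=1.0, horizon_h=24.0,
                                              model=model)
        assert np.allclose(ratios.to_numpy(), 1.0, atol=1e-6)
        assert np.allclose(influence.to_numpy(), 0.0, atol=1e-5)

    def test_no_outgoing_edges_means_no_influence(self, toy_two_gene):
        toy_net, toy_params = toy_two_gene
        ratios, influence = expression_screen(toy_net, toy_params, 0.1, 10.0,
                                              horizon_h=200.0)
        # B regulates nothing: A's readout stays at control
        assert ratios.loc["B"]["A"].to_numpy() == pytest.approx([1.0, 1.0], abs=1e-6)
        assert influence["B"] == pytest.approx(0.0, abs=1e-5)
        # A does regulate B
        assert influence["A"] > 0.01

    def test_control_equals_basal_state(self, net, params, model, y0):
        tc = run(net, params, ExperimentProtocol.lps_step(48.0, lps=0.0),
                 grid=[0, 48], model=model)
        np.testing.assert_allclose(tc.values[-1, :11], y0[:11], rtol=5e-4)
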