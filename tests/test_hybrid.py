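"""Hybrid layouts, teacher stepping, structural reduction, training."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hhesn.hybrid import (
    HybridVariant,
    build_hybrid_layout,
    hybrid_collect_states,
    hybrid_predict,
    hybrid_train,
    make_hybrid,
    min_delay_observations,
    surrogate_teacher_step,
)
from hhesn.neuron import ModelError, detune, resting_state
from hhesn.reservoir import (
    ReservoirConfig,
    collect_states,
    make_reservoir,
    predict_closed_loop,
    train_readout,
    train_reservoir,
)
from hhesn.timeseries import CurrentProtocol

VARIANTS = ["tvh-ih", "tvh-oh", "tvh-fh", "asvh-ih", "asvh-oh", "asvh-fh"]


class TestVariant:
    @pytest.mark.parametrize("tag", VARIANTS)
    def test_parse_round_trip(self, tag):
        assert HybridVariant.parse(tag).tag == tag

    def test_invalid_tag_rejected(self):
        with pytest.raises(ValueError):
            HybridVariant.parse("xvh-ih")

    def test_embedding_count_for_four_state_model(self):
        assert min_delay_observations(4) == 9


class TestLayout:
    def test_asvh_half_allocation(self):
        layout = build_hybrid_layout(HybridVariant.parse("asvh-fh"), 0.5, 1000)
        assert layout.counts == (250, 250, 125, 125, 125, 125)

    def test_gamma_zero_empties_model_channels(self):
        layout = build_hybrid_layout(HybridVariant.parse("asvh-ih"), 0.0, 300)
        assert layout.counts == (150, 150, 0, 0, 0, 0)

    def test_oh_variant_uses_data_split(self):
        layout = build_hybrid_layout(HybridVariant.parse("asvh-oh"), 0.5, 300)
        assert layout.counts == (150, 150)

    @given(
        st.sampled_from(VARIANTS),
        st.floats(0.0, 1.0),
        st.integers(8, 400),
    )
    def test_allocations_always_sum_to_n(self, tag, gamma, n):
        layout = build_hybrid_layout(HybridVariant.parse(tag), gamma, n)
        assert layout.n_nodes == n
        assert all(c >= 0 for c in layout.counts)


class TestTeacherStep:
    def test_fixed_point_is_preserved(self, neuron_params):
        rest = resting_state(neuron_params)
        out = surrogate_teacher_step(rest, neuron_params, rest.V, 0.0, 0.025)
        np.testing.assert_allclose(out.to_array(), rest.to_array(), atol=1e-9)

    def test_error_free_surrogate_tracks_reference(self, neuron_params, small_reference):
        train, _, ref = small_reference
        x = ref.data[0].copy()
        from hhesn.neuron import NeuronState

        worst = 0.0
        for t in range(1000):
            state = NeuronState(*x)
            out = surrogate_teacher_step(
                state, neuron_params, float(ref.V[t]), float(train.current[t]), train.dt
            )
            worst = max(worst, abs(out.V - ref.V[t + 1]))
            x = out.to_array()
        assert worst < 1e-6

    def test_gates_bounded_for_wild_feedback(self, neuron_params):
        rest = resting_state(neuron_params)
        for v_fb in (-200.0, 150.0):
            out = surrogate_teacher_step(rest, neuron_params, v_fb, 30.0, 0.025)
            arr = out.to_array()
            assert np.all(arr[1:] >= 0.0) and np.all(arr[1:] <= 1.0)


class TestStructure:
    @pytest.mark.parametrize(
        "tag, extra",
        [("tvh-ih", 0), ("tvh-oh", 1), ("tvh-fh", 1), ("asvh-ih", 0), ("asvh-oh", 4), ("asvh-fh", 4)],
    )
    def test_regressor_width_per_variant(self, neuron_params, tag, extra):
        cfg = ReservoirConfig(n_nodes=40, degree=8, spectral_radius=1.0,
                              input_scaling=0.8, ridge_beta=1e-3, seed=2)
        hyb = make_hybrid(cfg, neuron_params, tag, gamma=0.5)
        prot = CurrentProtocol(np.array([2.0, 4.0, 1.0]))
        v = np.array([-60.0, -59.5, -60.5])
        regs = hybrid_collect_states(hyb, prot, v)
        assert regs.shape == (2, 40 + extra)

    def test_tvh_ih_gamma_zero_reduces_to_reservoir(self, small_reference, neuron_params):
        # identical config and seed: the hybrid with no model nodes and no
        # model readout terms must reproduce the stand-alone reservoir
        # bit for bit, surrogate integration notwithstanding
        train, full, ref = small_reference
        v_train = ref.V[: train.n_samples]
        cfg = ReservoirConfig(n_nodes=100, seed=7)
        res = make_reservoir(cfg)
        train_reservoir(res, train, v_train)
        hyb = make_hybrid(cfg, neuron_params, "tvh-ih", gamma=0.0)
        hybrid_train(hyb, train, v_train)
        assert np.array_equal(res.readout.weights, hyb.reservoir.readout.weights)
        drive = CurrentProtocol(full.current[train.n_samples - 1 : -1])
        a = predict_closed_loop(res, drive)
        b = hybrid_predict(hyb, drive)
        assert np.array_equal(a.voltage, b.voltage)


@pytest.fixture(scope="module")
def trained_fh(neuron_params, small_reference):
    train, full, ref = small_reference
    cfg = ReservoirConfig(n_nodes=100, degree=8, spectral_radius=1.0,
                          input_scaling=0.8, ridge_beta=1e-3, seed=5)
    hyb = make_hybrid(cfg, neuron_params, "asvh-fh", gamma=0.5)
    hybrid_train(hyb, train, ref.V[: train.n_samples])
    return hyb, train, full, ref


class TestTraining:

    def test_mean_matching_over_training_window(self, trained_fh):
        hyb, train, full, ref = trained_fh
        v_train = ref.V[: train.n_samples]
        hyb2 = make_hybrid(hyb.config, hyb.surrogate_params, "asvh-fh", gamma=0.5)
        regs = hybrid_collect_states(hyb2, train, v_train)
        ro = hyb.reservoir.readout
        pred = regs @ ro.weights + ro.bias
        assert abs(pred.mean() - v_train[1:].mean()) < 1e-9

    def test_richer_regressor_fits_no_worse(self, neuron_params, small_reference):
        train, full, ref = small_reference
        v_train = ref.V[: train.n_samples]
        cfg = ReservoirConfig(n_nodes=100, degree=8, spectral_radius=1.0,
                              input_scaling=0.8, ridge_beta=1e-3, seed=5)
        res = make_reservoir(cfg)
        states = collect_states(res, train, v_train)
        ro_res = train_readout(states, v_train[1:], cfg.ridge_beta, cfg.input_scaling)
        resid_res = np.sqrt(np.mean((states @ ro_res.weights + ro_res.bias - v_train[1:]) ** 2))
        hyb = make_hybrid(cfg, neuron_params, "asvh-fh", gamma=0.0)
        regs = hybrid_collect_states(hyb, train, v_train)
        ro_hyb = train_readout(regs, v_train[1:], cfg.ridge_beta, cfg.input_scaling)
        resid_hyb = np.sqrt(np.mean((regs @ ro_hyb.weights + ro_hyb.bias - v_train[1:]) ** 2))
        assert resid_hyb <= resid_res + 1e-9

    def test_prediction_shapes_and_gates(self, trained_fh):
        hyb, train, full, ref = trained_fh
        drive = CurrentProtocol(full.current[train.n_samples - 1 : -1])
        out = hybrid_predict(hyb, drive)
        assert out.voltage.shape == (drive.n_samples,)
        assert out.gates.shape == (drive.n_samples, 3)
        assert np.all(out.gates >= 0.0) and np.all(out.gates <= 1.0)

    def test_zero_horizon(self, trained_fh):
        hyb = trained_fh[0]
        out = hybrid_predict(hyb, CurrentProtocol(np.zeros(5)), horizon=0)
        assert out.voltage.size == 0 and out.gates.size == 0

    def test_untrained_prediction_rejected(self, neuron_params):
        cfg = ReservoirConfig(n_nodes=40, seed=1)
        hyb = make_hybrid(cfg, neuron_params, "asvh-fh")
        with pytest.raises(RuntimeError):
            hybrid_predict(hyb, CurrentProtocol(np.zeros(5)))

    def test_deterministic_train_and_predict(self, neuron_params, small_reference):
        train, full, ref = small_reference
        v_train = ref.V[: train.n_samples]
        drive = CurrentProtocol(full.current[train.n_samples - 1 : -1])
        outs = []
        for _ in range(2):
            cfg = ReservoirConfig(n_nodes=60, degree=8, spectral_radius=1.0,
                                  input_scaling=0.8, ridge_beta=1e-3, seed=3)
            hyb = make_hybrid(cfg, detune(neuron_params, ModelError(eps_g=0.1)), "asvh-fh")
            hybrid_train(hyb, train, v_train)
            outs.append(hybrid_predict(hyb, drive).voltage)
        assert np.array_equal(outs[0], outs[1])
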