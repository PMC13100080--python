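"""Adjacency, scalers, state collection, ridge readout, closed loop."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.sparse.linalg import eigsh

from hhesn import _kernels
from hhesn.neuron import generate_reference
from hhesn.reservoir import (
    ReservoirConfig,
    build_adjacency,
    build_input_matrix,
    collect_states,
    fit_scaler,
    make_reservoir,
    predict_closed_loop,
    reservoir_step,
    train_readout,
    train_reservoir,
)
from hhesn.timeseries import CurrentProtocol

from _oracles import ridge_normal_equations


class TestAdjacency:
    def test_symmetric_binary_no_self_loops(self):
        a = build_adjacency(200, 6, 1.25, seed=0)
        dense = a.toarray()
        assert np.array_equal(dense, dense.T)
        assert np.all(dense.diagonal() == 0)
        vals = np.unique(dense[dense != 0])
        assert vals.size == 1  # single global scale of a 0/1 pattern

    def test_mean_degree_exact(self):
        a = build_adjacency(200, 6, 1.25, seed=1)
        assert a.nnz == 200 * 6  # nnz counts both triangle halves

    def test_spectral_radius_matches_config(self):
        a = build_adjacency(300, 8, 1.0, seed=2)
        lam = abs(
            eigsh(a, k=1, which="LM", v0=np.ones(300), return_eigenvectors=False)[0]
        )
        assert lam == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_in_seed(self):
        a = build_adjacency(100, 6, 1.25, seed=3)
        b = build_adjacency(100, 6, 1.25, seed=3)
        assert (a != b).nnz == 0


class TestInputMatrix:
    def test_rows_one_hot(self):
        w = build_input_matrix(10)
        assert np.all(w.sum(axis=1) == 1.0)
        assert set(np.unique(w)) == {0.0, 1.0}

    def test_column_sums_split_half(self):
        w = build_input_matrix(10)
        np.testing.assert_array_equal(w.sum(axis=0), [5, 5])

    def test_n4_block_pattern(self):
        w = build_input_matrix(4)
        np.testing.assert_array_equal(w, [[1, 0], [1, 0], [0, 1], [0, 1]])

    def test_odd_extra_node_to_voltage_block(self):
        w = build_input_matrix(5)
        np.testing.assert_array_equal(w.sum(axis=0), [2, 3])


class TestScaler:
    def test_contract_on_fitting_window(self, rng):
        x = rng.normal(3.0, 5.0, 4000)
        s = fit_scaler(x, 0.4)
        y = s.apply(x)
        assert abs(y.mean()) < 1e-12
        assert np.std(y) == pytest.approx(0.4, abs=1e-12)

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=50).filter(
            lambda v: max(v) - min(v) > 1e-6
        )
    )
    def test_round_trip(self, values):
        x = np.array(values)
        s = fit_scaler(x, 0.8)
        np.testing.assert_allclose(s.invert(s.apply(x)), x, atol=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            fit_scaler(np.full(10, 2.0), 0.4)


class TestStep:
    def test_zero_state_zero_input(self):
        a = build_adjacency(20, 4, 1.0, seed=0)
        w = build_input_matrix(20)
        out = reservoir_step(np.zeros(20), a, w, np.zeros(2))
        assert np.all(out == 0.0)

    def test_single_node_tanh(self):
        import scipy.sparse as sp

        a = sp.csr_matrix((1, 1))
        out = reservoir_step(np.zeros(1), a, np.array([[1.0]]), np.array([0.5]))
        assert out[0] == pytest.approx(np.tanh(0.5), abs=1e-12)

    def test_states_inside_unit_interval(self, rng):
        a = build_adjacency(50, 6, 1.25, seed=1)
        w = build_input_matrix(50)
        r = rng.uniform(-1, 1, 50)
        # scaled inputs stay well inside the tanh active range
        out = reservoir_step(r, a, w, np.array([0.8, -0.8]))
        assert np.max(np.abs(out)) < 1.0
        # even absurd inputs cannot escape [-1, 1] (float tanh saturates)
        out = reservoir_step(r, a, w, np.array([100.0, -100.0]))
        assert np.max(np.abs(out)) <= 1.0

    def test_non_finite_input_rejected(self):
        a = build_adjacency(10, 4, 1.0, seed=0)
        with pytest.raises(ValueError):
            reservoir_step(np.full(10, np.nan), a, build_input_matrix(10), np.zeros(2))


class TestEchoStateBoundedness:
    def test_long_run_stays_bounded(self, rng):
        # 1e5 teacher-forced steps with wild bounded inputs
        sys_ = make_reservoir(ReservoirConfig(n_nodes=50, seed=4))
        n = 100_000
        i_series = rng.uniform(-30, 30, n)
        v_series = rng.uniform(-100, 60, n)
        states = collect_states(
            sys_, CurrentProtocol(i_series), v_series
        )
        assert np.max(np.abs(states)) < 1.0
        assert np.all(np.isfinite(states))


class TestCollectStates:
    def test_sample_counting(self, rng):
        sys_ = make_reservoir(ReservoirConfig(n_nodes=20, seed=0))
        states = collect_states(
            sys_, CurrentProtocol(np.array([1.0, 2.0, 0.5])), np.array([-60.0, -59.0, -61.0])
        )
        assert states.shape == (2, 20)

    def test_first_state_from_zero_initialisation(self):
        sys_ = make_reservoir(ReservoirConfig(n_nodes=20, seed=0))
        i_series = np.array([2.0, 1.0, 0.0, 3.0])
        v_series = np.array([-60.0, -59.0, -61.0, -58.0])
        states = collect_states(sys_, CurrentProtocol(i_series), v_series)
        v_in = np.array(
            [sys_.scaler_i.apply(i_series[0]), sys_.scaler_v.apply(v_series[0])]
        )
        expected = np.tanh(build_input_matrix(20) @ v_in)
        np.testing.assert_allclose(states[0], expected, atol=1e-14)

    def test_deterministic(self, rng):
        i_series = rng.uniform(0, 10, 200)
        v_series = rng.uniform(-70, -50, 200)
        runs = []
        for _ in range(2):
            sys_ = make_reservoir(ReservoirConfig(n_nodes=30, seed=1))
            runs.append(collect_states(sys_, CurrentProtocol(i_series), v_series))
        assert np.array_equal(runs[0], runs[1])

    def test_length_mismatch_rejected(self):
        sys_ = make_reservoir(ReservoirConfig(n_nodes=20, seed=0))
        with pytest.raises(ValueError):
            collect_states(sys_, CurrentProtocol(np.ones(5)), np.ones(4))


class TestReadout:
    def test_recovers_exact_linear_map(self, rng):
        X = rng.normal(size=(500, 12))
        w_true = rng.normal(size=12)
        y = X @ w_true + 3.0
        ro = train_readout(X, y, beta=1e-12, sigma=0.4)
        resid = X @ ro.weights + ro.bias - y
        assert np.sqrt(np.mean(resid**2)) < 1e-6

    def test_mean_matching_bias(self, rng):
        X = rng.normal(size=(400, 8))
        y = rng.normal(2.5, 4.0, 400)
        ro = train_readout(X, y, beta=1e-3, sigma=0.4)
        pred = X @ ro.weights + ro.bias
        assert abs(pred.mean() - y.mean()) < 1e-9

    def test_ridge_shrinkage_monotone(self, rng):
        X = rng.normal(size=(300, 10))
        y = rng.normal(size=300)
        norms = [
            np.linalg.norm(train_readout(X, y, beta=b, sigma=0.4).weights_std)
            for b in (1e-6, 1e-4, 1e-2)
        ]
        assert norms[0] >= norms[1] >= norms[2]

    def test_matches_normal_equations_oracle(self, rng):
        # small random problem, independent inverse-based solve
        X = np.tanh(rng.normal(size=(200, 20)))
        y = rng.normal(size=200)
        ro = train_readout(X, y, beta=1e-4, sigma=0.4)
        w_ref, b_ref = ridge_normal_equations(X, y, 1e-4, 0.4)
        np.testing.assert_allclose(ro.weights, w_ref, atol=1e-8)
        assert ro.bias == pytest.approx(b_ref, abs=1e-8)

    def test_singular_without_ridge_raises_advice(self, rng):
        X = np.tile(rng.normal(size=(50, 1)), (1, 4))  # rank 1
        y = rng.normal(size=50)
        with pytest.raises(np.linalg.LinAlgError, match="beta > 0"):
            train_readout(X, y, beta=0.0, sigma=0.4)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            train_readout(np.ones((1, 3)), np.ones(1), beta=1e-3, sigma=0.4)


@pytest.fixture(scope="module")
def trained(small_reference):
    train, full, ref = small_reference
    sys_ = make_reservoir(ReservoirConfig(n_nodes=200, seed=11))
    train_reservoir(sys_, train, ref.V[: train.n_samples])
    return sys_, train, full, ref


class TestClosedLoop:

    def test_zero_horizon_empty(self, trained):
        sys_, train, full, ref = trained
        out = predict_closed_loop(sys_, CurrentProtocol(np.zeros(10)), horizon=0)
        assert out.voltage.size == 0

    def test_untrained_system_rejected(self):
        sys_ = make_reservoir(ReservoirConfig(n_nodes=20, seed=0))
        with pytest.raises(RuntimeError):
            predict_closed_loop(sys_, CurrentProtocol(np.zeros(10)))

    def test_deterministic(self, trained):
        sys_, train, full, ref = trained
        drive = CurrentProtocol(full.current[train.n_samples - 1 : -1])
        a = predict_closed_loop(sys_, drive)
        b = predict_closed_loop(sys_, drive)
        assert np.array_equal(a.voltage, b.voltage)

    def test_quiescent_easier_than_spiking(self, neuron_params, small_reference):
        # predict over 100 ms of zero drive then 100 ms of strong steps:
        # subthreshold stretches are predicted better than spiking ones
        train, _, _ = small_reference
        ref_train = generate_reference(neuron_params, train)
        drive = np.concatenate([np.zeros(4000), np.full(4001, 12.0)])
        full = train.concat(CurrentProtocol(drive))
        ref = generate_reference(neuron_params, full)
        n_tr = train.n_samples
        sys_ = make_reservoir(ReservoirConfig(n_nodes=200, seed=11))
        train_reservoir(sys_, train, ref.V[:n_tr])
        res = predict_closed_loop(
            sys_, CurrentProtocol(full.current[n_tr - 1 : -1])
        )
        rv = ref.V[n_tr:]
        quiet = np.sqrt(np.mean((res.voltage[:4000] - rv[:4000]) ** 2))
        spiking = np.sqrt(np.mean((res.voltage[4000:] - rv[4000:]) ** 2))
        assert quiet < spiking

    def test_output_finite_and_railed(self, trained):
        sys_, train, full, ref = trained
        drive = CurrentProtocol(full.current[train.n_samples - 1 : -1])
        res = predict_closed_loop(sys_, drive)
        assert np.all(np.isfinite(res.voltage))
        assert res.voltage.min() >= sys_.v_lo - 1e-12
        assert res.voltage.max() <= sys_.v_hi + 1e-12
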