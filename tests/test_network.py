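"""Core dynamics: initialisation, update equation and plasticity rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sornlab as sl
from sornlab.network import _phase_loop_python
from sornlab.tasks import build_input_map, compile_stream


def make_protocol(letters, imap, params, **kw):
    sym, drive = compile_stream(np.asarray(letters, dtype="U8"), imap, params)
    return sl.PhaseProtocol(sym=sym, drive=drive,
                            letters=np.asarray(letters, dtype="U8"), **kw)


class TestInit:
    def test_default_sizes_and_density(self):
        params = sl.SornParams(seed=1)
        state = sl.init_network(params)
        assert state.n_exc == 200 and state.n_inh == 40
        density = state.conn.mean()
        # binomial error on 200*199 Bernoulli(0.1) draws
        assert abs(density - 0.1) < 4 * np.sqrt(0.1 * 0.9 / (200 * 199))
        assert not np.diagonal(state.conn).any()
        state.check()

    def test_inhibitory_rows_normalized(self):
        state = sl.init_network(sl.SornParams(seed=2))
        np.testing.assert_allclose(state.w_ie.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(state.w_ei.sum(axis=1), 1.0, atol=1e-12)

    def test_excitatory_sums_normalized_after_init(self):
        state = sl.init_network(sl.SornParams(seed=3))
        rs = state.w_ee.sum(axis=1)
        cs = state.w_ee.sum(axis=0)
        assert np.abs(rs[rs > 0] - 1).max() < 1e-3
        assert np.abs(cs[cs > 0] - 1).max() < 1e-3

    def test_thresholds_evenly_spaced_and_permuted(self):
        params = sl.SornParams(seed=4)
        state = sl.init_network(params)
        expected = 0.5 * np.arange(1, 201) / 201
        np.testing.assert_allclose(np.sort(state.t_e), expected)
        assert ((state.h_targets > 0.09) & (state.h_targets < 0.11)).all()

    def test_no_connections_when_p_ee_zero(self):
        state = sl.init_network(sl.SornParams(n_exc=50, p_ee=0.0, seed=5))
        assert not state.conn.any() and not state.w_ee.any()
        # without excitation the network falls silent once thresholds are positive
        state.t_e = np.abs(state.t_e) + 0.01
        for _ in range(5):
            sl.step(state)
        assert not state.x.any() and not state.y.any()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sl.SornParams(h_ip=0.01, eps_ip=0.02)
        with pytest.raises(ValueError):
            sl.SornParams(p_ee=1.5)


class TestStep:
    def test_subthreshold_network_is_silent(self):
        state = sl.init_network(sl.SornParams(n_exc=30, seed=6))
        state.w_ee[:] = 0.0
        state.conn[:] = False
        state.w_ei[:] = 0.0
        sl.step(state)
        assert not state.x.any() and not state.y.any()

    def test_isolated_unit_follows_its_letter(self):
        # single unit driven only by its input: fires on the letter, not on blanks
        params = sl.SornParams(n_exc=20, n_input=1, p_ee=0.0, seed=7)
        state = sl.init_network(params)
        state.x[:] = 0.0
        state.t_e[:] = 0.4
        drive = np.zeros(20)
        drive[3] = 0.5
        sl.step(state, drive)
        assert state.x[3] == 1.0 and state.x.sum() == 1.0
        sl.step(state, None)
        assert not state.x.any()

    def test_threshold_is_strict(self):
        # activation exactly zero must not spike
        state = sl.init_network(sl.SornParams(n_exc=10, p_ee=0.0, seed=8))
        state.x[:] = 0.0
        state.t_e[:] = 0.5
        drive = np.full(10, 0.5)
        sl.step(state, drive)
        assert not state.x.any()

    def test_excitation_inhibition_balance_at_unit_t_i_max(self, rng):
        # with T^I spread over (0, 1), the active inhibitory fraction tracks
        # the active excitatory fraction
        params = sl.SornParams(seed=9, t_i_max=1.0)
        imap = build_input_map(["A", "B"], params, rng=rng)
        state = sl.init_network(params, w_eu=imap.w_eu(params.n_exc, params.w_in))
        letters = np.array(list("AB") * 2500, dtype="U8")
        proto = make_protocol(letters, imap, params, stdp=True, sn=True, ip=True,
                              record_inhibitory=True, shuffle_after=False)
        _, rec = sl.run_phase(state, proto, rng)
        xbar = rec.spikes[1000:].mean()
        ybar = rec.inhibitory_spikes[1000:].mean()
        assert abs(ybar - xbar) <= 3.0 / params.n_inh


class TestStdp:
    def test_single_causal_pair(self):
        state = sl.init_network(sl.SornParams(n_exc=10, seed=10))
        state.conn[:] = True
        np.fill_diagonal(state.conn, False)
        state.w_ee = np.where(state.conn, 0.5, 0.0)
        x_prev = np.zeros(10)
        x_now = np.zeros(10)
        x_prev[2] = 1.0  # j fired at t
        x_now[7] = 1.0   # i fired at t+1
        sl.apply_stdp(state, x_prev, x_now)
        assert state.w_ee[7, 2] == pytest.approx(0.501)
        assert state.w_ee[2, 7] == pytest.approx(0.499)

    def test_depression_floors_at_zero_and_prunes(self):
        state = sl.init_network(sl.SornParams(n_exc=6, n_input=2, seed=11))
        state.conn[:] = False
        state.conn[1, 0] = True
        state.w_ee[:] = 0.0
        state.w_ee[1, 0] = 0.0005
        x_prev = np.zeros(6); x_prev[1] = 1.0
        x_now = np.zeros(6); x_now[0] = 1.0
        sl.apply_stdp(state, x_prev, x_now)
        assert state.w_ee[1, 0] == 0.0
        assert not state.conn[1, 0]  # prune_zero_weights default

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_identical_states_give_no_update(self, seed):
        r = np.random.default_rng(seed)
        state = sl.init_network(sl.SornParams(n_exc=15, seed=seed))
        before = state.w_ee.copy()
        x = (r.random(15) < 0.3).astype(float)
        sl.apply_stdp(state, x, x)
        np.testing.assert_array_equal(state.w_ee, before)
        sl.apply_stdp(state, np.zeros(15), (r.random(15) < 0.3).astype(float))
        np.testing.assert_array_equal(state.w_ee, before)


class TestSynapticNormalization:
    def test_single_entry_update(self):
        state = sl.init_network(sl.SornParams(n_exc=5, n_input=2, seed=12))
        state.conn[:] = False
        state.w_ee[:] = 0.0
        state.conn[0, 1] = True
        state.w_ee[0, 1] = 0.4
        sl.apply_synaptic_normalization(state)
        assert state.w_ee[0, 1] == pytest.approx(0.46, abs=1e-15)

    def test_doubly_normalized_matrix_is_fixed_point(self):
        state = sl.init_network(sl.SornParams(n_exc=6, n_input=2, seed=13))
        w = np.zeros((6, 6))
        # permutation-like structure: all row and column sums exactly one
        w[0, 1] = w[1, 2] = w[2, 0] = 1.0
        w[3, 4] = w[4, 5] = w[5, 3] = 0.5
        w[3, 5] = w[4, 3] = w[5, 4] = 0.5
        state.w_ee = w.copy()
        state.conn = w > 0
        sl.apply_synaptic_normalization(state)
        np.testing.assert_allclose(state.w_ee, w, atol=1e-12)

    def test_iteration_converges_to_unit_sums(self, rng):
        state = sl.init_network(sl.SornParams(seed=14),
                                sn_max_iter=0)  # raw random weights
        for _ in range(10_000):
            sl.apply_synaptic_normalization(state)
        rs = state.w_ee.sum(axis=1)
        cs = state.w_ee.sum(axis=0)
        assert np.abs(rs[rs > 0] - 1).max() < 1e-3
        assert np.abs(cs[cs > 0] - 1).max() < 1e-3

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_preserves_nonnegativity_and_support(self, seed):
        state = sl.init_network(sl.SornParams(n_exc=20, seed=seed), sn_max_iter=1)
        support = state.w_ee > 0
        sl.apply_synaptic_normalization(state)
        assert (state.w_ee >= 0).all()
        np.testing.assert_array_equal(state.w_ee > 0, support)


class TestIntrinsicPlasticity:
    def test_threshold_updates(self):
        state = sl.init_network(sl.SornParams(n_exc=4, n_input=2, seed=15))
        state.h_targets[:] = 0.1
        t0 = state.t_e.copy()
        x = np.array([1.0, 0.0, 1.0, 0.0])
        sl.apply_ip(state, x)
        np.testing.assert_allclose(state.t_e - t0,
                                   [0.0009, -0.0001, 0.0009, -0.0001], atol=1e-15)

    def test_rates_track_targets_over_long_runs(self, random_letters_result):
        rec = random_letters_result.recordings["spontaneous"]
        err = np.abs(rec.rates() - random_letters_result.state.h_targets)
        assert err.max() < 0.02


class TestRunPhase:
    def test_no_plasticity_leaves_weights_untouched(self, rng):
        params = sl.SornParams(n_exc=50, seed=16)
        imap = build_input_map(["A"], params, rng=rng)
        state = sl.init_network(params, w_eu=imap.w_eu(50, 0.5))
        before = state.w_ee.copy()
        proto = make_protocol(["A", "_"] * 100, imap, params,
                              stdp=False, sn=False, ip=False)
        sl.run_phase(state, proto, rng)
        np.testing.assert_array_equal(state.w_ee, before)

    def test_zero_length_phase_gives_empty_recording(self, rng):
        params = sl.SornParams(n_exc=30, seed=17)
        imap = build_input_map(["A"], params, rng=rng)
        state = sl.init_network(params, w_eu=imap.w_eu(30, 0.5))
        proto = make_protocol([], imap, params)
        _, rec = sl.run_phase(state, proto, rng)
        assert rec.n_steps == 0

    def test_full_determinism_with_fixed_seed(self):
        def one():
            params = sl.SornParams(n_exc=60, seed=18)
            rngs = sl.spawn_rngs(99, ["map", "phase"])
            imap = build_input_map(["A", "B"], params, rng=rngs["map"])
            state = sl.init_network(params, w_eu=imap.w_eu(60, 0.5))
            letters = ["A", "B", "_"] * 400
            proto = make_protocol(letters, imap, params, stdp=True, sn=True,
                                  ip=True, structural=True)
            _, rec = sl.run_phase(state, proto, rngs["phase"])
            return rec.spikes, state.w_ee, state.t_e, state.x

        a, b = one(), one()
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_kernel_matches_reference_implementation(self):
        """The compiled phase loop reproduces the composed single-step ops."""
        def run(reference):
            params = sl.SornParams(n_exc=40, seed=19)
            rngs = sl.spawn_rngs(7, ["map", "phase"])
            imap = build_input_map(["A", "B", "C"], params, rng=rngs["map"])
            state = sl.init_network(params, w_eu=imap.w_eu(40, 0.5))
            letters = (["A", "B", "C"] + ["_"] * 2) * 80
            proto = make_protocol(letters, imap, params, stdp=True, sn=True,
                                  ip=True, structural=True)
            _, rec = sl.run_phase(state, proto, rngs["phase"],
                                  _python_reference=reference)
            return rec.spikes, state

        spikes_k, st_k = run(False)
        spikes_p, st_p = run(True)
        np.testing.assert_array_equal(spikes_k, spikes_p)
        np.testing.assert_array_equal(st_k.conn, st_p.conn)
        np.testing.assert_allclose(st_k.w_ee, st_p.w_ee, atol=1e-12)
        np.testing.assert_allclose(st_k.t_e, st_p.t_e, atol=1e-12)

    def test_noise_flip_tracking_and_stability(self, rng):
        params = sl.SornParams(n_exc=100, seed=20, noise_sd=0.01)
        imap = build_input_map(["A", "B"], params, rng=rng)
        state = sl.init_network(params, w_eu=imap.w_eu(100, 0.5))
        letters = ["A", "B"] * 4000
        proto = make_protocol(letters, imap, params, stdp=True, sn=True, ip=True)
        _, rec = sl.run_phase(state, proto, rng)
        total_spikes = rec.spikes.sum()
        assert rec.noise_flips > 0
        assert rec.noise_flips <= 0.10 * max(total_spikes, 1)
        # homeostasis keeps the rate near target despite the perturbation
        assert abs(rec.spikes[2000:].mean() - params.h_ip) < 0.02
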