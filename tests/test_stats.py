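"""Spike and weight statistics: ISI/CV, Fano factors, weight fits."""

import numpy as np
import pytest
import scipy.stats

from sornlab.network import SpikeRecording
from sornlab.stats import (
    TrialTensor,
    conditional_firing_probabilities,
    connection_fraction,
    fano_curve,
    fit_lognormal_weights,
    isi_cv_stats,
    mean_matched_fano,
)


def recording_from(spikes, letter="_"):
    spikes = np.asarray(spikes, dtype=np.uint8)
    return SpikeRecording(
        spikes=spikes, letters=np.full(spikes.shape[0], letter, dtype="U8")
    )


def bernoulli_tensor(rng, p=0.1, n_trials=200, n_neurons=50, pre=8, post=8, margin=4):
    width = margin + pre + post + 1
    spikes = (rng.random((n_trials, width, n_neurons)) < p).astype(np.uint8)
    return TrialTensor(
        spikes=spikes, onset_index=margin + pre, pre=pre, post=post, margin=margin,
        conditions=np.zeros(n_trials, dtype=int),
        input_units=np.zeros(n_neurons, dtype=bool),
    )


class TestIsiCv:
    def test_periodic_spiking_has_zero_cv(self):
        spikes = np.zeros((300, 2), dtype=np.uint8)
        spikes[::5, 0] = 1
        spikes[::3, 1] = 1
        st = isi_cv_stats(recording_from(spikes))
        np.testing.assert_allclose(st.cvs, 0.0, atol=1e-12)

    def test_bernoulli_train_has_geometric_cv(self, rng):
        # geometric ISIs: CV -> sqrt(1 - p) ~= 0.949 for p = 0.1
        spikes = (rng.random((200_000, 1)) < 0.1).astype(np.uint8)
        st = isi_cv_stats(recording_from(spikes))
        assert st.cvs[0] == pytest.approx(np.sqrt(0.9), abs=0.02)
        # and the ISI tail is exponential-like: ML scale near 1/p - shift
        assert st.exp_scale == pytest.approx(10.0, rel=0.1)

    def test_silent_neurons_excluded(self, rng):
        spikes = np.zeros((1000, 3), dtype=np.uint8)
        spikes[:, 0] = (rng.random(1000) < 0.2)
        st = isi_cv_stats(recording_from(spikes))
        assert st.n_excluded == 2 and st.cvs.size == 1

    def test_trained_network_cv_clusters_near_one(self, random_letters_result):
        st = isi_cv_stats(random_letters_result.recordings["spontaneous"])
        assert 0.8 <= st.cvs.mean() <= 1.2


class TestConnectionFraction:
    def test_extremes(self):
        zero = np.zeros((10, 10))
        full = np.ones((10, 10))
        np.fill_diagonal(full, 0.0)
        frac = connection_fraction([zero, full])
        np.testing.assert_allclose(frac, [0.0, 1.0])
        with pytest.raises(ValueError):
            connection_fraction([zero])

    def test_training_trace_converges(self, random_letters_result):
        # quarter-length windows: long enough that the equilibrium wobble of
        # structural turnover does not dominate the slope estimate
        trace = random_letters_result.conn_fraction
        w = trace.size // 4
        early = np.polyfit(np.arange(w), trace[:w], 1)[0]
        late = np.polyfit(np.arange(w), trace[-w:], 1)[0]
        assert abs(late) < 0.1 * abs(early)


class TestLognormalFit:
    def test_parameter_recovery(self, rng):
        w = np.zeros((80, 80))
        idx = rng.random((80, 80)) < 0.65
        np.fill_diagonal(idx, False)
        w[idx] = rng.lognormal(mean=-2.0, sigma=1.0, size=idx.sum())
        fit = fit_lognormal_weights(w)
        assert fit.n_weights >= 4000
        assert fit.mu == pytest.approx(-2.0, abs=0.1)
        assert fit.sigma == pytest.approx(1.0, abs=0.1)

    def test_uniform_weights_fit_worse_than_lognormal_sample(self, rng):
        w_uniform = rng.uniform(0.5, 1.5, size=(50, 50))
        w_ln = rng.lognormal(-1, 0.8, size=(50, 50))
        assert (fit_lognormal_weights(w_uniform).ks_lognormal
                > fit_lognormal_weights(w_ln).ks_lognormal)

    def test_too_few_weights_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_weights(np.eye(5))

    def test_trained_network_prefers_lognormal(self, random_letters_result):
        fit = fit_lognormal_weights(random_letters_result.w_ee)
        assert fit.ks_lognormal < fit.ks_normal


class TestFanoCurve:
    def test_bernoulli_mean_count_and_ff(self, rng):
        # i.i.d. Bernoulli(0.1), 5-step window: mean count 0.5, FF = 1 - p
        t = bernoulli_tensor(rng)
        curve = fano_curve(t, window=5)
        assert curve.mean_rate.mean() == pytest.approx(0.5, abs=0.05)
        assert curve.ff.mean() == pytest.approx(0.9, abs=0.05)

    def test_identical_trials_have_zero_ff(self, rng):
        t = bernoulli_tensor(rng, n_trials=30)
        t.spikes[:] = t.spikes[:1]
        curve = fano_curve(t)
        np.testing.assert_allclose(curve.ff, 0.0, atol=1e-12)

    def test_poisson_counts_give_unit_ff(self, rng):
        # Poisson surrogate trials: FF ~= 1 at every offset
        t = bernoulli_tensor(rng, n_trials=200)
        lam = 0.12
        t.spikes = np.minimum(rng.poisson(lam, size=t.spikes.shape), 1).astype(np.uint8)
        # binarized Poisson at small lam is Bernoulli(1 - exp(-lam)); use the
        # raw counts instead to make the surrogate exactly Poisson
        counts = rng.poisson(lam, size=t.spikes.shape)
        t.spikes = counts.astype(np.uint8)  # counts rarely exceed 1 but may
        curve = fano_curve(t)
        assert 0.85 <= np.nanmean(curve.ff) <= 1.1

    def test_input_units_excluded(self, rng):
        t = bernoulli_tensor(rng)
        t.input_units[:10] = True
        t.spikes[:, :, :10] = 1  # saturated input units must not contribute
        curve = fano_curve(t)
        assert curve.mean_rate.mean() == pytest.approx(0.5, abs=0.05)

    def test_window_longer_than_margin_warns(self, rng):
        t = bernoulli_tensor(rng, margin=2)
        with pytest.warns(UserWarning, match="margin"):
            curve = fano_curve(t, window=5)
        assert curve.offsets[0] > -t.pre


class TestMeanMatching:
    def test_identical_mean_distributions_keep_everything(self, rng):
        t = bernoulli_tensor(rng, n_trials=150)
        # equalize means across offsets exactly by repeating one time slice
        t.spikes[:] = t.spikes[:, :1, :]
        curve = mean_matched_fano(t, rng=rng)
        assert curve.fraction_discarded == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(curve.matched_ff, curve.ff, atol=1e-9)

    def test_matched_ff_defined_and_positive_on_heterogeneous_data(self, rng):
        # heterogeneous per-neuron rates with a rate rise after onset for half
        # of them: the mean histograms overlap, so matching discards some but
        # not all points
        n_trials, n_neurons = 120, 50
        pre = post = 8
        margin = 4
        width = margin + pre + post + 1
        base = rng.uniform(0.05, 0.2, size=n_neurons)
        p = np.tile(base, (n_trials, width, 1))
        p[:, margin + pre:, : n_neurons // 2] *= 1.5
        t = TrialTensor(
            spikes=(rng.random(p.shape) < p).astype(np.uint8),
            onset_index=margin + pre, pre=pre, post=post, margin=margin,
            conditions=np.zeros(n_trials, dtype=int),
            input_units=np.zeros(n_neurons, dtype=bool),
        )
        curve = mean_matched_fano(t, rng=rng)
        assert 0.0 < curve.fraction_discarded < 1.0
        assert np.isfinite(curve.matched_ff).all()


class TestConditionalProbabilities:
    def test_deterministic_chain(self):
        # i fires iff j fired one step earlier
        T = 2000
        rng = np.random.default_rng(0)
        sj = (rng.random(T) < 0.3).astype(np.uint8)
        spikes = np.zeros((T, 2), dtype=np.uint8)
        spikes[:, 0] = sj
        spikes[1:, 1] = sj[:-1]
        w = np.zeros((2, 2))
        w[1, 0] = 5.0
        fit = conditional_firing_probabilities(recording_from(spikes), w)
        assert fit.probabilities[0] == pytest.approx(1.0)

    def test_independent_neurons_give_baseline_rate(self, rng):
        T, n = 60_000, 20
        spikes = (rng.random((T, n)) < 0.1).astype(np.uint8)
        w = np.zeros((n, n))
        conn = rng.random((n, n)) < 0.3
        np.fill_diagonal(conn, False)
        w[conn] = 0.01
        fit = conditional_firing_probabilities(recording_from(spikes), w, conn=conn)
        assert fit.probabilities.mean() == pytest.approx(0.1, abs=0.01)

    def test_trained_network_probability_scales_with_weight(
        self, random_letters_result
    ):
        res = random_letters_result
        fit = conditional_firing_probabilities(
            res.recordings["spontaneous"], res.w_ee, conn=res.w_ee > 0
        )
        assert fit.pearson_r > 0.5
        assert fit.kappa > 0


class TestInputDrivenDriftProperty:
    def test_expected_update_proportional_to_presentation_probability(self):
        """For rare direct-input letter pairs presented at rates p and 2p,
        the expected STDP drift onto the successor pool scales with the
        presentation probability (ratio near 2, pooled over realizations)."""
        import sornlab as sl
        from sornlab.tasks import build_input_map, compile_stream

        def drift_values(seed, T=30_000, p=0.01):
            params = sl.SornParams(seed=seed)
            rngs = sl.spawn_rngs(seed, ["map", "stream", "phase"])
            imap = build_input_map(list("ABCD"), params, rng=rngs["map"])
            st = sl.init_network(params, w_eu=imap.w_eu(params.n_exc, params.w_in))
            r = rngs["stream"]
            letters = []
            while len(letters) < T:
                u = r.random()
                if u < p:
                    letters += ["A", "B"]       # pair at rate p
                elif u < 3 * p:
                    letters += ["C", "D"]       # pair at rate 2p
                else:
                    letters.append("_")
            letters = np.array(letters[:T], dtype="U8")
            sym, drive = compile_stream(letters, imap, params)
            proto = sl.PhaseProtocol(sym=sym, drive=drive, letters=letters,
                                     stdp=True, sn=True, structural=True, ip=True)
            conn0 = st.conn.copy()
            _, rec = sl.run_phase(st, proto, rngs["phase"])
            spikes = rec.spikes.astype(np.float64)
            joint = spikes[1:].T @ spikes[:-1]
            Tm = spikes.shape[0] - 1
            out = {}
            for src, dst in [("A", "B"), ("C", "D")]:
                conn = conn0[np.ix_(imap.pool(dst), imap.pool(src))]
                fwd = joint[np.ix_(imap.pool(dst), imap.pool(src))]
                rev = joint[np.ix_(imap.pool(src), imap.pool(dst))].T
                out[(src, dst)] = ((fwd - rev)[conn] / Tm)
            return out

        slow, fast = [], []
        for seed in range(1, 7):
            vals = drift_values(seed)
            slow.append(vals[("A", "B")])
            fast.append(vals[("C", "D")])
        slow = np.concatenate(slow)
        fast = np.concatenate(fast)
        assert slow.mean() > 0 and fast.mean() > 0
        assert 1.5 <= fast.mean() / slow.mean() <= 2.5


class TestStdpDriftProperty:
    def test_expected_update_tracks_weight_difference(self, random_letters_result):
        """In spontaneous activity the expected STDP update of a synapse grows
        with the weight asymmetry W_ij - W_ji (rank correlation > 0.5)."""
        res = random_letters_result
        rec = res.recordings["spontaneous"]
        spikes = rec.spikes.astype(np.float64)
        joint = spikes[1:].T @ spikes[:-1]          # counts x_i(t+1) & x_j(t)
        T = spikes.shape[0] - 1
        w = res.w_ee
        ii, jj = np.nonzero(w > 0)
        dw_expected = (joint[ii, jj] - joint[jj, ii]) / T  # / eta_stdp
        asym = w[ii, jj] - w[jj, ii]
        pos = asym > 0
        rho = scipy.stats.spearmanr(asym[pos], dw_expected[pos]).statistic
        assert rho > 0.5
        assert dw_expected[pos].mean() > 0
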