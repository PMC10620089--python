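import numpy as np
import pytest

from lplnet.snn_core import (
    DoubleExpTrace,
    InhSTDP,
    InhSTDPParams,
    LIFParams,
    NetworkTopology,
    SNNConfig,
    SpikingLPL,
    SpikingLPLParams,
    build_network,
    double_exp_filter,
    integrate_step,
    make_input_rate_traces,
    run_simulation,
)

EMPTY = np.empty(0, dtype=np.int64)


def small_topology(**kw):
    defaults = dict(n_input=50, n_exc=10, n_inh=4)
    defaults.update(kw)
    return NetworkTopology(**defaults)


class TestBuildNetwork:
    def test_default_sizes(self):
        state = build_network(NetworkTopology(), seed=0)
        assert state.W["in_e"].shape == (100, 500)
        assert state.W["ie"].shape == (100, 25)
        assert state.W["ei"].shape == (25, 100)

    def test_gaussian_ei_profile(self):
        # empirical connection frequency vs (j - 0.25 i) against the profile
        top = NetworkTopology(n_input=10, n_exc=400, n_inh=100, ei_slope=0.25)
        state = build_network(top, seed=1)
        j = np.arange(top.n_inh)[:, None]
        i = np.arange(top.n_exc)[None, :]
        d = j - 0.25 * i
        mask = state.mask["ei"]
        bins = np.arange(-8.5, 9.0, 1.0)
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (d >= lo) & (d < hi)
            n = int(sel.sum())
            if n < 200:
                continue
            p_hat = mask[sel].mean()
            p_true = np.exp(-(((lo + hi) / 2) ** 2) / 20.0)
            # binomial error with a few-sigma margin plus profile curvature
            tol = 4 * np.sqrt(max(p_true * (1 - p_true), 0.01) / n) + 0.06
            assert abs(p_hat - p_true) < tol

    def test_no_self_connections(self):
        state = build_network(small_topology(p_ii=1.0, p_ee=1.0, w_ee=0.1), seed=0)
        assert not np.any(np.diag(state.mask["ii"]))
        assert not np.any(np.diag(state.mask["ee"]))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            NetworkTopology(p_in_e=1.5)

    def test_weights_nonnegative(self):
        state = build_network(small_topology(), seed=3)
        for W in state.W.values():
            assert np.all(W >= 0)


class TestIntegrateStep:
    def test_exponential_relaxation_to_leak(self):
        params = LIFParams()
        state = build_network(small_topology(p_in_e=0.0, p_in_i=0.0), params=params, seed=0)
        state.exc.U[:] = -60.0
        for k in range(1000):  # 100 ms
            integrate_step(state, EMPTY)
        expect = params.U_leak + (-60.0 - params.U_leak) * np.exp(-100.0 / params.tau_mem)
        assert np.allclose(state.exc.U, expect, rtol=0.01)

    def test_threshold_jump_and_decay(self):
        params = LIFParams()
        state = build_network(small_topology(), params=params, seed=0)
        state.exc.U[0] = 100.0  # force a spike
        integrate_step(state, EMPTY)
        jumped = state.exc.theta[0]
        assert jumped > params.theta_rest + 99.0  # +100 mV minus one decay step
        for _ in range(50):
            state.exc.U[:] = params.U_leak  # hold below threshold
            integrate_step(state, EMPTY)
        assert state.exc.theta[0] < jumped  # decaying back toward rest

    def test_axonal_delay(self):
        params = LIFParams()
        state = build_network(
            small_topology(p_in_e=1.0, w_in_e=0.5), params=params, seed=0
        )
        g0 = state.exc.g_ampa.copy()
        spikes = np.array([0], dtype=np.int64)
        integrate_step(state, spikes)  # spike enters the queue at time t
        for k in range(7):  # t + 0.1 .. t + 0.7 ms: nothing delivered yet
            assert np.allclose(state.exc.g_ampa, 0.0)
            integrate_step(state, EMPTY)
        assert np.allclose(state.exc.g_ampa, 0.0)
        integrate_step(state, EMPTY)  # t + 0.8 ms: delivery
        assert np.any(state.exc.g_ampa > 0.4)

    def test_membrane_bounded(self):
        state = build_network(small_topology(p_in_e=1.0, w_in_e=2.0), seed=0)
        rng = np.random.default_rng(0)
        for k in range(5000):
            idx = np.flatnonzero(rng.random(50) < 0.05)
            integrate_step(state, idx)
            assert np.all(state.exc.U <= 0.0 + 1.0)
            assert np.all(state.exc.U >= -80.0 - 1.0)

    def test_nonfinite_state_surfaced(self):
        state = build_network(small_topology(), seed=0)
        state.exc.U[3] = np.nan
        with pytest.raises(FloatingPointError, match="neuron 3"):
            integrate_step(state, EMPTY)


class TestDoubleExpFilter:
    def test_zero_input(self):
        out = double_exp_filter(np.zeros(100), 2.0, 10.0, 0.1)
        assert np.allclose(out, 0.0)

    def test_linearity(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        fa = double_exp_filter(a, 2.0, 10.0, 0.1)
        fb = double_exp_filter(b, 2.0, 10.0, 0.1)
        fab = double_exp_filter(a + b, 2.0, 10.0, 0.1)
        assert np.allclose(fa + fb, fab, atol=1e-12)

    def test_impulse_response_matches_closed_form(self):
        dt = 1e-3
        tau_r, tau_f = 0.02, 0.1
        n = 1000
        x = np.zeros(n)
        x[0] = 1.0 / dt  # unit-area impulse
        out = double_exp_filter(x, tau_r, tau_f, dt)
        t = (np.arange(n) + 1) * dt
        expect = (np.exp(-t / tau_f) - np.exp(-t / tau_r)) / (tau_f - tau_r)
        err = np.max(np.abs(out - expect)) / np.max(expect)
        assert err < 5 * dt / tau_r  # Euler error O(dt)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            DoubleExpTrace((3,), -1.0, 1.0, 0.1)


class TestSpikingLPL:
    DT = 1e-4

    def make_rule(self, **kw):
        defaults = dict(moments_frozen=True, sbar_init=0.0, sigma2_init=0.1)
        defaults.update(kw)
        return SpikingLPL(1, 1, SpikingLPLParams(), self.DT, **defaults)

    def test_silent_presynaptic_no_change(self):
        rule = self.make_rule(sbar_init=20.0)
        U = np.array([-55.0])
        post = np.zeros(1, dtype=bool)
        total = 0.0
        for k in range(2000):
            post[0] = k % 100 == 0  # active post, silent pre
            total += abs(float(rule.step(EMPTY, post, U)[0, 0]))
        assert total == 0.0

    def test_transmitter_triggered_growth(self):
        # active pre, permanently silent post, error terms zero
        rule = self.make_rule(sbar_init=0.0)
        p = rule.p
        U = np.array([-70.0])
        post = np.zeros(1, dtype=bool)
        one = np.array([0], dtype=np.int64)
        total = 0.0
        n_pre = 0
        for k in range(5000):
            fire = k % 500 == 0
            dW = rule.step(one if fire else EMPTY, post, U)
            total += float(dW[0, 0])
            n_pre += int(fire)
        assert total == pytest.approx(n_pre * p.eta * p.delta)

    def test_periodic_post_self_predicting(self):
        # post period equals the prediction horizon: the filtered
        # predictive error integrates to ~zero after the transient
        rule = SpikingLPL(1, 1, SpikingLPLParams(), self.DT,
                          include_hebb=False, moments_frozen=True)
        period = int(round(rule.p.pred_delay / self.DT))
        U = np.array([-60.0])
        post = np.zeros(1, dtype=bool)
        vals = []
        n = 60 * period
        for k in range(n):
            post[0] = k % period == 0
            rule.step(EMPTY, post, U)
            if k > 20 * period:  # skip the transient of the first spike
                vals.append(rule.err.b[0])
        # after the transient, every spike is cancelled by its delayed copy
        assert np.max(np.abs(vals)) < 1e-8  # Hz; spikes alone peak at ~60

    def test_surrogate_derivative_shape(self):
        rule = self.make_rule()
        U = np.array([-50.0, -49.0, -51.0, -40.0])
        fp = rule.surrogate_fprime(U)
        assert fp[0] == pytest.approx(1.0)
        assert fp[1] == pytest.approx(0.25)
        assert fp[2] == pytest.approx(0.25)
        assert fp[3] < fp[1]


class TestInhSTDP:
    DT = 1e-4

    def test_no_spikes_no_change(self):
        rule = InhSTDP(2, 3, InhSTDPParams(), self.DT)
        W = np.full((3, 2), 0.5)
        mask = np.ones_like(W, dtype=bool)
        before = W.copy()
        for _ in range(100):
            rule.step(np.zeros(2, bool), np.zeros(3, bool), W, mask)
        assert np.array_equal(W, before)

    def test_single_pair_hand_computed(self):
        # post spike, then pre spike 5 ms later: explicit trace integration
        params = InhSTDPParams()
        rule = InhSTDP(1, 1, params, self.DT)
        W = np.array([[1.0]])
        mask = np.ones((1, 1), bool)
        lag = 50  # 5 ms
        pre = np.zeros(1, bool)
        post = np.zeros(1, bool)
        for k in range(200):
            post[0] = k == 0
            pre[0] = k == lag
            rule.step(pre, post, W, mask)
        # oracle: post trace jumps to 1 at k=0 then decays (lag steps of
        # multiplicative decay applied before the pre-spike update)
        x_post = (1.0 - self.DT / params.tau_stdp) ** lag
        expect = 1.0 + params.zeta * (x_post - 2 * params.kappa * params.tau_stdp)
        assert W[0, 0] == pytest.approx(expect, rel=1e-12)

    def test_literal_form_has_no_depression(self):
        params = InhSTDPParams(literal_form=True)
        rule = InhSTDP(1, 1, params, self.DT)
        W = np.array([[1.0]])
        mask = np.ones((1, 1), bool)
        pre = np.zeros(1, bool)
        for k in range(1000):
            pre[0] = k % 100 == 0
            rule.step(pre, np.zeros(1, bool), W, mask)
        assert W[0, 0] > 1.0  # pre spikes alone potentiate: no fixed point


@pytest.fixture(scope="module")
def quick_sim():
    top = NetworkTopology(n_input=50, n_exc=10, n_inh=4)
    cfg = SNNConfig(topology=top, duration=5.0, seed=3)
    return cfg, run_simulation(cfg)


class TestRunSimulation:
    def test_deterministic(self, quick_sim):
        cfg, res = quick_sim
        res2 = run_simulation(cfg)
        assert np.array_equal(res.raster.times, res2.raster.times)
        assert np.array_equal(res.raster.ids, res2.raster.ids)
        assert np.array_equal(res.w_in_e, res2.w_in_e)

    def test_backends_agree(self):
        top = NetworkTopology(n_input=50, n_exc=10, n_inh=4)
        cfg = SNNConfig(topology=top, duration=2.0, seed=5)
        a = run_simulation(cfg, backend="numba")
        b = run_simulation(cfg, backend="numpy")
        assert np.array_equal(a.raster.ids, b.raster.ids)
        assert np.allclose(a.raster.times, b.raster.times)
        assert np.allclose(a.w_in_e, b.w_in_e)
        assert np.allclose(a.w_ie, b.w_ie)

    def test_weights_stay_in_bounds(self, quick_sim):
        cfg, res = quick_sim
        assert np.all(res.w_in_e >= cfg.lpl.w_min)
        assert np.all(res.w_in_e <= cfg.lpl.w_max)
        assert np.all(res.w_ie >= 0)

    def test_unknown_ablation_rejected(self):
        with pytest.raises(ValueError):
            SNNConfig(ablation="bogus")

    def test_snapshots_time_ordered(self, quick_sim):
        _, res = quick_sim
        t = res.snapshots["t"]
        assert np.all(np.diff(t) > 0)

    def test_input_traces_cover_five_populations(self):
        tr = make_input_rate_traces(n_per_pop=10, seed=0)
        assert set(tr) == {"P0", "P1", "P2", "P1_ctl", "P2_ctl"}
        p0 = tr["P0"][0]
        assert np.allclose(p0, 5.0)

    def test_dt_halving_rate_convergence(self):
        top = NetworkTopology(n_input=50, n_exc=10, n_inh=4)
        rates = []
        for dt in (0.1, 0.05):
            cfg = SNNConfig(
                topology=top, duration=20.0, seed=9,
                lif=LIFParams(dt=dt), plastic_input=False, plastic_inhib=False,
            )
            rates.append(run_simulation(cfg).exc_rate)
        assert abs(rates[0] - rates[1]) / max(rates[1], 1e-9) < 0.05

    def test_inhib_off_raises_rates(self):
        top = NetworkTopology(n_input=100, n_exc=20, n_inh=5)
        base = run_simulation(
            SNNConfig(topology=top, duration=15.0, plastic_input=False, seed=2)
        )
        no_inh = run_simulation(
            SNNConfig(topology=top, duration=15.0, plastic_input=False,
                      ablation="inhib_off", seed=2)
        )
        assert no_inh.exc_rate > base.exc_rate


class TestInhibitoryFixedPoint:
    def test_feedforward_motif_settles_at_target_rate(self):
        # excitatory drive plus plastic inhibition: postsynaptic rate
        # converges to kappa (learning rate raised to fit the short run)
        top = NetworkTopology(n_input=100, n_exc=10, n_inh=4, w_in_e=0.35, w_in_i=0.35)
        cfg = SNNConfig(
            topology=top, duration=80.0, plastic_input=False, plastic_inhib=True,
            istdp=InhSTDPParams(zeta=5e-3), seed=1,
        )
        res = run_simulation(cfg)
        assert res.exc_rate == pytest.approx(10.0, rel=0.2)
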