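import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lplnet.metrics import cluster_selectivity
from lplnet.rate_lpl import (
    LPLHyperparams,
    PairedBatch,
    RateLayer,
    decorrelation_loss,
    get_activation,
    hebbian_loss,
    lpl_rule_form1,
    lpl_rule_form2,
    lpl_weight_update,
    oja_update,
    predictive_loss,
    sliding_threshold,
    train_single_neuron,
    update_moments,
)
from lplnet.synthetic_data import ClusterSequenceConfig, gen_cluster_pairs


def frozen_mean_loss(W, x_curr, z_prev0, zbar0, hp, f):
    """Independent evaluation of the combined objective with the stated
    stop-gradient conventions (previous activity and mean frozen)."""
    B, _ = x_curr.shape
    M = W.shape[0]
    z = f(x_curr @ W.T)
    L = np.sum((z - z_prev0) ** 2) / (2 * M * B)
    s2 = np.sum((z - zbar0) ** 2, axis=0) / (B - 1)
    L += hp.lambda1 * np.mean(-np.log(s2 + hp.epsilon))
    if M >= 2 and hp.lambda2 > 0:
        d = z - zbar0
        sq = d**2
        tot = sq.sum(axis=1)
        L += hp.lambda2 * np.sum(sq * (tot[:, None] - sq)) / ((B - 1) * (M * M - M))
    return L


class TestLosses:
    def test_predictive_zero_when_identical(self):
        z = np.ones((3, 2))
        assert predictive_loss(z, z) == 0.0

    def test_predictive_hand_values(self):
        assert predictive_loss(np.array([[2.0]]), np.array([[1.0]])) == pytest.approx(0.5)
        assert predictive_loss(np.array([[1.0], [0.0]]),
                               np.array([[0.0], [1.0]])) == pytest.approx(0.5)

    def test_predictive_shape_mismatch(self):
        with pytest.raises(ValueError):
            predictive_loss(np.ones((2, 2)), np.ones((3, 2)))

    def test_hebbian_unit_variance(self, rng):
        z = rng.normal(size=(200, 3))
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        assert hebbian_loss(z) == pytest.approx(0.0, abs=1e-12)

    def test_hebbian_hand_value(self):
        assert hebbian_loss(np.array([[0.0], [2.0]])) == pytest.approx(-np.log(2.0))

    def test_hebbian_log_scaling(self, rng):
        z = rng.normal(size=(50, 4))
        c = 3.0
        assert hebbian_loss(c * z) == pytest.approx(hebbian_loss(z) - 2 * np.log(c))

    def test_hebbian_needs_batch(self):
        with pytest.raises(ValueError):
            hebbian_loss(np.ones((1, 2)))

    def test_decorrelation_zero_deviations(self):
        assert decorrelation_loss(np.ones((4, 3))) == 0.0

    def test_decorrelation_hand_value(self):
        z = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert decorrelation_loss(z) == pytest.approx(2.0)

    def test_decorrelation_single_neuron_convention(self, rng):
        assert decorrelation_loss(rng.normal(size=(5, 1))) == 0.0

    def test_decorrelation_covariance_variant(self, rng):
        z = rng.normal(size=(30, 4))
        d = z - z.mean(0)
        C = d.T @ d / 29
        off = C - np.diag(np.diag(C))
        expect = np.sum(off**2) / 12
        assert decorrelation_loss(z, variant="covariance") == pytest.approx(expect)


class TestWeightUpdate:
    def test_pure_decay_when_all_errors_vanish(self):
        # constant input: z_curr == z_prev and z_curr == z_bar for all b
        rng = np.random.default_rng(0)
        hp = LPLHyperparams(eta=0.1, lambda1=1.0, lambda2=1.0, eta_w=0.5)
        layer = RateLayer(3, 2, hyper=hp, rng=rng)
        x = np.tile(rng.normal(size=3), (4, 1))
        dW = lpl_weight_update(layer, PairedBatch(x, x))
        assert np.allclose(dW, -hp.eta * hp.eta_w * layer.W)

    @pytest.mark.parametrize("activation", ["linear", "tanh", "softplus0"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_numerical_gradient(self, activation, seed):
        rng = np.random.default_rng(seed)
        N, M, B = 3, 2, 4
        hp = LPLHyperparams(eta=1.0, lambda1=0.7, lambda2=1.3, eta_w=0.0)
        layer = RateLayer(N, M, hyper=hp, activation=activation, rng=rng)
        f, _ = get_activation(activation)
        x_prev = rng.normal(size=(B, N))
        x_curr = rng.normal(size=(B, N))
        z_prev0 = layer.forward(x_prev)
        z0 = layer.forward(x_curr)
        zbar0 = z0.mean(axis=0)
        dW = lpl_weight_update(layer, PairedBatch(x_prev, x_curr))
        num = np.zeros_like(layer.W)
        eps = 1e-6
        for i in range(M):
            for j in range(N):
                Wp = layer.W.copy()
                Wp[i, j] += eps
                Wm = layer.W.copy()
                Wm[i, j] -= eps
                num[i, j] = (
                    frozen_mean_loss(Wp, x_curr, z_prev0, zbar0, hp, f)
                    - frozen_mean_loss(Wm, x_curr, z_prev0, zbar0, hp, f)
                ) / (2 * eps)
        rel = np.abs(dW + num) / (np.abs(num) + 1e-12)
        assert rel.max() < 1e-5

    def test_single_neuron_predictive_only_closed_form(self):
        # lambda1 = lambda2 = eta_w = 0, B = 1, linear f: dW_j = -eta (z - z_prev) x_j
        rng = np.random.default_rng(3)
        hp = LPLHyperparams(eta=0.2, lambda1=0.0, lambda2=0.0, eta_w=0.0)
        layer = RateLayer(3, 1, hyper=hp, rng=rng)
        xp = rng.normal(size=(1, 3))
        xc = rng.normal(size=(1, 3))
        z = float(layer.forward(xc)[0, 0])
        zp = float(layer.forward(xp)[0, 0])
        dW = lpl_weight_update(layer, PairedBatch(xp, xc), refresh_moments=False)
        assert np.allclose(dW, -hp.eta * (z - zp) * xc)

    def test_small_batch_with_batch_moments_rejected(self):
        layer = RateLayer(2, 1, rng=np.random.default_rng(0))
        b = PairedBatch(np.ones((1, 2)), np.ones((1, 2)))
        with pytest.raises(ValueError):
            lpl_weight_update(layer, b)


class TestMoments:
    def test_batch_moments_hand_value(self):
        layer = RateLayer(1, 1, rng=np.random.default_rng(0))
        z = np.array([[0.0], [2.0]])
        z_bar, s2 = update_moments(layer, z)
        assert z_bar[0] == pytest.approx(1.0)
        assert s2[0] == pytest.approx(2.0)

    def test_stale_moments_lag_one_batch(self):
        layer = RateLayer(1, 1, moment_mode="stale", rng=np.random.default_rng(0))
        z1 = np.array([[0.0], [2.0]])
        z2 = np.array([[5.0], [7.0]])
        update_moments(layer, z1)
        z_bar, s2 = update_moments(layer, z2)
        assert z_bar[0] == pytest.approx(1.0)  # moments of z1, not z2
        assert s2[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("mode", ["batch", "stale", "exponential"])
    def test_constant_stream_converges(self, mode):
        layer = RateLayer(1, 1, moment_mode=mode, moment_tau=5.0,
                          rng=np.random.default_rng(0))
        z = np.full((8, 1), 3.0)
        for _ in range(200):
            z_bar, s2 = update_moments(layer, z)
        assert z_bar[0] == pytest.approx(3.0, abs=1e-6)
        assert s2[0] == pytest.approx(0.0, abs=1e-6)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            RateLayer(1, 1, moment_mode="bogus", rng=np.random.default_rng(0))


class TestSlidingThreshold:
    def test_reduces_to_mean_when_static(self):
        assert sliding_threshold(1.5, 2.0, 0.0) == pytest.approx(1.5)

    def test_hand_value(self):
        assert sliding_threshold(1.0, 2.0, 0.5, lam=1.0) == pytest.approx(2.0)

    def test_zero_lambda_rejected(self):
        with pytest.raises(ValueError):
            sliding_threshold(1.0, 2.0, 0.5, lam=0.0)

    @given(
        z=st.floats(-5, 5), z_bar=st.floats(-5, 5), dz=st.floats(-5, 5),
        s2=st.floats(0.01, 10), x=st.floats(-3, 3), fp=st.floats(0.01, 2),
        lam=st.floats(0.1, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_two_forms_identical(self, z, z_bar, dz, s2, x, fp, lam):
        a = lpl_rule_form1(x, fp, dz, z, z_bar, s2, eta=0.3, lam=lam)
        b = lpl_rule_form2(x, fp, dz, z, z_bar, s2, eta=0.3, lam=lam)
        assert np.isclose(a, b, rtol=1e-12, atol=1e-12)


class TestOja:
    def test_fixed_point_at_leading_eigenvector(self, rng):
        C = np.array([[3.0, 1.0], [1.0, 2.0]])
        w = np.linalg.eigh(C)[1][:, -1]
        x = rng.multivariate_normal(np.zeros(2), C, size=200_000)
        dw = oja_update(w, x, eta=1.0)
        assert np.linalg.norm(dw) < 0.02

    def test_converges_to_pc1(self, rng):
        C = np.diag([4.0, 1.0])
        x = rng.multivariate_normal(np.zeros(2), C, size=5000)
        w = rng.normal(size=2) * 0.3
        for _ in range(600):
            sel = rng.integers(0, 5000, size=128)
            w += oja_update(w, x[sel], eta=0.1)
        pc1 = np.linalg.eigh(np.cov(x.T))[1][:, -1]
        assert abs(abs(w @ pc1) - 1.0) < 0.05  # unit norm and aligned

    def test_cluster_data_high_noise_aligns_with_y(self):
        cfg = ClusterSequenceConfig(sigma_y=2.0, seed=0)
        res = train_single_neuron(cfg, rule="oja", n_steps=1200, seed=0)
        w = res.final_w / np.linalg.norm(res.final_w)
        assert abs(w[1]) > 0.95


class TestSingleNeuron:
    def test_lpl_selective_at_high_noise(self):
        cfg = ClusterSequenceConfig(sigma_y=2.0, crossover_prob=0.0, seed=1)
        res = train_single_neuron(cfg, rule="lpl", n_steps=1500, seed=1)
        probe = gen_cluster_pairs(cfg, n_pairs=4000, rng=np.random.default_rng(2))
        z = probe.x_curr @ res.final_w
        chi = cluster_selectivity(
            z[probe.labels_curr == 1].mean(), z[probe.labels_curr == 0].mean(),
            z.max(), z.min(),
        )
        assert chi > 0.5

    def test_hebb_off_activity_collapses(self):
        cfg = ClusterSequenceConfig(sigma_y=1.0, seed=0)
        res = train_single_neuron(cfg, rule="hebb_off", n_steps=12_000, seed=0)
        assert res.mean_abs_activity[-1] < 1e-2 * res.mean_abs_activity[0]

    def test_pred_off_keeps_activity_bounded_away_from_zero(self):
        cfg = ClusterSequenceConfig(sigma_y=1.0, seed=0)
        res = train_single_neuron(cfg, rule="pred_off", n_steps=1500, seed=0)
        assert res.activity_variance[-1] > 1e-2

    def test_collapse_dichotomy_variance(self):
        cfg = ClusterSequenceConfig(sigma_y=1.0, seed=4)
        pred_only = train_single_neuron(cfg, rule="hebb_off", n_steps=12_000, seed=4)
        hebb_only = train_single_neuron(cfg, rule="pred_off", n_steps=1500, seed=4)
        assert pred_only.activity_variance[-1] < 1e-4 * pred_only.activity_variance[0]
        assert hebb_only.activity_variance[-1] > 1e-2

    def test_no_var_modulation_degenerates(self):
        # without the variance denominator the activity runs away (or
        # collapses) for at least one Hebbian strength
        cfg = ClusterSequenceConfig(sigma_y=1.0, seed=2)
        degenerate = []
        for lam1 in (0.1, 1.0, 10.0):
            hyper = LPLHyperparams(eta=0.05, lambda1=lam1)
            with np.errstate(over="ignore", invalid="ignore"):
                res = train_single_neuron(
                    cfg, rule="no_var_modulation", hyper=hyper, n_steps=300, seed=2
                )
            v0, v1 = res.activity_variance[0], res.activity_variance[-1]
            degenerate.append(
                (not np.isfinite(v1)) or v1 > 1e3 * v0 or v1 < 1e-6 * v0
            )
        assert any(degenerate)

    def test_zero_learning_rate_freezes_weights(self):
        cfg = ClusterSequenceConfig(sigma_y=0.5, seed=0)
        res = train_single_neuron(
            cfg, rule="lpl", hyper=LPLHyperparams(eta=0.0), n_steps=50, seed=0
        )
        assert np.allclose(res.weights[0], res.weights[-1])

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            train_single_neuron(ClusterSequenceConfig(), rule="bcm", n_steps=1)
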