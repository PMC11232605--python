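"""Risk network: forward ops vs. loop oracles, closed-form losses,
gradient checks and training reductions."""

import numpy as np
import pytest

from sepsaki._autodiff import Tensor
from sepsaki.exceptions import ConfigError, ValidationError
from sepsaki.risk import (AKIRiskModel, AKIRiskResults,
                          PatientSample, _init_params, _representation,
                          attention_weights, classifier_loss,
                          correlation_matrix, discriminator_loss, encode,
                          fuse, joint_objective,
                          knowledge_aware_representation,
                          reconstruction_loss)


def softmax(v):
    e = np.exp(v - v.max())
    return e / e.sum()


class TestEncode:
    def test_identity(self):
        x = np.array([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(encode(x, np.eye(3), np.zeros(3)), x)

    def test_zero_input_gives_bias(self):
        b = np.array([0.3, -0.1])
        np.testing.assert_array_equal(
            encode(np.zeros(4), np.zeros((2, 4)), b), b)

    def test_hand_example(self):
        W = np.array([[1.0, 2.0], [0.0, -1.0]])
        x = np.array([3.0, 4.0])
        b = np.array([0.5, 0.5])
        np.testing.assert_allclose(encode(x, W, b), [11.5, -3.5])

    def test_shape_mismatch(self):
        with pytest.raises(ConfigError):
            encode(np.zeros(3), np.zeros((2, 4)), np.zeros(2))


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        x = np.array([1.0, 2.0])
        assert reconstruction_loss(x, x) == 0.0

    def test_unit_residual(self):
        assert reconstruction_loss(np.array([1.0, 0.0]),
                                   np.array([0.0, 0.0])) == 1.0

    def test_quadratic_homogeneity(self, rng):
        x = rng.normal(size=6)
        d = rng.normal(size=6)
        base = reconstruction_loss(x, x + d)
        assert reconstruction_loss(x, x + 3 * d) == pytest.approx(
            9 * base, rel=1e-12)

    def test_batch_mean(self, rng):
        X = rng.normal(size=(4, 3))
        Xh = rng.normal(size=(4, 3))
        per = [reconstruction_loss(X[i], Xh[i]) for i in range(4)]
        assert reconstruction_loss(X, Xh) == pytest.approx(np.mean(per))


class TestCoAttention:
    def test_basis_outer_product(self):
        e1 = np.array([1.0, 0.0])
        e2 = np.array([0.0, 1.0])
        M = correlation_matrix(e1, e2)
        assert M[0, 1] == 1.0 and M.sum() == 1.0

    def test_zero_vector_zero_matrix(self):
        assert not correlation_matrix(np.zeros(3),
                                      np.ones(3)).any()

    def test_rank_at_most_one(self, rng):
        for _ in range(20):
            M = correlation_matrix(rng.normal(size=5), rng.normal(size=5))
            s = np.linalg.svd(M, compute_uv=False)
            assert (s[1:] < 1e-10).all()

    def test_constant_matrix_uniform_attention(self):
        a_p, a_k = attention_weights(np.full((4, 4), 2.7))
        np.testing.assert_allclose(a_p, np.full(4, 0.25))
        np.testing.assert_allclose(a_k, np.full(4, 0.25))

    def test_attention_weights_are_distributions(self, rng):
        a_p, a_k = attention_weights(rng.normal(size=(6, 6)))
        for a in (a_p, a_k):
            assert a.sum() == pytest.approx(1.0)
            assert (a > 0).all()

    def test_two_by_two_hand_softmax(self):
        M = np.array([[1.0, 0.0], [0.0, 0.0]])
        a_p, a_k = attention_weights(M)
        np.testing.assert_allclose(a_p, softmax(np.array([0.5, 0.0])),
                                   atol=1e-12)
        np.testing.assert_allclose(a_p, [0.62245933, 0.37754067],
                                   atol=1e-6)

    def test_fuse_zero_inputs(self):
        z = np.zeros(3)
        b_p, b_k = fuse(z, z, z, z, np.eye(3), np.eye(3))
        assert not b_p.any() and not b_k.any()

    def test_fuse_bounded(self, rng):
        d = 4
        b_p, b_k = fuse(rng.normal(size=d), rng.normal(size=d),
                        rng.random(d), rng.random(d),
                        rng.normal(size=(d, d)), rng.normal(size=(d, d)))
        assert (np.abs(b_p) < 1).all() and (np.abs(b_k) < 1).all()

    def test_fuse_hand_example(self):
        z_p = np.array([1.0, 2.0])
        z_k = np.array([0.5, -1.0])
        alpha = np.array([0.5, 0.5])
        b_p, b_k = fuse(z_p, z_k, alpha, alpha, np.eye(2), np.eye(2))
        np.testing.assert_allclose(b_p, np.tanh([1.25, 1.5]), atol=1e-12)
        np.testing.assert_allclose(b_k, np.tanh([1.0, 0.0]), atol=1e-12)

    def test_identity_gate_concatenates_latents(self):
        z_p = np.array([0.3, -0.2])
        z_k = np.array([1.0, 0.5])
        pi = knowledge_aware_representation(np.ones(2), np.ones(2),
                                            z_p, z_k)
        np.testing.assert_array_equal(pi, np.concatenate([z_p, z_k]))

    def test_representation_length(self, rng):
        for d in (1, 3, 8):
            pi = knowledge_aware_representation(
                np.tanh(rng.normal(size=d)), np.tanh(rng.normal(size=d)),
                rng.normal(size=d), rng.normal(size=d))
            assert pi.shape == (2 * d,)


class TestLosses:
    def test_blind_discriminator_loss(self, rng):
        const_half = lambda pi: np.full(len(np.atleast_2d(pi)), 0.5)
        val = discriminator_loss(const_half, rng.normal(size=(5, 4)),
                                 rng.normal(size=(7, 4)))
        assert val == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_perfect_discrimination_loss_vanishes(self, rng):
        sharp = lambda pi: np.where(np.atleast_2d(pi)[:, 0] > 0,
                                    1 - 1e-9, 1e-9)
        src = np.abs(rng.normal(size=(6, 4))) + 0.1
        tgt = -np.abs(rng.normal(size=(6, 4))) - 0.1
        assert discriminator_loss(sharp, src, tgt) < 1e-6

    def test_swap_symmetry(self, rng):
        d = lambda pi: 1 / (1 + np.exp(-np.atleast_2d(pi).sum(axis=1)))
        d_flip = lambda pi: 1 - d(pi)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(4, 3))
        assert discriminator_loss(d, a, b) == pytest.approx(
            discriminator_loss(d_flip, b, a), rel=1e-12)

    def test_uniform_classifier_binary_loss(self, rng):
        c = lambda pi: np.full((len(np.atleast_2d(pi)), 2), 0.5)
        val = classifier_loss(c, rng.normal(size=(8, 4)),
                              rng.integers(0, 2, 8))
        assert val == pytest.approx(np.log(2), abs=1e-12)

    def test_oracle_classifier_loss_zero(self):
        labels = np.array([0, 1, 1])
        onehot = np.eye(2)[labels]
        c = lambda pi: onehot
        assert classifier_loss(c, np.zeros((3, 4)), labels) == pytest.approx(
            0.0, abs=1e-9)

    def test_duplicating_batch_keeps_mean(self, rng):
        pi = rng.normal(size=(5, 4))
        y = rng.integers(0, 2, 5)
        c = lambda z: 1 / (1 + np.exp(-np.atleast_2d(z)[:, :2]))
        c_norm = lambda z: (lambda p: p / p.sum(1, keepdims=True))(c(z))
        single = classifier_loss(c_norm, pi, y)
        doubled = classifier_loss(c_norm, np.vstack([pi, pi]),
                                  np.concatenate([y, y]))
        assert doubled == pytest.approx(single, rel=1e-12)

    def test_out_of_range_label(self):
        c = lambda pi: np.full((1, 2), 0.5)
        with pytest.raises(ValidationError):
            classifier_loss(c, np.zeros((1, 4)), [2])

    def test_joint_objective_arithmetic(self):
        assert joint_objective(1.0, 2.0, 3.0, 0.5, 0.1) == pytest.approx(
            2.3)
        assert joint_objective(1.7, 9.9, 4.2, 0.0, 0.0) == 1.7

    def test_joint_objective_linear_in_lambdas(self):
        base = joint_objective(1.0, 2.0, 3.0, 0.0, 0.0)
        assert joint_objective(1.0, 2.0, 3.0, 0.2, 0.0) - base == \
            pytest.approx(0.4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigError):
            joint_objective(1, 1, 1, -0.1, 0)


class TestBatchForwardMatchesLoopOracle:
    """The vectorised batch path must agree with an explicit per-sample
    evaluation built from the single-vector operations."""

    def test_agreement_to_1e10(self, rng):
        p, d_k, d_z, hidden, K = 4, 4, 4, 3, 2
        for _ in range(100):
            params = _init_params(p, d_k, d_z, hidden, K, rng)
            tensors = {k: Tensor(v) for k, v in params.items()}
            Xp = rng.normal(size=(3, p))
            Xk = rng.normal(size=(3, d_k))
            out = _representation(tensors, Tensor(Xp), Tensor(Xk))
            for i in range(3):
                z_p = encode(Xp[i], params["W_p1"], params["b_p1"])
                z_k = encode(Xk[i], params["W_k1"], params["b_k1"])
                M = correlation_matrix(z_p, z_k)
                a_p, a_k = attention_weights(M)
                b_p, b_k = fuse(z_p, z_k, a_p, a_k, params["U_p1"],
                                params["U_k1"])
                pi = knowledge_aware_representation(b_p, b_k, z_p, z_k)
                np.testing.assert_allclose(out["Pi"].value[i], pi,
                                           atol=1e-10)
                np.testing.assert_allclose(
                    out["Xk_hat"].value[i],
                    encode(z_k, params["W_k2"], params["b_k2"]),
                    atol=1e-10)


class TestGradients:
    def _total_loss(self, values, Xp_s, Xk_s, y_s, Xp_t, Xk_t,
                    lam1, lam2):
        """Joint objective as a pure function of parameter values (no
        gradient reversal: plain L_cls + lam1 L_adv + lam2 L_rec)."""
        from sepsaki.risk import _classify, _cross_entropy, _discriminate
        params = {k: Tensor(v, requires_grad=True)
                  for k, v in values.items()}
        rs = _representation(params, Tensor(Xp_s), Tensor(Xk_s))
        rt = _representation(params, Tensor(Xp_t), Tensor(Xk_t))
        diff = rs["Xk_hat"] - Tensor(Xk_s)
        l_rec = (diff * diff).sum(axis=1).mean()
        l_cls = _cross_entropy(_classify(params, rs["Pi"]), y_s)
        eps = 1e-12
        d_s = _discriminate(params, rs["Pi"])
        d_t = _discriminate(params, rt["Pi"])
        l_adv = (-(d_s.clip(eps, 1 - eps).log()).mean()
                 - ((1 - d_t).clip(eps, 1 - eps).log()).mean())
        total = l_cls + lam1 * l_adv + lam2 * l_rec
        return total, params

    def test_analytic_matches_central_differences(self, rng):
        p, d_k, d_z, hidden, K = 3, 3, 3, 3, 2
        n_checks = 0
        for _ in range(5):
            values = _init_params(p, d_k, d_z, hidden, K, rng)
            Xp_s = rng.normal(size=(4, p))
            Xk_s = rng.normal(size=(4, d_k))
            y_s = rng.integers(0, K, 4)
            Xp_t = rng.normal(size=(3, p))
            Xk_t = rng.normal(size=(3, d_k))
            args = (Xp_s, Xk_s, y_s, Xp_t, Xk_t, 0.3, 0.2)
            total, params = self._total_loss(values, *args)
            total.backward()
            eps = 1e-6
            for name in values:
                grad = params[name].grad
                flat = values[name].reshape(-1)
                for idx in rng.choice(flat.size,
                                      size=min(4, flat.size),
                                      replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = self._total_loss(values, *args)[0].value
                    flat[idx] = orig - eps
                    lm = self._total_loss(values, *args)[0].value
                    flat[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = grad.reshape(-1)[idx]
                    assert ana == pytest.approx(
                        num, rel=1e-5, abs=1e-8), name
                    n_checks += 1
        assert n_checks >= 100


def _tiny_problem(rng, n=30, p=4, d_k=3):
    Xs = rng.normal(size=(n, p))
    Ks = rng.normal(size=(n, d_k))
    beta = np.array([1.5, -1.5, 0.0, 0.0])
    ys = (rng.random(n) < 1 / (1 + np.exp(-Xs @ beta))).astype(int)
    if ys.min() == ys.max():
        ys[0] = 1 - ys[0]
    Xt = rng.normal(size=(n, p)) + np.array([0, 0, 1.0, 1.0])
    Kt = rng.normal(size=(n, d_k))
    return Xs, Ks, ys, Xt, Kt


class TestTraining:
    def test_lam1_zero_reduces_to_plain_supervised(self, rng):
        # with lam1 = 0 the discriminator never feeds back into the
        # representation: both adversarial schemes give the same
        # classifier/reconstruction traces
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        m = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4)
        grl = m.fit(lam1=0.0, epochs=20, seed=3,
                    scheme="gradient-reversal")
        alt = m.fit(lam1=0.0, epochs=20, seed=3, scheme="alternating")
        np.testing.assert_allclose(grl.traces["cls"], alt.traces["cls"],
                                   rtol=1e-10)
        np.testing.assert_allclose(grl.traces["rec"], alt.traces["rec"],
                                   rtol=1e-10)

    def test_fixed_seed_reproducible(self, rng):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        m = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4)
        a = m.fit(epochs=10, seed=5)
        b = m.fit(epochs=10, seed=5)
        for k in a.state.params:
            np.testing.assert_array_equal(a.state.params[k],
                                          b.state.params[k])

    def test_losses_finite_and_nonnegative_throughout(self, rng):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        res = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4).fit(
            epochs=50, seed=1)
        for key in ("cls", "adv", "rec", "total"):
            tr = res.traces[key]
            assert np.isfinite(tr).all()
            assert (tr >= 0).all()

    def test_classifier_learns_source(self, rng):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng, n=100)
        res = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4).fit(
            epochs=150, seed=1)
        assert res.traces["cls"][-1] < res.traces["cls"][0]

    def test_alternating_scheme_runs(self, rng):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        res = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4).fit(
            epochs=10, seed=1, scheme="alternating")
        assert np.isfinite(res.traces["total"]).all()

    def test_no_shift_makes_adversarial_training_a_wash(self):
        # zero covariate shift: both centers share P(x), so adversarial
        # alignment should neither help nor hurt target AUC (paired
        # t-test across replicate cohorts, alpha = 0.05)
        from scipy import stats
        from sklearn.metrics import roc_auc_score

        from sepsaki.simulate import CohortSpec, make_cohort
        diffs = []
        for seed in range(8):
            spec = CohortSpec(n_source=200, n_target=200, p=6,
                              shift=(0.0,) * 6, seed=seed)
            cohort, man = make_cohort(spec)
            r = np.random.default_rng(seed)
            Ks = r.normal(size=(200, 4))
            Kt = r.normal(size=(200, 4))
            xcols = [f"x{j}" for j in range(6)]
            Xs = cohort.source[xcols].to_numpy()
            Xt = cohort.target[xcols].to_numpy()
            aucs = {}
            for lam1 in (0.1, 0.0):
                res = AKIRiskModel(Xs, Ks, man.source_labels, Xt, Kt,
                                   d_z=8, hidden=8).fit(
                    lam1=lam1, epochs=200, learning_rate=0.2, seed=seed)
                aucs[lam1] = roc_auc_score(
                    man.target_labels, res.predict_proba(Xt, Kt)[:, 1])
            diffs.append(aucs[0.1] - aucs[0.0])
        _, p_value = stats.ttest_1samp(diffs, 0.0)
        assert p_value > 0.05

    def test_unknown_scheme_rejected(self, rng):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        with pytest.raises(ConfigError):
            AKIRiskModel(Xs, Ks, ys, Xt, Kt).fit(scheme="wgan")


class TestPrediction:
    def test_rows_sum_to_one(self, rng):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        res = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4).fit(
            epochs=5, seed=0)
        probs = res.predict_proba(Xt, Kt)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_batch_equals_per_sample(self, rng):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        res = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4).fit(
            epochs=5, seed=0)
        batch = res.predict_proba(Xt, Kt)
        for i in range(len(Xt)):
            single = res.predict_proba(Xt[i:i + 1], Kt[i:i + 1])
            np.testing.assert_allclose(batch[i], single[0], atol=1e-12)

    def test_patient_sample_interface(self, rng):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        res = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4).fit(
            epochs=5, seed=0)
        sample = PatientSample(x_p=Xt[0], x_k=Kt[0], center="target")
        probs = res.predict_risk(sample)
        assert probs.shape == (2,)
        assert probs.sum() == pytest.approx(1.0)

    def test_target_samples_cannot_carry_labels(self):
        with pytest.raises(ValidationError):
            PatientSample(x_p=np.zeros(2), x_k=np.zeros(2),
                          center="target", y=1)

    def test_results_round_trip_through_json(self, rng, tmp_path):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        res = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4).fit(
            epochs=5, seed=0)
        path = tmp_path / "model.json"
        res.save(path)
        back = AKIRiskResults.load(path)
        np.testing.assert_array_equal(
            back.predict_proba(Xt, Kt), res.predict_proba(Xt, Kt))
        assert back.config["seed"] == 0

    def test_summary_mentions_key_quantities(self, rng):
        Xs, Ks, ys, Xt, Kt = _tiny_problem(rng)
        res = AKIRiskModel(Xs, Ks, ys, Xt, Kt, d_z=4, hidden=4).fit(
            epochs=5, seed=0)
        text = res.summary()
        assert "lambda1" in text and "classifier loss" in text
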