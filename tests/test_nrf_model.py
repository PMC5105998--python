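import numpy as np
import pytest

from nrfkit.nrf_model import (RHO1, RHO2, NRFHyper, NRFParams, activation_g,
                              forward, init_params, objective,
                              smooth_loss_and_grad, train)


def random_params(rng, J=3, F=4, H=3, scale=0.5):
    return NRFParams(w_in=scale * rng.standard_normal((J, F, H)),
                     b_hidden=scale * rng.standard_normal(J),
                     w_out=scale * rng.standard_normal(J),
                     b_out=scale * float(rng.standard_normal()))


class TestActivation:
    def test_fixed_constants_anchor_unity(self):
        assert round(RHO1, 4) == 1.7159
        assert RHO2 == 1.5
        assert activation_g(1.0) == pytest.approx(1.0, abs=1e-12)
        assert activation_g(-1.0) == pytest.approx(-1.0, abs=1e-12)

    def test_odd_with_saturating_asymptote(self):
        assert activation_g(0.0) == 0.0
        z = np.linspace(-3, 3, 11)
        assert np.allclose(activation_g(-z), -activation_g(z), atol=1e-15)
        assert activation_g(50.0) == pytest.approx(1.7159, abs=1e-4)


class TestForward:
    def test_zero_weights_constant_output(self, rng):
        p = NRFParams(w_in=np.zeros((3, 2, 2)), b_hidden=np.zeros(3),
                      w_out=np.zeros(3), b_out=0.8)
        X = rng.standard_normal((30, 2, 2))
        assert np.allclose(forward(p, X).y_hat, activation_g(0.8))

    def test_small_signal_taylor_slope(self, rng):
        # J=1, w_out=1, zero biases: yhat ~ (rho1/rho2)^2 * a for tiny a
        p = NRFParams(w_in=np.ones((1, 1, 1)), b_hidden=np.zeros(1),
                      w_out=np.ones(1), b_out=0.0)
        X = 1e-6 * rng.standard_normal((100, 1, 1))
        tr = forward(p, X)
        slope = (RHO1 / RHO2) ** 2
        assert np.allclose(tr.y_hat, slope * X[:, 0, 0], rtol=1e-6)

    def test_matches_nested_loop_oracle(self, rng):
        p = random_params(rng)
        X = rng.standard_normal((15, 4, 3))
        tr = forward(p, X)
        for t in range(15):
            a = [sum(p.w_in[j, f, h] * X[t, f, h]
                     for f in range(4) for h in range(3)) + p.b_hidden[j]
                 for j in range(3)]
            z = [RHO1 * np.tanh(v / RHO2) for v in a]
            a_o = sum(p.w_out[j] * z[j] for j in range(3)) + p.b_out
            assert tr.y_hat[t] == pytest.approx(
                RHO1 * np.tanh(a_o / RHO2), abs=1e-12)

    def test_outputs_bounded_by_rho1(self, rng):
        p = random_params(rng, scale=5.0)
        X = 10 * rng.standard_normal((200, 4, 3))
        tr = forward(p, X)
        assert np.all(np.abs(tr.z_hidden) <= RHO1)
        assert np.all(np.abs(tr.y_hat) <= RHO1)

    def test_sign_flip_symmetry(self, rng):
        p = random_params(rng)
        X = rng.standard_normal((50, 4, 3))
        flipped = NRFParams(w_in=p.w_in.copy(), b_hidden=p.b_hidden.copy(),
                            w_out=p.w_out.copy(), b_out=p.b_out)
        flipped.w_in[1] *= -1
        flipped.b_hidden[1] *= -1
        flipped.w_out[1] *= -1
        assert np.allclose(forward(p, X).y_hat, forward(flipped, X).y_hat,
                           atol=1e-12)


class TestObjective:
    def test_perfect_prediction_zero(self, rng):
        p = random_params(rng)
        X = rng.standard_normal((20, 4, 3))
        y = forward(p, X).y_hat
        assert objective(p, X, y, lam=0.0) == 0.0

    def test_penalty_increment_is_lambda_delta(self, rng):
        # with all output weights zero, perturbing a hidden weight cannot
        # change the prediction, so the objective rises by exactly lam*|d|
        X = rng.standard_normal((20, 4, 3))
        y = rng.standard_normal(20)
        p = NRFParams(w_in=np.zeros((3, 4, 3)), b_hidden=np.zeros(3),
                      w_out=np.zeros(3), b_out=0.1)
        base = objective(p, X, y, lam=2.0)
        p.w_in[1, 2, 0] = 0.37
        assert objective(p, X, y, lam=2.0) - base == pytest.approx(
            2.0 * 0.37, abs=1e-12)

    def test_two_bin_toy_hand_computed(self):
        p = NRFParams(w_in=np.array([[[1.0]]]), b_hidden=np.array([0.0]),
                      w_out=np.array([2.0]), b_out=0.0)
        X = np.array([[[0.5]], [[-0.5]]])
        y = np.array([0.0, 0.0])
        z = RHO1 * np.tanh(0.5 / RHO2)
        yh = RHO1 * np.tanh(2 * z / RHO2)
        expected = 0.5 * (yh ** 2 + yh ** 2) + 0.3 * (1.0 + 2.0)
        assert objective(p, X, y, lam=0.3) == pytest.approx(expected,
                                                            abs=1e-12)


class TestInit:
    def test_bounds_follow_fan_in(self):
        hyper = NRFHyper(J=20, seed=0)
        p = init_params(hyper, F=34, H=20)
        assert np.abs(p.w_in).max() <= 1 / 681
        assert np.abs(p.b_hidden).max() <= 1 / 681
        assert np.abs(p.w_out).max() <= 1 / 21
        assert abs(p.b_out) <= 1 / 21

    def test_same_seed_bitwise_identical(self):
        hyper = NRFHyper(J=5, seed=7)
        a = init_params(hyper, F=6, H=4)
        b = init_params(hyper, F=6, H=4)
        assert np.array_equal(a.w_in, b.w_in)
        assert np.array_equal(a.w_out, b.w_out)
        assert a.b_out == b.b_out


class TestGradient:
    def test_analytic_gradient_matches_central_differences(self, rng):
        p = random_params(rng, J=2, F=3, H=2)
        X = rng.standard_normal((25, 3, 2))
        y = rng.standard_normal(25)
        _, g = smooth_loss_and_grad(p, X, y)
        eps = 1e-6

        def loss_with(**delta):
            q = NRFParams(
                w_in=p.w_in + delta.get("w_in", 0),
                b_hidden=p.b_hidden + delta.get("b_hidden", 0),
                w_out=p.w_out + delta.get("w_out", 0),
                b_out=p.b_out + delta.get("b_out", 0))
            return smooth_loss_and_grad(q, X, y)[0]

        for j in range(2):
            for f in range(3):
                for h in range(2):
                    e = np.zeros((2, 3, 2))
                    e[j, f, h] = eps
                    fd = (loss_with(w_in=e) - loss_with(w_in=-e)) / (2 * eps)
                    assert g.w_in[j, f, h] == pytest.approx(fd, rel=1e-5,
                                                            abs=1e-8)
        e = np.zeros(2)
        e[1] = eps
        fd = (loss_with(w_out=e) - loss_with(w_out=-e)) / (2 * eps)
        assert g.w_out[1] == pytest.approx(fd, rel=1e-5)
        fd = (loss_with(b_out=eps) - loss_with(b_out=-eps)) / (2 * eps)
        assert g.b_out == pytest.approx(fd, rel=1e-5)


def toy_training_data(seed, T=400, F=5, H=4):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((T, F, H))
    gt = random_params(rng, J=2, F=F, H=H, scale=0.8)
    y = forward(gt, X).y_hat + 0.02 * rng.standard_normal(T)
    return X, y


class TestTrain:
    def test_huge_penalty_collapses_weights(self):
        X, y = toy_training_data(0)
        hyper = NRFHyper(J=4, lam=1e5, seed=0, max_iter=10)
        p = train(X, y, hyper)
        assert np.abs(p.w_in).max() < 1e-3
        assert np.abs(p.w_out).max() < 1e-3
        assert np.ptp(forward(p, X).y_hat) < 1e-2

    def test_objective_monotone_and_below_init(self):
        X, y = toy_training_data(1)
        hyper = NRFHyper(J=4, lam=0.5, seed=1, max_iter=10)
        hist = []
        p = train(X, y, hyper, history=hist)
        assert all(a >= b - 1e-9 for a, b in zip(hist, hist[1:]))
        assert objective(p, X, y, 0.5) <= hist[0]

    def test_deterministic_given_seed(self):
        X, y = toy_training_data(2)
        hyper = NRFHyper(J=3, lam=0.5, seed=3, max_iter=5)
        a = train(X, y, hyper)
        b = train(X, y, hyper)
        assert np.array_equal(a.w_in, b.w_in)
        assert a.b_out == b.b_out

    def test_effective_hu_count_non_increasing_in_lambda(self):
        from nrfkit.rf_analysis import effective_hus
        X, y = toy_training_data(4, T=600)
        counts = []
        for lam in (0.2, 2.0, 20.0, 200.0):
            p = train(X, y, NRFHyper(J=5, lam=lam, seed=0, max_iter=12))
            profs = effective_hus(p, X)
            nonzero = ~p.pruned_mask()
            counts.append(sum(q.effective and nonzero[q.index]
                              for q in profs))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
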