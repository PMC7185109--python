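import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from splitlbi.grid import VoxelMask
from splitlbi.lbi import (
    ModelHyperparams,
    ModelState,
    Standardizer,
    default_step_size,
    fit_path,
    full_loss,
    gradients,
    logistic_loss,
    predict_label,
    predict_proba,
    select_checkpoint,
    soft_threshold,
    sparse_projection,
    split_lbi_step,
)
from splitlbi.operator import DifferenceOperator, build_difference_operator

from conftest import random_logistic_instance


def identity_operator(P):
    from scipy import sparse

    return DifferenceOperator(
        sparse.identity(P, format="csr"), P, 0, 0.0, np.empty((0, 2), dtype=np.int64)
    )


def line_mask(P):
    """P voxels in a straight line (P-1 edges)."""
    inside = np.zeros((P, 3, 3), dtype=bool)
    inside[:, 1, 1] = True
    return VoxelMask(inside)


def zero_state(P, m):
    return ModelState(np.zeros(P), 0.0, np.zeros(m), np.zeros(m))


class TestLosses:
    def test_zero_coefficients_give_n_log2(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((13, 4))
        y = (rng.random(13) < 0.5).astype(int)
        assert logistic_loss(np.zeros(4), 0.0, X, y) == pytest.approx(13 * np.log(2))

    def test_separated_data_loss_vanishes_monotonically(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        losses = [logistic_loss(np.array([c]), 0.0, X, y) for c in (1, 10, 100, 700)]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-200

    def test_matches_extended_precision_oracle(self):
        rng = np.random.default_rng(1)
        X, y = random_logistic_instance(rng, 17, 5)
        beta = rng.standard_normal(5)
        b0 = 0.3
        eta = np.asarray(X @ beta + b0, dtype=np.longdouble)
        p = 1.0 / (1.0 + np.exp(-eta))
        oracle = -float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        assert logistic_loss(beta, b0, X, y) == pytest.approx(oracle, rel=1e-12)

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            logistic_loss(np.zeros(2), 0.0, np.zeros((3, 2)), np.array([0, 1, 2]))

    def test_full_loss_penalty_vanishes_when_gamma_matches(self):
        rng = np.random.default_rng(2)
        X, y = random_logistic_instance(rng, 12, 6)
        D = build_difference_operator(line_mask(6), rho=1.0)
        beta = rng.standard_normal(6)
        state = ModelState(beta, 0.1, np.asarray(D.matrix @ beta), np.zeros(D.n_rows))
        assert full_loss(state, X, y, D, nu=0.7) == pytest.approx(
            logistic_loss(beta, 0.1, X, y)
        )

    def test_full_loss_at_origin(self):
        rng = np.random.default_rng(3)
        X, y = random_logistic_instance(rng, 9, 4)
        D = identity_operator(4)
        state = zero_state(4, 4)
        assert full_loss(state, X, y, D, nu=1.0) == pytest.approx(9 * np.log(2))

    def test_nonpositive_nu_rejected(self):
        rng = np.random.default_rng(4)
        X, y = random_logistic_instance(rng, 8, 3)
        with pytest.raises(ValueError):
            full_loss(zero_state(3, 3), X, y, identity_operator(3), nu=0.0)


def finite_difference_grads(state, X, y, D, nu, h=1e-6):
    P, m = len(state.beta), len(state.gamma)
    gb = np.zeros(P)
    for j in range(P):
        for sgn, acc in ((1, 1.0), (-1, -1.0)):
            s = state.copy()
            s.beta = s.beta.copy()
            s.beta[j] += sgn * h
            gb[j] += acc * full_loss(s, X, y, D, nu)
        gb[j] /= 2 * h
    gg = np.zeros(m)
    for j in range(m):
        for sgn, acc in ((1, 1.0), (-1, -1.0)):
            s = state.copy()
            s.gamma = s.gamma.copy()
            s.gamma[j] += sgn * h
            gg[j] += acc * full_loss(s, X, y, D, nu)
        gg[j] /= 2 * h
    up = state.copy()
    up.intercept += h
    dn = state.copy()
    dn.intercept -= h
    gi = (full_loss(up, X, y, D, nu) - full_loss(dn, X, y, D, nu)) / (2 * h)
    return gb, gi, gg


class TestGradients:
    def test_closed_forms_at_origin(self):
        rng = np.random.default_rng(5)
        X, y = random_logistic_instance(rng, 10, 4)
        D = identity_operator(4)
        gb, gi, gg = gradients(zero_state(4, 4), X, y, D, nu=1.0)
        assert gb == pytest.approx(X.T @ (0.5 - y))
        assert gi == pytest.approx(np.sum(0.5 - y))
        assert gg == pytest.approx(np.zeros(4))

    def test_gamma_gradient_zero_when_split_is_tight(self):
        rng = np.random.default_rng(6)
        X, y = random_logistic_instance(rng, 10, 5)
        D = build_difference_operator(line_mask(5), rho=1.0)
        beta = rng.standard_normal(5)
        state = ModelState(beta, 0.0, np.asarray(D.matrix @ beta), np.zeros(D.n_rows))
        _, _, gg = gradients(state, X, y, D, nu=2.0)
        assert np.allclose(gg, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_logistic_instance(rng, 14, 5)
        D = build_difference_operator(line_mask(5), rho=0.8)
        state = ModelState(
            rng.standard_normal(5) * 0.5,
            0.2,
            rng.standard_normal(D.n_rows) * 0.3,
            rng.standard_normal(D.n_rows),
        )
        gb, gi, gg = gradients(state, X, y, D, nu=1.3)
        fb, fi, fg = finite_difference_grads(state, X, y, D, 1.3)
        assert gb == pytest.approx(fb, rel=1e-6, abs=1e-8)
        assert gi == pytest.approx(fi, rel=1e-6, abs=1e-8)
        assert gg == pytest.approx(fg, rel=1e-6, abs=1e-8)


class TestSoftThreshold:
    def test_scalar_cases(self):
        assert soft_threshold(np.array([0.5]))[0] == 0.0
        assert soft_threshold(np.array([2.0]))[0] == 1.0
        assert soft_threshold(np.array([-3.0]))[0] == -2.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=20))
    def test_matches_elementwise_oracle(self, vals):
        z = np.array(vals)
        out = soft_threshold(z, 1.0)
        for zi, oi in zip(z, out):
            expected = np.sign(zi) * max(abs(zi) - 1.0, 0.0)
            assert oi == expected


class TestStepSize:
    def test_doubling_kappa_halves_alpha(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 6))
        D = identity_operator(6)
        a1 = default_step_size(1.0, 1.0, X, D)
        a2 = default_step_size(2.0, 1.0, X, D)
        assert a2 == pytest.approx(a1 / 2)

    def test_identity_closed_form(self):
        X = np.eye(7)
        D = identity_operator(7)
        assert default_step_size(3.0, 1.0, X, D) == pytest.approx(
            0.9 / (3.0 * (0.25 + 1.0)), rel=1e-6
        )

    def test_spectral_terms_match_dense_eigensolver(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((12, 9))
        D = build_difference_operator(line_mask(9), rho=1.0)
        kappa, nu = 2.0, 0.5
        lx = np.linalg.eigvalsh(X.T @ X).max()
        ld = np.linalg.eigvalsh((D.matrix.T @ D.matrix).toarray()).max()
        expected = 0.9 / (kappa * (lx / 4 + ld / nu))
        assert default_step_size(kappa, nu, X, D) == pytest.approx(expected, rel=1e-6)

    def test_zero_design_rejected(self):
        with pytest.raises(ValueError):
            default_step_size(1.0, 1.0, np.zeros((4, 3)), identity_operator(3))


class TestStepMechanics:
    def test_z_stays_zero_until_beta_moves_on_identity_block(self):
        # centered balanced labels: grad_gamma = 0 at the origin
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1, 0, 0, 1])
        D = identity_operator(1)
        h = ModelHyperparams(alpha=0.01)
        s1 = split_lbi_step(zero_state(1, 1), X, y, D, h)
        assert s1.z[0] == 0.0

    def test_support_entry_requires_z_above_one(self):
        X = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        y = np.array([1, 1, 0, 0])
        D = identity_operator(1)
        h = ModelHyperparams(alpha=0.05, kappa=2.0)
        s = zero_state(1, 1)
        entered = False
        for _ in range(400):
            s = split_lbi_step(s, X, y, D, h)
            if s.gamma[0] != 0:
                entered = True
                assert abs(s.z[0]) > 1.0
                break
            assert abs(s.z[0]) <= 1.0
        assert entered

    def test_one_step_matches_hand_unrolled_computation(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((8, 2))
        y = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        D = build_difference_operator(line_mask(2), rho=1.0)  # rows: I2, (1,-1)
        nu, kappa, alpha = 1.5, 2.0, 0.01
        h = ModelHyperparams(nu=nu, kappa=kappa, alpha=alpha)
        state = ModelState(
            np.array([0.3, -0.2]), 0.1, np.zeros(3), np.array([0.4, -0.1, 1.2])
        )
        out = split_lbi_step(state, X, y, D, h)

        # independent unroll
        eta = X @ state.beta + state.intercept
        r = expit(eta) - y
        Dmat = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, -1.0]])
        dres = Dmat @ state.beta - state.gamma
        gb = X.T @ r + Dmat.T @ dres / nu
        z_new = state.z + (alpha / nu) * dres
        gamma_new = kappa * np.sign(z_new) * np.maximum(np.abs(z_new) - 1, 0)
        assert out.beta == pytest.approx(state.beta - kappa * alpha * gb)
        assert out.intercept == pytest.approx(state.intercept - kappa * alpha * r.sum())
        assert out.z == pytest.approx(z_new)
        assert out.gamma == pytest.approx(gamma_new)
        assert out.t == pytest.approx(kappa * alpha)


def strong_signal_instance(seed, n=40, p=20, strength=2.0):
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)])
    X = rng.standard_normal((n, p))
    X[:, :4] += strength * (2 * y[:, None] - 1)  # four informative features
    return Standardizer.fit(X).transform(X), y


class TestFitPath:
    def test_kernel_and_numpy_paths_agree(self):
        X, y = strong_signal_instance(0)
        D = build_difference_operator(line_mask(20), rho=1.0)
        h = ModelHyperparams(t_max=5.0, max_steps=4000)
        p1 = fit_path(X, y, D, h, use_kernel=True)
        p2 = fit_path(X, y, D, h, use_kernel=False)
        assert len(p1) == len(p2)
        assert p1.checkpoints[-1].beta == pytest.approx(p2.checkpoints[-1].beta, abs=1e-12)
        assert p1.checkpoints[-1].z == pytest.approx(p2.checkpoints[-1].z, abs=1e-12)

    def test_null_data_has_empty_early_support(self):
        rng = np.random.default_rng(10)
        X = Standardizer.fit(rng.standard_normal((40, 20))).transform(
            rng.standard_normal((40, 20))
        )
        y = np.concatenate([np.ones(20, dtype=int), np.zeros(20, dtype=int)])
        D = build_difference_operator(line_mask(20), rho=1.0)
        path = fit_path(X, y, D, ModelHyperparams(t_max=0.5), use_kernel=True)
        assert path.support_size[0] == 0

    def test_strong_feature_enters_first(self):
        rng = np.random.default_rng(11)
        y = np.concatenate([np.ones(20, dtype=int), np.zeros(20, dtype=int)])
        X = rng.standard_normal((40, 10))
        X[:, 3] += 3.0 * (2 * y - 1)
        X = Standardizer.fit(X).transform(X)
        D = build_difference_operator(line_mask(10), rho=1.0)
        path = fit_path(X, y, D, ModelHyperparams(t_max=60.0))
        order = path.entry_order()
        assert order, "no feature ever entered the support"
        assert order[0] == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_supports_nearly_nested_on_strong_signal(self, seed):
        X, y = strong_signal_instance(seed)
        D = build_difference_operator(line_mask(20), rho=1.0)
        path = fit_path(X, y, D, ModelHyperparams(t_max=40.0))
        P = 20
        supports = [set(np.flatnonzero(s.gamma[:P])) for s in path.checkpoints]
        nested = sum(
            1 for a, b in zip(supports, supports[1:]) if a.issubset(b)
        )
        assert nested >= 0.95 * (len(supports) - 1)

    def test_support_matches_z_threshold_at_every_checkpoint(self):
        X, y = strong_signal_instance(1)
        D = build_difference_operator(line_mask(20), rho=1.0)
        path = fit_path(X, y, D, ModelHyperparams(t_max=40.0))
        for s in path.checkpoints:
            assert set(np.flatnonzero(s.gamma)) == set(np.flatnonzero(np.abs(s.z) > 1))
            # gamma = kappa * soft-threshold(z) exactly
            assert s.gamma == pytest.approx(10.0 * soft_threshold(s.z, 1.0))

    def test_loss_nonincreasing_over_50_step_windows(self):
        for seed in (0, 1, 2):
            X, y = strong_signal_instance(seed)
            D = build_difference_operator(line_mask(20), rho=1.0)
            path = fit_path(X, y, D, ModelHyperparams(t_max=40.0))
            losses = np.array(path.train_loss)
            stride = path.hyper.checkpoint_stride
            lag = max(1, int(np.ceil(50 / stride)))
            assert (losses[lag:] <= losses[:-lag] + 1e-9).all()

    def test_divergent_step_size_raises_diagnostic(self):
        X, y = strong_signal_instance(2)
        D = build_difference_operator(line_mask(20), rho=1.0)
        h = ModelHyperparams(alpha=5.0, t_max=1e9, max_steps=2000)
        with pytest.raises(FloatingPointError):
            fit_path(X, y, D, h)

    def test_needs_stopping_information(self):
        X, y = strong_signal_instance(3)
        D = build_difference_operator(line_mask(20), rho=1.0)
        with pytest.raises(ValueError):
            fit_path(X, y, D, ModelHyperparams())  # no t_max, no validation data


class TestSparseProjection:
    def test_full_support_returns_dense_beta(self):
        D = identity_operator(4)
        state = ModelState(np.array([1.0, -2.0, 3.0, 0.5]), 0.0,
                           np.ones(4), np.full(4, 2.0))
        est = sparse_projection(state, D)
        assert est.beta_tilde == pytest.approx(state.beta)

    def test_empty_support_returns_zero(self):
        D = identity_operator(4)
        state = zero_state(4, 4)
        state.beta = np.array([1.0, 2.0, 3.0, 4.0])
        est = sparse_projection(state, D)
        assert np.all(est.beta_tilde == 0)
        assert est.support.size == 0

    def test_mixed_support(self):
        D = identity_operator(3)
        state = ModelState(np.array([1.0, 2.0, 3.0]), 0.0,
                           np.array([0.0, 5.0, 0.0]), np.zeros(3))
        est = sparse_projection(state, D)
        assert est.beta_tilde == pytest.approx([0.0, 2.0, 0.0])
        assert list(est.support) == [1]


class TestSelection:
    def _path_with_devs(self, devs):
        from splitlbi.lbi import LBIPath

        path = LBIPath()
        # one-feature states whose validation deviance is controlled by beta
        for i, _ in enumerate(devs):
            path.checkpoints.append(
                ModelState(np.array([float(i)]), 0.0, np.zeros(1), np.zeros(1),
                           k=i + 1, t=float(i + 1))
            )
        return path

    def test_single_checkpoint_path(self):
        path = self._path_with_devs([1.0])
        X_val = np.array([[1.0]])
        y_val = np.array([1])
        assert select_checkpoint(path, X_val, y_val).t == 1.0

    def test_minimizing_checkpoint_returned(self):
        path = self._path_with_devs([0, 1, 2])
        # y=1: larger beta -> smaller deviance -> last checkpoint wins
        assert select_checkpoint(path, np.array([[1.0]]), np.array([1])).t == 3.0
        # y=0: beta=0 wins
        assert select_checkpoint(path, np.array([[1.0]]), np.array([0])).t == 1.0

    def test_ties_resolve_to_earliest_t(self):
        path = self._path_with_devs([0, 1, 2])
        # X=0 makes every checkpoint equally good
        assert select_checkpoint(path, np.array([[0.0]]), np.array([1])).t == 1.0

    def test_empty_validation_rejected(self):
        path = self._path_with_devs([0])
        with pytest.raises(ValueError):
            select_checkpoint(path, np.empty((0, 1)), np.empty(0))


class TestPrediction:
    def test_zero_model_gives_half_and_label_zero(self):
        state = zero_state(3, 3)
        X = np.random.default_rng(0).standard_normal((5, 3))
        assert predict_proba(state, X) == pytest.approx(np.full(5, 0.5))
        assert np.all(predict_label(state, X) == 0)  # tie -> NC

    def test_large_intercept_labels_all_positive(self):
        state = ModelState(np.zeros(2), 50.0, np.zeros(2), np.zeros(2))
        assert np.all(predict_label(state, np.zeros((4, 2))) == 1)

    def test_matches_sigmoid_oracle(self):
        rng = np.random.default_rng(12)
        beta = rng.standard_normal(6)
        X = rng.standard_normal((20, 6))
        state = ModelState(beta, -0.4, np.zeros(6), np.zeros(6))
        assert predict_proba(state, X) == pytest.approx(expit(X @ beta - 0.4))


class TestStandardizer:
    def test_zero_variance_columns_map_to_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        std = Standardizer.fit(X)
        Xs = std.transform(X)
        assert np.all(Xs[:, 0] == 0.0)
        assert Xs[:, 1] == pytest.approx((X[:, 1] - 3.0) / X[:, 1].std())
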