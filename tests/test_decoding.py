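import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ventrilab.decoding import (WindowGrid, auc_from_dvals, binarize_label,
                                crossval_auc, decision_values, forward_model,
                                pattern_similarity, train_rlda,
                                train_rlda_windows, window_features)
from ventrilab.epochs import EpochArray, epoch_times

from conftest import av_epochs_and_dva


class TestWindowGrid:
    def test_window_arithmetic_matches_brute_force(self):
        times = epoch_times(-0.8, 0.65, 150.0)
        grid = WindowGrid.from_times(times, 150.0)
        assert grid.win_samples == 6 and grid.step_samples == 1
        # brute force: enumerate every start whose 6 samples all lie in range
        eps = 0.5 / 150
        starts = [i for i in range(len(times) - 5)
                  if times[i] >= -0.4 - eps and times[i + 5] <= 0.5 + eps]
        assert list(grid.starts) == starts
        n_in_range = np.sum((times >= -0.4 - eps) & (times <= 0.5 + eps))
        assert grid.n_windows == n_in_range - 6 + 1
        assert np.all(np.diff(grid.centers) > 0)

    def test_windows_inside_analysis_range(self):
        times = epoch_times(-0.8, 0.65, 150.0)
        grid = WindowGrid.from_times(times, 150.0)
        assert times[grid.starts[0]] >= -0.4 - 1e-9
        assert times[grid.starts[-1] + grid.win_samples - 1] <= 0.5 + 1e-9


class TestBinarize:
    def test_left_right_and_zero_exclusion(self):
        labels, mask = binarize_label([-23.2, 11.6, 0.0, -11.6, 34.8])
        assert list(mask) == [True, True, False, True, True]
        assert list(labels) == [False, True, False, True]

    def test_design_classes_balanced(self):
        from ventrilab.design import generate_design
        df = generate_design("ST", 1)
        labels, mask = binarize_label(df[df.trial_type == "AV"].delta_va)
        assert mask.all()
        assert labels.sum() == (~labels).sum() == 180

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one side"):
            binarize_label([1.0, 2.0, 3.0])


class TestRlda:
    def test_full_shrinkage_weights_parallel_to_mean_difference(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        y = np.arange(40) % 2 == 0
        X[y] += [1, 2, 0, -1, 0.5]
        w, _ = train_rlda(X, y, lam=1.0)
        diff = X[y].mean(0) - X[~y].mean(0)
        cos = w @ diff / np.linalg.norm(w) / np.linalg.norm(diff)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_separated_classes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4)) * 0.1
        y = np.arange(200) % 2 == 0
        X[y] += [3, 0, 0, 0]
        w, b = train_rlda(X, y, lam=0.1)
        cos = w[0] / np.linalg.norm(w)
        assert cos > 0.99
        dv = X @ w + b
        assert ((dv > 0) == y).mean() == 1.0

    def test_brute_force_linear_algebra_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = np.arange(20) % 2 == 0
        X[y] += 0.5
        lam = 0.1
        w, b = train_rlda(X, y, lam)
        # independent direct computation
        mu_l, mu_r = X[~y].mean(0), X[y].mean(0)
        Xc = np.concatenate([X[~y] - mu_l, X[y] - mu_r])
        S = Xc.T @ Xc / (len(X) - 2)
        Sreg = (1 - lam) * S + lam * np.trace(S) / 3 * np.eye(3)
        w_ref = np.linalg.inv(Sreg) @ (mu_r - mu_l)
        b_ref = -0.5 * w_ref @ (mu_r + mu_l)
        assert np.allclose(w, w_ref, atol=1e-10)
        assert b == pytest.approx(b_ref, abs=1e-10)
        dv = X @ w + b
        assert np.allclose(dv, X @ w_ref + b_ref, atol=1e-10)

    def test_batched_windows_match_single_window(self):
        rng = np.random.default_rng(3)
        Xw = rng.normal(size=(30, 4, 7))
        y = np.arange(30) % 2 == 0
        W, B = train_rlda_windows(Xw, y, lam=0.1)
        for j in (0, 3, 6):
            w, b = train_rlda(Xw[:, :, j], y, lam=0.1)
            assert np.allclose(W[j], w) and B[j] == pytest.approx(b)

    def test_too_few_trials_per_class(self):
        with pytest.raises(ValueError, match="per class"):
            train_rlda(np.zeros((3, 2)), np.array([True, False, False]))


class TestAuc:
    def test_rank_auc_matches_pairwise_oracle_and_sklearn(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 25).astype(bool)
        y[:2] = [True, False]
        dv = rng.normal(size=(25, 3))
        dv[:, 1] = np.round(dv[:, 1], 1)  # force ties
        auc = auc_from_dvals(y, dv)
        for j in range(3):
            # O(n^2) pairwise comparison
            pairs = [(0.5 if dv[i, j] == dv[k, j] else float(dv[i, j] > dv[k, j]))
                     for i in np.flatnonzero(y) for k in np.flatnonzero(~y)]
            assert auc[j] == pytest.approx(np.mean(pairs), abs=1e-12)
            assert auc[j] == pytest.approx(roc_auc_score(y, dv[:, j]), abs=1e-12)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 40).astype(bool)
        dv = rng.normal(size=(40, 2))
        assert np.allclose(auc_from_dvals(y, dv),
                           auc_from_dvals(y, np.exp(3 * dv) + 7))


class TestCrossval:
    def test_high_snr_signal_and_null_outside_envelope(self, strong_subject):
        sd, params = strong_subject
        ep, dva = av_epochs_and_dva(sd)
        res = crossval_auc(ep, dva, seed=0)
        c, width = params.pattern_latency["dva"]
        inside = np.abs(res.grid.centers - c) <= width
        outside = res.grid.centers < c - 6 * width
        assert res.auc[inside].min() > 0.95
        assert abs(res.auc[outside].mean() - 0.5) < 0.05
        assert np.all((res.auc >= 0) & (res.auc <= 1))

    def test_invariance_to_channel_order_and_global_scale(self, strong_subject):
        sd, _ = strong_subject
        ep, dva = av_epochs_and_dva(sd)
        res = crossval_auc(ep, dva, seed=3)
        perm = np.random.default_rng(0).permutation(ep.n_channels)
        ep2 = EpochArray(5.0 * ep.data[:, perm], ep.times, ep.fs,
                         trial_index=ep.trial_index)
        res2 = crossval_auc(ep2, dva, seed=3)
        assert np.allclose(res.auc, res2.auc, atol=1e-9)
        # decision values are invariant: weights scale as 1/alpha under x -> alpha x
        assert np.allclose(res.dvals, res2.dvals, rtol=1e-6)
        assert np.allclose(res.weights[:, perm] / 5.0, res2.weights, rtol=1e-6)

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(6)
        times = epoch_times(-0.1, 0.29, 150.0)
        data = rng.normal(size=(80, 6, times.size))
        ep = EpochArray(data, times, 150.0)
        grid = WindowGrid.from_times(times, 150.0, tmin=-0.05, tmax=0.25)
        values = rng.choice([-1.0, 1.0], 80)
        res = crossval_auc(ep, values, grid=grid, seed=1)
        assert abs(res.auc.mean() - 0.5) < 0.05


class TestForwardModel:
    def test_recovers_generating_pattern(self, strong_subject):
        sd, params = strong_subject
        ep, dva = av_epochs_and_dva(sd)
        res = crossval_auc(ep, dva, seed=0)
        c, _ = params.pattern_latency["dva"]
        j = np.argmin(np.abs(res.grid.centers - c))
        truth = sd.truth["patterns"]["dva"]
        r = np.corrcoef(res.fwd[j], truth)[0, 1]
        assert abs(r) > 0.95

    def test_constant_decision_values_degenerate(self, caplog):
        rng = np.random.default_rng(7)
        Xw = rng.normal(size=(20, 3, 2))
        dv = np.ones((20, 2))
        with caplog.at_level("WARNING"):
            fwd = forward_model(dv, Xw)
        assert np.allclose(fwd, 0.0)
        assert "degenerate" in caplog.text

    def test_orthogonal_distractor_near_zero(self):
        rng = np.random.default_rng(8)
        n = 400
        g = rng.choice([-1.0, 1.0], n)
        distract = rng.choice([-1.0, 1.0], n)  # independent of g
        pattern = np.array([1.0, 0, 0, 0])
        distractor = np.array([0, 0, 0, 1.0])
        X = (np.outer(g, pattern) + np.outer(distract, distractor)
             + 0.1 * rng.normal(size=(n, 4)))
        fwd = forward_model(g[:, None], X[:, :, None])
        assert abs(fwd[0, 0]) == pytest.approx(1.0)
        assert abs(fwd[0, 3]) < 0.2


class TestPatternSimilarity:
    def test_identity_and_sign_flip(self):
        rng = np.random.default_rng(9)
        p = rng.normal(size=(6, 12))
        res = pattern_similarity(p, p, n_boot=50, seed=0)
        assert res["r"] == pytest.approx(1.0)
        res2 = pattern_similarity(p, -p, n_boot=50, seed=0)
        assert res2["r"] == pytest.approx(-1.0)

    def test_independent_patterns_ci_covers_zero(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(10, 30))
        b = rng.normal(size=(10, 30))
        res = pattern_similarity(a, b, n_boot=500, seed=1)
        assert res["ci"][0] < 0 < res["ci"][1]
        assert not res["significant"]

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            pattern_similarity(np.zeros((3, 4)), np.zeros((3, 5)))
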