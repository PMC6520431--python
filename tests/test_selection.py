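"""OFR ranking, the greedy-regression oracle, and random-probe retention."""

import numpy as np
import pytest

from attnbci.selection import SelectionConfig, encode_target, probe_select, rank_ofr


def greedy_residual_oracle(X, y, kmax):
    """Exhaustive greedy: at each step pick the feature maximizing R^2 of the
    regression on all features chosen so far plus the candidate, recomputed
    from scratch by least squares."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    chosen = []
    for _ in range(kmax):
        best, best_r2 = None, -np.inf
        for j in range(X.shape[1]):
            if j in chosen:
                continue
            cols = Xc[:, chosen + [j]]
            beta, *_ = np.linalg.lstsq(cols, yc, rcond=None)
            resid = yc - cols @ beta
            r2 = 1.0 - (resid @ resid) / (yc @ yc)
            if r2 > best_r2 + 1e-12:
                best, best_r2 = j, r2
        chosen.append(best)
    return chosen


class TestEncodeTarget:
    def test_pairwise_gives_signed_vector(self):
        Y = encode_target(np.array(["easy", "hard", "easy", "hard"]))
        assert Y.shape == (4, 1)
        assert set(Y.ravel()) == {-1.0, 1.0}

    def test_three_class_helmert_contrasts_orthogonal_zero_mean(self):
        labels = np.array(["easy", "medium", "hard"] * 10)
        Y = encode_target(labels)
        assert Y.shape == (30, 2)
        assert Y[:, 0] @ Y[:, 1] == pytest.approx(0.0)
        np.testing.assert_allclose(Y.mean(axis=0), 0.0, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            encode_target(np.array(["easy", "easy"]))

    def test_three_class_graded_feature_is_highly_relevant(self):
        """A feature tracking class means (-1, 0, 1) outranks pure noise."""
        rng = np.random.default_rng(0)
        labels = np.array(["easy", "medium", "hard"] * 60)
        means = {"easy": -1.0, "medium": 0.0, "hard": 1.0}
        signal = np.array([means[l] for l in labels]) + 0.05 * rng.standard_normal(180)
        X = np.column_stack([rng.standard_normal((180, 10)), signal])
        r = rank_ofr(X, encode_target(labels))
        assert r.order[0] == 10
        assert r.relevance[0] > 0.9


class TestRankOfr:
    def test_exact_column_ranked_first_with_unit_relevance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 6))
        r = rank_ofr(X, X[:, 3].copy())
        assert r.order[0] == 3
        assert r.relevance[0] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_candidates_order_matches_correlation(self):
        rng = np.random.default_rng(2)
        # orthonormal columns that are also zero-mean: orthogonalize against
        # the constant vector first, so centering inside OFR changes nothing
        raw = np.column_stack([np.ones(80), rng.standard_normal((80, 8))])
        Q = np.linalg.qr(raw)[0][:, 1:]
        y = rng.standard_normal(80)
        r = rank_ofr(Q, y)
        yc = y - y.mean()
        expected = list(np.argsort(-np.abs(Q.T @ yc)))
        assert r.order == expected[: len(r.order)]

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_greedy_oracle_small_instances(self, trial):
        rng = np.random.default_rng(400 + trial)
        p = int(rng.integers(3, 9))
        X = rng.standard_normal((30, p))
        y = rng.standard_normal(30)
        r = rank_ofr(X, y)
        assert r.order == greedy_residual_oracle(X, y, len(r.order))

    def test_relevances_lie_in_unit_interval(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 12))
        y = rng.standard_normal(50)
        r = rank_ofr(X, y)
        assert all(0.0 <= v <= 1.0 for v in r.relevance)

    def test_column_permutation_permutes_ranking(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 7))
        y = X[:, 2] + 0.5 * rng.standard_normal(40)
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        r1 = rank_ofr(X, y)
        r2 = rank_ofr(X[:, perm], y)
        assert [int(perm[j]) for j in r2.order] == r1.order

    def test_zero_variance_columns_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 4))
        X[:, 1] = 2.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            r = rank_ofr(X, rng.standard_normal(30))
        assert 1 not in r.order


class TestProbeSelect:
    def test_perfect_feature_always_kept(self):
        kept = 0
        for s in range(25):
            rng = np.random.default_rng(3000 + s)
            X = rng.standard_normal((200, 51))
            y = X[:, 0] + 0.01 * rng.standard_normal(200)
            res = probe_select(X, y, SelectionConfig(seed=s))
            kept += bool(res.kept[0])
        assert kept == 25

    def test_kept_features_form_prefix_of_ranking(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((150, 30))
        y = X[:, :3] @ np.array([1.0, 0.8, 0.6]) + rng.standard_normal(150)
        res = probe_select(X, y, SelectionConfig(seed=11))
        assert res.kept_order == res.order[: res.n_kept]
        assert res.n_kept <= SelectionConfig().max_features
        assert sorted(np.flatnonzero(res.kept)) == sorted(res.kept_order)

    def test_null_false_selection_rate_near_nominal(self):
        """All-noise candidates: mean kept fraction stays near the 5% design point."""
        fracs = []
        for s in range(60):
            rng = np.random.default_rng(5000 + s)
            X = rng.standard_normal((200, 50))
            y = rng.standard_normal(200)
            res = probe_select(X, y, SelectionConfig(seed=s))
            fracs.append(res.n_kept / 50)
        assert np.mean(fracs) <= 0.07

    def test_default_quantile_is_95_percent(self):
        assert SelectionConfig().probe_quantile == 0.95

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SelectionConfig(probe_quantile=1.5)
        with pytest.raises(ValueError):
            SelectionConfig(n_probes=5)
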