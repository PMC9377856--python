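"""Selectors: the normalized information-gain score against a direct
entropy oracle, planted-feature recovery, and the mask/projection
contracts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegfuse as ef
from eegfuse.features import FeatureMatrix, Provenance
from eegfuse.selection import save_selection_model, load_selection_model


def _matrix(values: np.ndarray) -> FeatureMatrix:
    prov = tuple(Provenance("AR", "C3", i) for i in range(values.shape[1]))
    return FeatureMatrix(values=values, provenance=prov)


def _entropy_oracle(table: np.ndarray) -> float:
    """Direct evaluation of 2*I/(H_split + H_class) from a 2x2 count table."""
    total = table.sum()
    ps = table.sum(axis=1) / total
    pc = table.sum(axis=0) / total
    pj = table.ravel() / total
    h = lambda p: -sum(x * np.log2(x) for x in p if x > 0)
    hs, hc, hj = h(ps), h(pc), h(pj)
    mutual = hs + hc - hj
    return 0.0 if hs + hc == 0 else 2 * mutual / (hs + hc)


def _planted(rng, n=200, n_noise=23, flip=0.0):
    """Label column (optionally noisy) followed by pure-noise columns."""
    y = rng.integers(0, 2, n)
    signal_col = y.astype(float).copy()
    if flip:
        mask = rng.random(n) < flip
        signal_col[mask] = 1 - signal_col[mask]
    X = np.column_stack([signal_col, rng.standard_normal((n, n_noise))])
    labels = np.where(y == 1, "right", "left")
    return _matrix(X), labels


class TestSplitScore:
    def test_perfect_balanced_split_scores_one(self):
        counts = ef.SplitCounts(left={"A": 20, "B": 0}, right={"A": 0, "B": 20})
        assert ef.split_score(counts) == pytest.approx(1.0, abs=1e-12)

    def test_independent_split_scores_zero(self):
        counts = ef.SplitCounts(left={"A": 10, "B": 10}, right={"A": 10, "B": 10})
        assert ef.split_score(counts) == pytest.approx(0.0, abs=1e-12)

    def test_matches_entropy_oracle_on_random_tables(self, rng):
        for _ in range(1000):
            table = rng.integers(0, 50, size=(2, 2)).astype(float)
            if table.sum() < 2 or table.sum(axis=0).max() == 0:
                continue
            counts = ef.SplitCounts(
                left={"A": table[0, 0], "B": table[0, 1]},
                right={"A": table[1, 0], "B": table[1, 1]},
            )
            assert ef.split_score(counts) == pytest.approx(
                max(0.0, _entropy_oracle(table)), abs=1e-10
            )

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            ef.split_score(ef.SplitCounts(left={}, right={}))

    @given(
        a=st.integers(0, 40), b=st.integers(0, 40),
        c=st.integers(0, 40), d=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_bounded_in_unit_interval(self, a, b, c, d):
        if a + b + c + d < 2 or (a + b + c + d) == 0:
            return
        counts = ef.SplitCounts(left={"A": a, "B": b}, right={"A": c, "B": d})
        s = ef.split_score(counts)
        assert 0.0 <= s <= 1.0 + 1e-12


class TestExtraTrees:
    def test_defaults_match_stage_constants(self):
        cfg = ef.ETConfig()
        assert cfg.n_trees == 10 and cfg.min_split == 2
        assert cfg.features_per_node is None  # m = M

    def test_label_column_ranks_first(self, rng):
        X, y = _planted(rng, n=200)
        model = ef.et_fit(X, y, ef.ETConfig(seed=5))
        assert int(np.argmax(model.scores)) == 0
        assert 0 in model.mask

    def test_importances_normalized(self, rng):
        X, y = _planted(rng, n=150)
        model = ef.et_fit(X, y, ef.ETConfig(seed=1))
        assert np.all(model.scores >= 0)
        assert model.scores.sum() == pytest.approx(1.0, abs=1e-12)

    def test_k_keep_mask_size(self, rng):
        X, y = _planted(rng, n=100)
        model = ef.et_fit(X, y, ef.ETConfig(k_keep=20, seed=2))
        assert model.mask.size == 20
        assert np.array_equal(model.mask, np.unique(model.mask))

    def test_builds_requested_number_of_trees(self, rng):
        X, y = _planted(rng, n=80)
        model = ef.et_fit(X, y, ef.ETConfig(n_trees=10, seed=0))
        assert len(model.extra["trees"]) == 10
        assert model.extra["min_split"] == 2
        assert model.extra["features_per_node"] == X.n_features  # m = M

    def test_determinism(self, rng):
        X, y = _planted(rng, n=120)
        m1 = ef.et_fit(X, y, ef.ETConfig(seed=9))
        m2 = ef.et_fit(X, y, ef.ETConfig(seed=9))
        assert np.array_equal(m1.mask, m2.mask)
        assert np.array_equal(m1.scores, m2.scores)

    def test_constant_column_gets_zero_importance(self, rng):
        X, y = _planted(rng, n=100, n_noise=10)
        vals = X.values.copy()
        vals[:, 5] = 7.0
        model = ef.et_fit(_matrix(vals), y, ef.ETConfig(seed=3))
        assert model.scores[5] == 0.0

    def test_informative_features_reach_top5(self, rng):
        """3 informative + 21 noise features: informatives recovered in
        the top-5 importances for nearly all seeds."""
        n = 300
        y = rng.integers(0, 2, n)
        effect = np.where(y == 1, 1.0, 0.0)
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            X = np.column_stack(
                [
                    effect + r.standard_normal(n),
                    effect + r.standard_normal(n),
                    effect + r.standard_normal(n),
                    r.standard_normal((n, 21)),
                ]
            )
            model = ef.et_fit(
                _matrix(X), np.where(y == 1, "right", "left"), ef.ETConfig(seed=seed)
            )
            top5 = set(np.argsort(model.scores)[::-1][:5])
            hits += {0, 1, 2} <= top5
        assert hits >= 0.9 * n_seeds


class TestRFE:
    def test_24_to_20_in_four_rounds(self, fused_features, filtered_epochs):
        model = ef.rfe_fit(fused_features, filtered_epochs.labels, n_keep=20)
        assert model.mask.size == 20
        assert model.extra["n_rounds"] == 4

    def test_keep_all_identity(self, rng):
        X, y = _planted(rng, n=60, n_noise=5)
        model = ef.rfe_fit(X, y, n_keep=X.n_features)
        assert np.array_equal(model.mask, np.arange(X.n_features))
        assert model.extra["n_rounds"] == 0

    def test_n_keep_exceeding_features_warns_and_keeps_all(self, rng):
        X, y = _planted(rng, n=60, n_noise=5)
        with pytest.warns(UserWarning, match="keeping all"):
            model = ef.rfe_fit(X, y, n_keep=99)
        assert model.mask.size == X.n_features

    def test_planted_columns_survive(self, rng):
        """Two label-correlated columns among 22 noise columns survive
        elimination to 20."""
        n = 400
        y = rng.integers(0, 2, n)
        effect = np.where(y == 1, 1.5, -1.5)
        X = np.column_stack(
            [
                effect + 0.5 * rng.standard_normal(n),
                effect + 0.5 * rng.standard_normal(n),
                rng.standard_normal((n, 22)),
            ]
        )
        model = ef.rfe_fit(_matrix(X), np.where(y == 1, "r", "l"), n_keep=20)
        assert {0, 1} <= set(model.mask.tolist())


class TestPCA:
    def test_component_count(self, fused_features):
        model = ef.pca_fit(fused_features, n_components=20)
        assert model.components.shape == (20, fused_features.n_features)
        # orthonormal rows
        G = model.components @ model.components.T
        assert np.allclose(G, np.eye(20), atol=1e-8)

    def test_rank_limit(self, rng):
        basis = rng.standard_normal((2, 10))
        coefs = rng.standard_normal((50, 2))
        X = _matrix(coefs @ basis)
        model = ef.pca_fit(X, n_components=5)
        explained = model.scores / model.scores.sum()
        assert explained[:2].sum() >= 0.9999

    def test_reconstruction_error_equals_trailing_eigenvalues(self, rng):
        X = _matrix(rng.standard_normal((80, 12)) @ np.diag(np.arange(1, 13)))
        k = 5
        model = ef.pca_fit(X, n_components=k)
        proj = ef.apply_selection(model, X)
        recon = proj.values @ model.components + model.center
        err = np.mean(np.sum((X.values - recon) ** 2, axis=1))
        # oracle: full eigendecomposition of the covariance
        C = np.cov(X.values, rowvar=False, ddof=1)
        eigs = np.sort(np.linalg.eigvalsh(C))[::-1]
        expected = eigs[k:].sum() * (X.n_trials - 1) / X.n_trials
        assert err == pytest.approx(expected, rel=1e-8)

    def test_excess_components_capped_with_warning(self, rng):
        X = _matrix(rng.standard_normal((10, 4)))
        with pytest.warns(UserWarning, match="capped"):
            model = ef.pca_fit(X, n_components=20)
        assert model.components.shape[0] == 4


class TestReliefF:
    def test_label_identical_feature_gets_max_weight(self, rng):
        X, y = _planted(rng, n=200)
        model = ef.relieff_weights(X, y, k_neighbors=10, k_keep=5, seed=0)
        assert int(np.argmax(model.scores)) == 0

    def test_null_feature_weight_near_zero(self, rng):
        n = 500
        y = np.where(rng.integers(0, 2, n) == 1, "right", "left")
        X = _matrix(rng.standard_normal((n, 6)))
        model = ef.relieff_weights(X, y, k_neighbors=10, k_keep=3, seed=0)
        assert np.all(np.abs(model.scores) < 0.05)

    def test_duplicated_column_symmetric_weights(self, rng):
        X, y = _planted(rng, n=150, n_noise=6, flip=0.2)
        vals = np.column_stack([X.values, X.values[:, 0]])
        model = ef.relieff_weights(_matrix(vals), y, k_neighbors=8, k_keep=4, seed=0)
        assert model.scores[0] == pytest.approx(model.scores[-1], abs=1e-10)

    def test_k_neighbors_must_fit_class_counts(self, rng):
        X, y = _planted(rng, n=20)
        with pytest.raises(ValueError, match="k_neighbors"):
            ef.relieff_weights(X, y, k_neighbors=50)


class TestApplySelection:
    def test_identity_mask(self, rng):
        X, y = _planted(rng, n=50, n_noise=5)
        model = ef.rfe_fit(X, y, n_keep=X.n_features)
        out = ef.apply_selection(model, X)
        assert np.array_equal(out.values, X.values)

    def test_masks_are_index_subsets(self, fused_features, filtered_epochs):
        y = filtered_epochs.labels
        for model in (
            ef.et_fit(fused_features, y, ef.ETConfig(seed=1)),
            ef.rfe_fit(fused_features, y, n_keep=20),
            ef.relieff_weights(fused_features, y, k_neighbors=10, seed=1),
        ):
            assert set(model.mask.tolist()) <= set(range(fused_features.n_features))
            out = ef.apply_selection(model, fused_features)
            assert out.n_features == 20
            assert np.array_equal(
                out.values, fused_features.values[:, model.mask]
            )

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _planted(rng, n=40, n_noise=5)
        model = ef.rfe_fit(X, y, n_keep=3)
        bad = _matrix(rng.standard_normal((10, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            ef.apply_selection(model, bad)


def test_selection_model_json_round_trip(tmp_path, rng):
    X, y = _planted(rng, n=80)
    model = ef.et_fit(X, y, ef.ETConfig(seed=4))
    path = tmp_path / "model.json"
    save_selection_model(model, path)
    loaded = load_selection_model(path)
    assert loaded.kind == "et"
    assert np.array_equal(loaded.mask, model.mask)
    assert np.allclose(loaded.scores, model.scores)
    assert loaded.extra["tree_node_counts"] == [
        t.count_nodes() for t in model.extra["trees"]
    ]
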