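"""Ensemble feature selection: ReliefF against a hand oracle, bootstrap
behaviour, vote aggregation and the end-to-end selector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermaug import SyntheticTableSpec, ValidationError, generate_feature_table
from dermaug.selection import (
    AggregatedRanking,
    BootstrapConfig,
    ImportanceMatrix,
    aggregate_votes,
    bootstrap_subsets,
    ensemble_select,
    relief_weights,
)


def brute_relief(X, y, k):
    """Literal per-instance hit/miss computation on [0,1]-scaled features."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(0), X.max(0)
    rng = hi - lo
    Xs = np.where(rng > 0, (X - lo) / np.where(rng > 0, rng, 1), 0.0)
    n, D = Xs.shape
    W = np.zeros(D)
    for a in range(n):
        dists = [np.abs(Xs[a] - Xs[b]).sum() for b in range(n)]
        hits = sorted((d, b) for b, d in enumerate(dists)
                      if b != a and y[b] == y[a])[:k]
        misses = sorted((d, b) for b, d in enumerate(dists)
                        if y[b] != y[a])[:k]
        W += np.mean([np.abs(Xs[b] - Xs[a]) for _, b in misses], axis=0)
        W -= np.mean([np.abs(Xs[b] - Xs[a]) for _, b in hits], axis=0)
    return W / n


class TestRelief:
    def test_matches_hand_computation_on_six_samples(self):
        """Six-sample dataset: weights equal the literal per-instance
        hit/miss evaluation to 1e-9."""
        X = np.array([
            [0.0, 1.0, 0.2],
            [0.1, 0.9, 0.8],
            [0.2, 1.0, 0.4],
            [1.0, 0.0, 0.6],
            [0.9, 0.1, 0.1],
            [0.8, 0.0, 0.9],
        ])
        y = np.array([0, 0, 0, 1, 1, 1])
        w = relief_weights(X, y, k_neighbors=2)
        assert np.allclose(w, brute_relief(X, y, 2), atol=1e-9)
        # the class-separating features outrank the noise feature
        assert w[0] > w[2] and w[1] > w[2]

    def test_matches_hand_computation_random_data(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 4))
        y = np.array([0, 1] * 6)
        assert np.allclose(relief_weights(X, y, k_neighbors=3),
                           brute_relief(X, y, 3), atol=1e-9)

    def test_label_copy_outranks_noise(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 200)
            X = np.column_stack([y.astype(float), rng.standard_normal(200)])
            w = relief_weights(X, y)
            assert w[0] > w[1]

    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.full(40, 3.0), rng.standard_normal(40)])
        y = np.array([0, 1] * 20)
        assert relief_weights(X, y)[0] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="class"):
            relief_weights(np.random.randn(10, 3), np.zeros(10))


class TestBootstrap:
    def test_deterministic_given_seed(self):
        cfg = BootstrapConfig(M=3, seed=5, stratified=False)
        a = bootstrap_subsets(50, cfg)
        b = bootstrap_subsets(50, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_single_subset_for_m_one(self):
        assert len(bootstrap_subsets(10, BootstrapConfig(M=1, seed=0))) == 1

    def test_unique_fraction_matches_bootstrap_theory(self):
        """Size-n resamples contain ~63.2% unique indices (1 - 1/e)."""
        cfg = BootstrapConfig(M=100, seed=1, stratified=False)
        subsets = bootstrap_subsets(1000, cfg)
        frac = np.mean([len(np.unique(s)) / 1000 for s in subsets])
        assert abs(frac - (1 - np.exp(-1))) < 0.02

    def test_stratified_preserves_class_counts(self):
        y = np.array([0] * 80 + [1] * 20)
        cfg = BootstrapConfig(M=10, seed=2, stratified=True)
        for idx in bootstrap_subsets(100, cfg, y=y):
            assert (y[idx] == 1).sum() == 20
            assert (y[idx] == 0).sum() == 80


class TestAggregateVotes:
    def test_hand_counted_votes(self):
        """M=3, D=4, top_t=2: votes counted by hand from the weight rows."""
        W = np.array([
            [0.9, 0.5, 0.1, 0.0],   # votes: f0, f1
            [0.2, 0.8, 0.7, 0.1],   # votes: f1, f2
            [0.6, 0.3, 0.9, 0.2],   # votes: f2, f0
        ])
        imp = ImportanceMatrix(W, ["f0", "f1", "f2", "f3"])
        agg = aggregate_votes(imp, top_t=2)
        assert dict(zip(agg.feature_names, agg.votes)) == \
            {"f0": 2, "f1": 2, "f2": 2, "f3": 0}
        assert agg.ranking[-1] == "f3"

    def test_unanimous_rows_reduce_to_single_ranking(self):
        row = np.array([0.1, 0.9, 0.4, 0.7])
        imp = ImportanceMatrix(np.tile(row, (5, 1)), list("abcd"))
        agg = aggregate_votes(imp, top_t=2)
        assert agg.ranking == ["b", "d", "c", "a"]  # descending weight

    def test_top_t_equals_d_forces_tie_on_mean_rank(self):
        rng = np.random.default_rng(3)
        W = rng.standard_normal((4, 6))
        imp = ImportanceMatrix(W, [f"f{i}" for i in range(6)])
        agg = aggregate_votes(imp, top_t=6)
        assert (agg.votes == 4).all()
        by_mean_rank = sorted(range(6), key=lambda f: (agg.mean_ranks[f],
                                                       imp.feature_names[f]))
        assert agg.ranking == [imp.feature_names[f] for f in by_mean_rank]

    @given(st.integers(1, 8), st.integers(2, 10), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_votes_conserved(self, M, D, seed):
        """Sum of votes over features is exactly M * top_t."""
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((M, D))
        top_t = 1 + seed % D
        agg = aggregate_votes(ImportanceMatrix(W, [f"f{i}" for i in range(D)]),
                              top_t)
        assert agg.votes.sum() == M * top_t
        assert sorted(agg.ranking) == sorted(f"f{i}" for i in range(D))


class TestEnsembleSelect:
    def test_permutation_invariance(self):
        """Shuffling feature columns permutes the selection identically."""
        table, _ = generate_feature_table(SyntheticTableSpec(
            n_maj=60, n_min=40, n_features=12, n_informative=4,
            effect_size=1.5, seed=8))
        X = table.features.to_numpy()
        y = table.labels.to_numpy()
        names = table.feature_names
        cfg = BootstrapConfig(M=10, seed=0)
        sel_a, _ = ensemble_select(X, y, cfg, k_final=4, feature_names=names)
        perm = np.random.default_rng(1).permutation(X.shape[1])
        sel_b, _ = ensemble_select(X[:, perm], y, cfg, k_final=4,
                                   feature_names=[names[p] for p in perm])
        assert sel_a == sel_b

    def test_recovers_planted_signal(self):
        table, info = generate_feature_table(SyntheticTableSpec(
            n_maj=200, n_min=200, n_features=50, n_informative=10,
            effect_size=1.5, seed=0))
        selected, ranking = ensemble_select(
            table.features.to_numpy(), table.labels.to_numpy(),
            BootstrapConfig(M=50, seed=0), k_final=10,
            feature_names=table.feature_names)
        assert len(set(selected) & set(info)) >= 8
        assert len(ranking.ranking) == 50

    def test_single_learner_follows_its_weight_order(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((1, 8))
        imp = ImportanceMatrix(W, [f"f{i}" for i in range(8)])
        agg = aggregate_votes(imp, top_t=3)
        expected = [f"f{i}" for i in np.argsort(-W[0], kind="stable")]
        # top_t features first (by weight), the rest ordered by mean rank,
        # which for M=1 is again the weight order
        assert agg.ranking == expected

    def test_k_final_validated(self):
        table, _ = generate_feature_table(SyntheticTableSpec(
            n_maj=30, n_min=20, n_features=5, n_informative=2, seed=1))
        with pytest.raises(ValidationError, match="k_final"):
            ensemble_select(table.features.to_numpy(), table.labels.to_numpy(),
                            BootstrapConfig(M=2, seed=0), k_final=9)

    def test_half_sample_stability_not_worse_than_single_relief(self):
        """Jaccard overlap of selections across disjoint halves: the ensemble
        is at least as stable as one Relief run (median over 10 seeds)."""
        def jaccard(a, b):
            return len(set(a) & set(b)) / len(set(a) | set(b))

        ens, single = [], []
        for seed in range(10):
            table, _ = generate_feature_table(SyntheticTableSpec(
                n_maj=120, n_min=120, n_features=30, n_informative=6,
                effect_size=1.2, seed=seed))
            X = table.features.to_numpy()
            y = table.labels.to_numpy()
            names = table.feature_names
            idx = np.random.default_rng(seed).permutation(len(y))
            halves = idx[: len(y) // 2], idx[len(y) // 2:]
            sels, singles = [], []
            for h in halves:
                s, _ = ensemble_select(X[h], y[h], BootstrapConfig(M=20, seed=seed),
                                       k_final=6, feature_names=names)
                sels.append(s)
                w = relief_weights(X[h], y[h])
                singles.append([names[j] for j in np.argsort(-w)[:6]])
            ens.append(jaccard(*sels))
            single.append(jaccard(*singles))
        assert np.median(ens) >= np.median(single)
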