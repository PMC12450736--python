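from dataclasses import dataclass

import numpy as np
import pytest

import ftirscreen as fs
from ftirscreen.mc_ga_lda import _stratified_subsample


@dataclass
class FakePatient:
    patient_id: str
    label: str


def labelled(n_pos, n_neg):
    return [FakePatient(f"A{i}", "positive") for i in range(n_pos)] + [
        FakePatient(f"B{i}", "negative") for i in range(n_neg)
    ]


class TestStratifiedSplit:
    def test_balanced_100_gives_35_35_15_15(self):
        train, test = fs.stratified_split(labelled(50, 50), fs.SplitConfig(seed=0))
        assert len(train) == 70 and len(test) == 30
        assert sum(t.startswith("A") for t in train) == 35
        assert sum(t.startswith("B") for t in train) == 35

    def test_round_half_up_on_train_side(self):
        train, test = fs.stratified_split(labelled(5, 5), fs.SplitConfig(seed=1))
        # 0.7 * 5 = 3.5 -> 4 train per class
        assert len(train) == 8 and len(test) == 2

    def test_deterministic_and_partition(self):
        pats = labelled(9, 7)
        a = fs.stratified_split(pats, fs.SplitConfig(seed=5))
        b = fs.stratified_split(pats, fs.SplitConfig(seed=5))
        assert a == b
        train, test = a
        assert set(train) | set(test) == {p.patient_id for p in pats}
        assert set(train) & set(test) == set()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fs.stratified_split(labelled(5, 0), fs.SplitConfig(seed=0))

    def test_unlabelled_rejected(self):
        pats = labelled(3, 3) + [FakePatient("U", "unknown")]
        with pytest.raises(ValueError):
            fs.stratified_split(pats, fs.SplitConfig(seed=0))


def closed_form_lda_scores(X, y, Xq):
    """Independent oracle: explicit pooled-covariance discriminant via
    matrix inverse and loops."""
    X0 = X[y == 0]
    X1 = X[y == 1]
    mu0 = np.array([c.mean() for c in X0.T])
    mu1 = np.array([c.mean() for c in X1.T])
    k = X.shape[1]
    S = np.zeros((k, k))
    for row in X0:
        S += np.outer(row - mu0, row - mu0)
    for row in X1:
        S += np.outer(row - mu1, row - mu1)
    S /= len(X) - 2
    w = np.linalg.inv(S) @ (mu1 - mu0)
    mid = (mu0 + mu1) / 2.0
    return np.array([w @ (q - mid) for q in Xq])


class TestFitLda:
    def test_analytic_two_variable_case(self):
        X0 = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        X1 = X0 + np.array([2.0, 0.0])
        X = np.vstack([X0, X1])
        y = np.array([0] * 4 + [1] * 4)
        m = fs.fit_lda(X, y, gamma=0.0)
        assert m.w[1] == pytest.approx(0.0, abs=1e-12)
        assert m.w[0] > 0
        assert m.score(np.array([[1.0, 0.0]]))[0] == pytest.approx(0.0, abs=1e-10)

    def test_boundary_at_projected_midpoint(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = np.array([0] * 15 + [1] * 15)
        X[y == 1] += 1.0
        m = fs.fit_lda(X, y, gamma=0.0)
        mid = (m.mu0 + m.mu1) / 2.0
        assert m.score(mid[None, :])[0] == pytest.approx(0.0, abs=1e-8)

    def test_relabelling_negates_weights(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 3))
        y = np.array([0] * 12 + [1] * 12)
        X[y == 1] += 0.8
        m = fs.fit_lda(X, y, gamma=0.0)
        m2 = fs.fit_lda(X, 1 - y, gamma=0.0)
        np.testing.assert_allclose(m2.w, -m.w, atol=1e-10)
        np.testing.assert_allclose(m2.b, -m.b, atol=1e-10)

    def test_mirror_symmetry_preserves_decisions(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(24, 3))
        y = np.array([0] * 12 + [1] * 12)
        X[y == 1] += 0.8
        m = fs.fit_lda(X, y, gamma=0.0)
        m2 = fs.fit_lda(-X, 1 - y, gamma=0.0)
        np.testing.assert_allclose(m2.score(-X), -m.score(X), atol=1e-9)

    def test_matches_closed_form_oracle_on_random_instances(self):
        """Well-conditioned regime, gamma=0: scores agree with an
        independent closed-form discriminant to 1e-8, over 100 draws."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(10, 21))
            X = rng.normal(size=(2 * n, k))
            y = np.array([0] * n + [1] * n)
            X[y == 1] += rng.normal(0, 1, size=k)
            m = fs.fit_lda(X, y, gamma=0.0)
            np.testing.assert_allclose(
                m.score(X), closed_form_lda_scores(X, y, X), atol=1e-8
            )

    def test_decision_agreement_with_sklearn(self):
        """Cross-check against an established LDA implementation at the
        decision level (scaling conventions differ)."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(10, 21))
            X = rng.normal(size=(2 * n, k))
            y = np.array([0] * n + [1] * n)
            X[y == 1] += rng.normal(0, 1.5, size=k)
            m = fs.fit_lda(X, y, gamma=0.0)
            ref = sklearn.LinearDiscriminantAnalysis(
                solver="lsqr", priors=[0.5, 0.5]
            ).fit(X, y)
            ours = (m.score(X) > 0).astype(int)
            np.testing.assert_array_equal(ours, ref.predict(X))

    def test_singular_covariance_handled_by_shrinkage(self):
        # more variables than samples: must still produce finite weights
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 20))
        y = np.array([0] * 4 + [1] * 4)
        m = fs.fit_lda(X, y)
        assert m.gamma > 0
        assert np.all(np.isfinite(m.w))
        cond = np.linalg.cond(m.pooled_cov)
        assert cond <= 1e8 * (1 + 1e-6)

    def test_single_class_rejected(self):
        X = np.zeros((6, 2))
        with pytest.raises(ValueError):
            fs.fit_lda(X, np.zeros(6, dtype=int))


def planted_data(rng, n_cal=40, n_val=30, n_vars=20, informative=(3, 11), shift=2.0):
    def draw(n):
        X = rng.normal(size=(n, n_vars))
        y = np.array([0] * (n // 2) + [1] * (n - n // 2))
        for j in informative:
            X[y == 1, j] += shift
        return X, y

    return draw(n_cal) + draw(n_val)


class TestGaSelect:
    def test_recovers_planted_informative_variables(self):
        """Exactly two variables carry class signal; the GA finds both
        in >= 90 % of seeded runs."""
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(100 + seed)
            Xc, yc, Xv, yv = planted_data(rng, n_val=100, shift=3.0)
            cfg = fs.GAConfig(
                population_size=30, generations=30, k_min=2, k_max=5,
                mutation_rate=0.05, parsimony_weight=0.005, seed=seed,
            )
            idx = fs.ga_select(Xc, yc, Xv, yv, cfg)
            hits += {3, 11} <= set(idx.tolist())
        assert hits >= int(0.9 * n_runs)

    def test_zero_generations_returns_valid_mask(self):
        rng = np.random.default_rng(0)
        Xc, yc, Xv, yv = planted_data(rng)
        cfg = fs.GAConfig(population_size=10, generations=0, k_min=2, k_max=5, seed=1)
        idx = fs.ga_select(Xc, yc, Xv, yv, cfg)
        assert 2 <= idx.size <= 5
        assert np.all(np.diff(idx) > 0)

    def test_large_parsimony_penalty_forces_k_min(self):
        rng = np.random.default_rng(1)
        Xc, yc, Xv, yv = planted_data(rng)
        big = fs.GAConfig(population_size=16, generations=10, k_min=2, k_max=8,
                          parsimony_weight=10.0, seed=2)
        none = fs.GAConfig(population_size=16, generations=10, k_min=2, k_max=8,
                           parsimony_weight=0.0, seed=2)
        idx_big = fs.ga_select(Xc, yc, Xv, yv, big)
        idx_none = fs.ga_select(Xc, yc, Xv, yv, none)
        assert idx_big.size == 2
        assert idx_big.size <= idx_none.size

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        Xc, yc, Xv, yv = planted_data(rng)
        cfg = fs.GAConfig(population_size=12, generations=5, k_min=2, k_max=6, seed=9)
        a = fs.ga_select(Xc, yc, Xv, yv, cfg)
        b = fs.ga_select(Xc, yc, Xv, yv, cfg)
        np.testing.assert_array_equal(a, b)

    def test_k_max_exceeding_variables_rejected(self):
        rng = np.random.default_rng(3)
        Xc, yc, Xv, yv = planted_data(rng, n_vars=10, informative=(3, 7))
        cfg = fs.GAConfig(k_min=2, k_max=50, seed=0)
        with pytest.raises(ValueError):
            fs.ga_select(Xc, yc, Xv, yv, cfg)


class TestTrainEnsemble:
    def test_model_count_and_sub_seeds(self, small_cohort, tiny_ga):
        ens = fs.train_ensemble(
            small_cohort, fs.PreprocConfig(), tiny_ga, fs.McConfig(n_models=4, seed=1)
        )
        assert ens.n_models == 4
        assert len(ens.sub_seeds) == 4
        assert len(set(ens.sub_seeds)) == 4

    def test_single_model_degenerate(self, small_cohort, tiny_ga):
        ens = fs.train_ensemble(
            small_cohort, fs.PreprocConfig(), tiny_ga, fs.McConfig(n_models=1, seed=2)
        )
        assert ens.n_models == 1

    def test_selection_frequency_invariant(self, small_ensemble):
        total = sum(m.variable_indices.size for m in small_ensemble.models)
        assert int(small_ensemble.selection_frequency.sum()) == total

    def test_quarantined_ids_rejected(self, small_cohort, tiny_ga):
        some_id = small_cohort.patients[0].patient_id
        with pytest.raises(ValueError, match="leaked"):
            fs.train_ensemble(
                small_cohort, fs.PreprocConfig(), tiny_ga,
                fs.McConfig(n_models=1, seed=0), quarantined_ids=[some_id],
            )

    def test_seed_determinism_model_by_model(self, small_cohort, tiny_ga):
        mk = lambda: fs.train_ensemble(
            small_cohort, fs.PreprocConfig(), tiny_ga, fs.McConfig(n_models=3, seed=5)
        )
        a, b = mk(), mk()
        assert a.sub_seeds == b.sub_seeds
        for ma, mb in zip(a.models, b.models):
            np.testing.assert_array_equal(ma.variable_indices, mb.variable_indices)
            np.testing.assert_array_equal(ma.w, mb.w)
            assert ma.b == mb.b

    def test_json_round_trip(self, small_ensemble, tmp_path):
        path = tmp_path / "ens.json"
        small_ensemble.to_json(path)
        back = fs.Ensemble.from_json(path)
        assert back.n_models == small_ensemble.n_models
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, small_ensemble.wavenumbers.size))
        np.testing.assert_allclose(
            back.scores(X), small_ensemble.scores(X), atol=1e-12
        )
        np.testing.assert_array_equal(
            back.selection_frequency, small_ensemble.selection_frequency
        )

    def test_stratified_subsample_leaves_validation(self):
        y = np.array([0] * 10 + [1] * 10)
        rng = np.random.default_rng(0)
        cal, val = _stratified_subsample(y, 0.8, rng)
        assert val.size > 0
        assert set(cal) | set(val) == set(range(20))
        assert set(cal) & set(val) == set()
        assert {0, 1} <= set(y[cal]) and len(set(y[cal])) == 2
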