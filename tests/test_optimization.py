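"""Grid-search optimization of ApEn parameters against labeled classes."""

import numpy as np
import pytest

from rotormap.optimization import (
    GRID_M,
    GRID_R,
    ClassApEnDistribution,
    grid_search,
    interclass_minmax_distance,
    interclass_percentile_distance,
    kfold_validate,
    objective_scores,
    spearman_apen_vs_class,
)
from rotormap.synthetic_egm import (
    CLASSES,
    FractionationDataset,
    LabeledEGM,
    generate_dataset,
    generate_planted_dataset,
)


def _dist(**kwargs):
    return ClassApEnDistribution({c: np.asarray(v, float) for c, v in kwargs.items()})


class TestCriteria:
    def test_identical_constant_classes_dp_zero(self):
        d = _dist(C0=[0.5] * 10, C1=[0.5] * 10, C2=[0.5] * 10, C3=[0.5] * 10)
        assert interclass_percentile_distance(d) == 0.0

    def test_disjoint_classes_match_hand_evaluation(self):
        vals = {
            "C0": np.linspace(0.0, 0.1, 11),
            "C1": np.linspace(0.3, 0.4, 11),
            "C2": np.linspace(0.6, 0.7, 11),
            "C3": np.linspace(0.9, 1.0, 11),
        }
        d = _dist(**vals)
        # type-7 quantiles of linspace(a, a+0.1, 11): Q1 = a+0.025, Q3 = a+0.075
        expected_dp = sum(
            (np.quantile(vals[CLASSES[k + 1]], 0.25) - np.quantile(vals[CLASSES[k]], 0.75))
            for k in range(3)
        )
        assert interclass_percentile_distance(d) == pytest.approx(expected_dp, abs=1e-12)
        # adjacent gap: Q1(a + 0.3) - Q3(a) = (0.3 + 0.025) - 0.075 = 0.25
        assert interclass_percentile_distance(d) == pytest.approx(3 * 0.25, abs=1e-9)
        expected_dmm = 3 * 0.2
        assert interclass_minmax_distance(d) == pytest.approx(expected_dmm, abs=1e-12)

    def test_translation_invariance_of_dp(self):
        rng = np.random.default_rng(0)
        base = {c: rng.normal(size=30) for c in CLASSES}
        d0 = interclass_percentile_distance(_dist(**base))
        d1 = interclass_percentile_distance(
            _dist(**{c: v + 7.3 for c, v in base.items()})
        )
        assert d1 == pytest.approx(d0, abs=1e-12)

    def test_identical_spread_classes_dmm_is_minus_3_ranges(self):
        v = np.linspace(0.2, 0.8, 25)
        d = _dist(C0=v, C1=v, C2=v, C3=v)
        assert interclass_minmax_distance(d) == pytest.approx(-3 * 0.6, abs=1e-12)
        assert interclass_minmax_distance(d) <= 0.0

    def test_widening_a_class_never_increases_dmm(self):
        rng = np.random.default_rng(1)
        base = {c: rng.normal(loc=i, size=30) for i, c in enumerate(CLASSES)}
        d0 = interclass_minmax_distance(_dist(**base))
        widened = dict(base)
        widened["C1"] = (base["C1"] - base["C1"].mean()) * 2.5 + base["C1"].mean()
        d1 = interclass_minmax_distance(_dist(**widened))
        assert d1 <= d0 + 1e-12

    def test_empty_class_rejected(self):
        d = ClassApEnDistribution({"C0": np.array([1.0]), "C1": np.array([])})
        with pytest.raises(ValueError):
            interclass_percentile_distance(d)


class TestObjective:
    def test_equal_criteria_give_their_common_rescaled_value(self):
        dp = np.array([[0.1, 0.5, 0.9]])
        f = objective_scores(dp, dp)
        assert np.allclose(f, (dp - 0.1) / 0.8)

    def test_single_combination_grid(self):
        f = objective_scores(np.array([[0.7]]), np.array([[-0.2]]))
        assert f.shape == (1, 1)
        assert np.isfinite(f).all()

    def test_ranking_invariant_under_joint_affine_rescale(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            dp = rng.normal(size=(5, 30))
            dmm = rng.normal(size=(5, 30))
            f0 = objective_scores(dp, dmm)
            f1 = objective_scores(3.2 * dp + 1.0, 3.2 * dmm + 1.0)
            assert np.argmax(f0) == np.argmax(f1)
            assert np.allclose(np.argsort(f0.ravel()), np.argsort(f1.ravel()))


class TestGridSearch:
    def test_grid_has_150_combinations(self):
        assert len(GRID_M) * len(GRID_R) == 150
        assert GRID_R[0] == 0.02 and GRID_R[-1] == 0.60

    def test_identical_signals_tie_break_to_simplest(self):
        x = np.random.default_rng(3).normal(size=300)
        items = [
            LabeledEGM(samples=x.copy(), fs=1000.0, label=c)
            for c in CLASSES
            for _ in range(3)
        ]
        ds = FractionationDataset(items=items, fs=1000.0)
        res = grid_search(ds, window=300)
        assert np.allclose(res.f, res.f.flat[0])
        assert (res.best_m, res.best_r) == (1, 0.02)

    def test_planted_optimum_recovered(self):
        for seed in (0, 1, 2):
            ds = generate_planted_dataset(3, 0.36, n_per_class=30, n_samples=500, seed=seed)
            res = grid_search(ds, window=500)
            assert (res.best_m, res.best_r) == (3, 0.36)

    def test_signal_shorter_than_window_excluded_with_warning(self):
        ds = generate_dataset(3, duration_ms=1000.0, seed=5)
        ds.items[0].samples = ds.items[0].samples[:400]
        with pytest.warns(UserWarning, match="excluded"):
            res = grid_search(ds, window=1000)
        assert res.f.shape == (5, 30)

    def test_optimum_beats_poor_corner_on_default_synthetic(self):
        ds = generate_dataset(15, duration_ms=1000.0, seed=0)
        res = grid_search(ds, window=1000)
        i_corner = np.where(GRID_M == 1)[0][0]
        j_corner = np.where(GRID_R == 0.60)[0][0]
        assert res.f.max() > res.f[i_corner, j_corner]


class TestKFold:
    def test_agreement_on_planted_dataset(self):
        ds = generate_planted_dataset(3, 0.36, n_per_class=30, n_samples=500, seed=0)
        kf = kfold_validate(ds, window=500, k=2, seed=0)
        assert kf.agreement_rate == 1.0
        assert kf.modal_best == (3, 0.36)

    def test_same_seed_same_partitions(self):
        ds = generate_planted_dataset(2, 0.20, n_per_class=12, n_samples=300, seed=1)
        a = kfold_validate(ds, window=300, k=3, seed=5)
        b = kfold_validate(ds, window=300, k=3, seed=5)
        assert a.fold_best == b.fold_best

    def test_k_exceeding_class_size_rejected(self):
        ds = generate_dataset(3, duration_ms=1000.0, seed=2)
        with pytest.raises(ValueError, match="fewer than"):
            kfold_validate(ds, window=1000, k=10)


class TestSpearman:
    def test_monotone_values_give_rho_one(self):
        items = []
        rng = np.random.default_rng(4)
        sigmas = [0.02, 0.08, 0.2, 0.45]  # below the ApEn saturation regime
        for i, c in enumerate(CLASSES):
            for _ in range(5):
                # noise level grows with class index -> ApEn increases
                x = np.sin(np.arange(600) / 5.0) + rng.normal(0, sigmas[i], 600)
                items.append(LabeledEGM(samples=x, fs=1000.0, label=c))
        ds = FractionationDataset(items=items, fs=1000.0)
        rho = spearman_apen_vs_class(ds, m=2, r_frac=0.2, window=600)
        assert rho > 0.95

    def test_permuted_labels_uncorrelated(self):
        """Label permutation destroys the correlation (mean rho ~ 0)."""
        from scipy.stats import spearmanr

        from rotormap.entropy import apen

        ds = generate_dataset(25, duration_ms=1000.0, seed=6)
        vals = np.array([apen(it.samples[:1000], 2, 0.2) for it in ds.items])
        cls = np.array([CLASSES.index(it.label) for it in ds.items])
        rng = np.random.default_rng(7)
        rhos = [
            spearmanr(vals, rng.permutation(cls)).statistic for _ in range(100)
        ]
        assert abs(np.mean(rhos)) < 0.05

    def test_zero_variance_rejected(self):
        items = [
            LabeledEGM(samples=np.zeros(300), fs=1000.0, label=c)
            for c in CLASSES
            for _ in range(3)
        ]
        ds = FractionationDataset(items=items, fs=1000.0)
        with pytest.raises(ValueError):
            spearman_apen_vs_class(ds, m=2, r_frac=0.2, window=300)
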