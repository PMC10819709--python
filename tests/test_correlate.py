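import numpy as np
import pytest
from scipy import stats

from vocstack import (
    CorrelationConfig,
    PlatformView,
    averaged_correlations,
    blood_association,
    cca_first_variate,
    fisher_z_mean,
    merge_psc_groups,
    permutation_screen,
    rfe_to_significance,
)

CFG = CorrelationConfig(n_iterations=10, alpha=0.05, n_permutations=99, seed=2)


class TestCcaFirstVariate:
    def test_identical_columns_give_unit_correlation(self, rng):
        x = rng.normal(size=(30, 1))
        r1, _, _, p = cca_first_variate(x, x.copy(), n_permutations=99, seed=0)
        assert r1 == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_univariate_reduces_to_absolute_pearson(self, rng):
        x = rng.normal(size=(40, 1))
        y = -2.0 * x + 0.3 * rng.normal(size=(40, 1))
        r1, _, _, _ = cca_first_variate(x, y, n_permutations=9, seed=0)
        assert r1 == pytest.approx(abs(stats.pearsonr(x[:, 0], y[:, 0])[0]), abs=1e-6)

    def test_matches_sklearn_cca(self, rng):
        from sklearn.cross_decomposition import CCA

        X = rng.normal(size=(60, 4))
        Y = rng.normal(size=(60, 3))
        Y[:, 0] += 0.8 * X[:, 1]
        r1, _, _, _ = cca_first_variate(X, Y, n_permutations=9, seed=0)
        ref = CCA(n_components=1, scale=True).fit(X, Y)
        xs, ys = ref.transform(X, Y)
        assert r1 == pytest.approx(abs(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1]), abs=1e-4)

    def test_sample_size_precondition(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError, match="n > max"):
            cca_first_variate(X, X, n_permutations=9)

    def test_rank_deficiency_triggers_ridge_warning(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 2] = X[:, 1]  # exact collinearity
        Y = rng.normal(size=(30, 2))
        with pytest.warns(UserWarning, match="ridge"):
            cca_first_variate(X, Y, n_permutations=9, seed=0)

    def test_null_permutation_p_roughly_uniform(self, rng):
        ps = []
        for i in range(100):
            X = rng.normal(size=(50, 3))
            Y = rng.normal(size=(50, 3))
            _, _, _, p = cca_first_variate(X, Y, n_permutations=49, seed=i)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRfe:
    def test_already_significant_sets_untouched(self, rng):
        X = rng.normal(size=(50, 3))
        Y = X + 0.1 * rng.normal(size=(50, 3))
        sx, sy, r1, p, sig = rfe_to_significance(X, Y, CFG, seed=0)
        assert sig and len(sx) == 3 and len(sy) == 3

    def test_all_noise_flagged_not_significant(self, rng):
        ok = 0
        for i in range(5):
            X = rng.normal(size=(40, 4))
            Y = rng.normal(size=(40, 4))
            *_, p, sig = rfe_to_significance(X, Y, CFG, seed=i)
            ok += (not sig)
        assert ok >= 3  # at alpha=0.05 the null rarely reaches significance

    def test_planted_pair_survives_elimination(self, rng):
        hits = 0
        runs = 20
        for i in range(runs):
            X = rng.normal(size=(45, 4))
            Y = rng.normal(size=(45, 4))
            Y[:, 2] = 0.9 * X[:, 1] + 0.4 * rng.normal(size=45)
            sx, sy, _, _, sig = rfe_to_significance(
                X, Y, CFG, x_names=list("abcd"), y_names=list("wxyz"), seed=i)
            hits += sig and ("b" in sx) and ("y" in sy)
        assert hits >= 0.8 * runs


class TestPermutationScreen:
    def test_single_iteration_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        cfg = CorrelationConfig(n_iterations=1, n_permutations=99)
        with pytest.raises(ValueError, match="insufficient iterations"):
            permutation_screen(PlatformView(X, ("a", "b", "c")),
                               PlatformView(X, ("d", "e", "f")), cfg)

    def test_planted_pair_screened_in(self, rng):
        n = 45
        X = np.abs(rng.normal(size=(n, 4))) + 0.5
        Y = rng.normal(size=(n, 4))
        Y[:, 1] = np.log(X[:, 2] + 0.1) * 2 + 0.3 * rng.normal(size=n)
        X[rng.random((n, 4)) < 0.15] = np.nan  # imputation path exercised
        cfg = CorrelationConfig(n_iterations=12, n_permutations=60, seed=4)
        res = permutation_screen(PlatformView(X, ("x0", "x1", "x2", "x3")),
                                 PlatformView(Y, ("y0", "y1", "y2", "y3")), cfg)
        assert "x2" in res.selected_x and "y1" in res.selected_y

    def test_null_screen_keeps_few_features(self, rng):
        kept = 0
        total = 0
        for i in range(3):
            X = np.abs(rng.normal(size=(40, 4))) + 0.5
            Y = rng.normal(size=(40, 4))
            cfg = CorrelationConfig(n_iterations=10, n_permutations=60, seed=10 + i)
            res = permutation_screen(PlatformView(X, tuple("abcd")),
                                     PlatformView(Y, tuple("wxyz")), cfg)
            kept += len(res.selected_x) + len(res.selected_y)
            total += 8
        assert kept / total <= 0.25


class TestAveragedCorrelations:
    def test_fisher_z_closed_forms(self):
        assert fisher_z_mean([0.5, 0.5]) == pytest.approx(0.5, abs=1e-9)
        expect = np.tanh(np.arctanh(0.8) / 2)
        assert fisher_z_mean([0.0, 0.8]) == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(0.5, abs=1e-12)

    def test_order_invariance_and_identity(self, rng):
        r = rng.uniform(-0.9, 0.9, size=10)
        assert fisher_z_mean(r) == pytest.approx(fisher_z_mean(r[::-1]))
        assert fisher_z_mean([0.3] * 5) == pytest.approx(0.3)

    def test_complete_data_averaging_is_idempotent(self, rng):
        X = rng.normal(size=(40, 2))
        Y = np.column_stack([X[:, 0] * 2 + 0.05 * rng.normal(size=40),
                             rng.normal(size=40)])
        cfg = CorrelationConfig(n_iterations=3, n_permutations=60, seed=0)
        res = averaged_correlations(PlatformView(X, ("a", "b")),
                                    PlatformView(Y, ("c", "d")),
                                    ["a", "b"], ["c", "d"], cfg)
        single, *_ = cca_first_variate(X, Y, n_permutations=9, seed=0)
        assert res.canonical_r == pytest.approx(single, abs=1e-9)

    def test_bh_adjustment_never_decreases_p(self, rng):
        X = np.abs(rng.normal(size=(30, 3))) + 0.5
        X[rng.random((30, 3)) < 0.1] = np.nan
        Y = rng.normal(size=(30, 2))
        cfg = CorrelationConfig(n_iterations=4, n_permutations=60, seed=1)
        res = averaged_correlations(PlatformView(X, ("a", "b", "c")),
                                    PlatformView(Y, ("d", "e")),
                                    ["a", "b"], ["d", "e"], cfg)
        assert (res.univariate_p_adj.to_numpy() >= res.univariate_p.to_numpy() - 1e-12).all()

    def test_empty_screened_set_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(ValueError, match="non-empty"):
            averaged_correlations(PlatformView(X, ("a", "b")),
                                  PlatformView(X, ("c", "d")), [], ["c"], CFG)


class TestBloodAssociation:
    def test_linked_breath_blood_recovered(self, default_cohort):
        _, breath, truth = default_cohort
        lab = merge_psc_groups(breath.samples)
        xv = PlatformView(np.log(breath.values), tuple(breath.features))
        cfg = CorrelationConfig(n_iterations=8, n_permutations=99, seed=6)
        res = blood_association(xv, breath, lab.as_array(), cfg)
        assert res.canonical_r >= 0.8
        # the generator's blood-linked breath markers show the linkage
        linked = [m for m in truth.blood_linked_breath if m in res.univariate_r.index]
        assert linked
        assert res.univariate_r.loc[linked].abs().to_numpy().max() >= 0.6

    def test_shuffled_blood_not_significant(self, default_cohort, rng):
        import dataclasses

        _, breath, _ = default_cohort
        lab = merge_psc_groups(breath.samples)
        # shuffle blood across patients to break the linkage
        perm = rng.permutation(breath.n_samples)
        samples = [dataclasses.replace(s, blood=breath.samples[j].blood)
                   for s, j in zip(breath.samples, perm)]
        from vocstack import FeatureTable

        shuffled = FeatureTable(breath.values, samples, breath.features)
        xv = PlatformView(np.log(breath.values), tuple(breath.features))
        cfg = CorrelationConfig(n_iterations=6, n_permutations=99, seed=7)
        res = blood_association(xv, shuffled, lab.as_array(), cfg)
        assert not res.significant

    def test_constant_blood_column_dropped(self, rng):
        from vocstack.core import FeatureTable, Group, SampleMeta

        n = 12
        samples = [SampleMeta(sample_id=f"s{i}", patient_id=f"p{i}", group=Group.PSC,
                              blood={"ALP": 100.0 + i, "AST": 30.0 + 2 * i,
                                     "ALT": 5.0, "bilirubin": 8.0 + i})
                   for i in range(n)]
        t = FeatureTable(np.abs(rng.normal(size=(n, 6))) + 0.5, samples,
                         [f"f{j}" for j in range(6)])
        xv = PlatformView(np.log(t.values), tuple(t.features))
        cfg = CorrelationConfig(n_iterations=4, n_permutations=60, seed=2)
        with pytest.warns(UserWarning, match="constant blood"):
            res = blood_association(xv, t, np.ones(n, int), cfg)
        assert "ALT" not in res.selected_y

    def test_too_few_complete_patients_rejected(self, rng):
        from vocstack.core import FeatureTable, Group, SampleMeta

        samples = [SampleMeta(sample_id=f"s{i}", patient_id=f"p{i}", group=Group.PSC,
                              blood={"ALP": 100.0} if i < 3 else {})
                   for i in range(8)]
        t = FeatureTable(np.abs(rng.normal(size=(8, 3))) + 0.5, samples, ["a", "b", "c"])
        xv = PlatformView(np.log(t.values), tuple(t.features))
        with pytest.raises(ValueError, match="fewer than 6"):
            blood_association(xv, t, np.ones(8, int), CFG)
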