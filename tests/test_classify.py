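import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats

from vocstack import (
    FeatureTable,
    SelectionConfig,
    fit_evaluate,
    merge_psc_groups,
    proximity_covariate_test,
    roc_metrics,
    split_duplicate_safe,
    stratified_auc,
    water_content_model,
)
from vocstack._rf import pcoa
from vocstack.classify import ProximityMatrix
from vocstack.core import Group, SampleMeta

FAST = SelectionConfig(n_iterations=10, rf_trees=50, seed=3)


def pair_counting_auc(probs, y):
    """Exhaustive concordant-pair AUC (ties count 1/2)."""
    pos = [p for p, l in zip(probs, y) if l == 1]
    neg = [p for p, l in zip(probs, y) if l == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a, b in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestRocMetrics:
    def test_perfect_predictions(self):
        r = roc_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert (r.auc, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)

    def test_constant_probabilities_are_chance(self):
        assert roc_metrics([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == 0.5

    def test_hand_worked_six_sample_example(self):
        probs = [0.9, 0.8, 0.7, 0.4, 0.3, 0.2]
        y = [1, 1, 0, 1, 0, 0]
        r = roc_metrics(probs, y)
        assert r.auc == pytest.approx(pair_counting_auc(probs, y))
        assert r.auc == pytest.approx(8 / 9)

    def test_trapezoid_matches_pair_counting_on_random_vectors(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=20)
            if len(set(y)) < 2:
                y[0], y[1] = 0, 1
            probs = rng.random(20)
            assert roc_metrics(probs, y).auc == pytest.approx(
                pair_counting_auc(probs, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_metrics([0.1, 0.2], [1, 1])


def _dup_samples(n_pos, n_neg, dup=True):
    out = []
    for i in range(n_pos + n_neg):
        grp = Group.PSC if i < n_pos else Group.IBD
        for d in (1, 2) if dup else (1,):
            out.append(SampleMeta(
                sample_id=f"s{i}_{d}", patient_id=f"p{i}", group=grp,
                duplicate_index=d, water_content=70.0,
                severity_score=2.0 if grp is Group.PSC else None))
    return out


class TestDuplicateSafeSplit:
    def test_duplicates_never_straddle(self):
        samples = _dup_samples(6, 10)
        pids = np.array([s.patient_id for s in samples])
        for seed in range(100):
            train, test = split_duplicate_safe(samples, FAST, seed)
            assert set(pids[train]).isdisjoint(set(pids[test]))

    def test_singletons_reduce_to_stratified_split(self):
        samples = _dup_samples(6, 10, dup=False)
        train, test = split_duplicate_safe(samples, FAST, 0)
        assert len(train) + len(test) == 16

    def test_class_fractions_within_one_patient(self):
        samples = _dup_samples(24, 49)
        y = merge_psc_groups(samples).as_array()
        pids = np.array([s.patient_id for s in samples])
        for seed in range(20):
            train, _ = split_duplicate_safe(samples, FAST, seed)
            n_pos = len({p for p in pids[train] if y[list(pids).index(p)] == 1})
            n_pos = len(set(pids[train][y[train] == 1]))
            n_neg = len(set(pids[train][y[train] == 0]))
            assert abs(n_pos - 0.83 * 24) <= 1.0
            assert abs(n_neg - 0.73 * 49) <= 1.0


def _separable_table(n=12):
    samples = _dup_samples(n // 2, n // 2, dup=False)
    y = merge_psc_groups(samples).as_array()
    # ratio a/b separates perfectly: a = 100 for positives, 1 for negatives
    a = np.where(y == 1, 100.0, 1.0) * np.linspace(0.9, 1.1, n)
    b = np.ones(n)
    return FeatureTable(np.column_stack([a, b]), samples, ["a", "b"]), y


class TestFitEvaluate:
    def test_perfectly_separable_ratio_reaches_auc_one(self):
        table, y = _separable_table()
        res = fit_evaluate(table, y, [("a", "b")], FAST)
        assert res.auc == 1.0

    def test_proximity_invariants_and_probability_range(self, small_bio):
        lab = merge_psc_groups(small_bio.samples)
        res = fit_evaluate(small_bio, lab.as_array(),
                           [(small_bio.features[0], small_bio.features[1])], FAST)
        P = res.proximity.values
        assert np.allclose(P, P.T) and np.allclose(np.diag(P), 1.0)
        assert P.min() >= 0 and P.max() <= 1
        assert res.probabilities.min() >= 0 and res.probabilities.max() <= 1
        ProximityMatrix(P, res.sample_ids)  # revalidates invariants

    def test_single_class_pool_rejected(self):
        table, y = _separable_table()
        with pytest.raises(ValueError):
            fit_evaluate(table, np.ones_like(y), [("a", "b")], FAST)


class TestWaterContentModel:
    def test_informative_water_reaches_auc_one(self):
        samples = _dup_samples(6, 6, dup=False)
        y = merge_psc_groups(samples).as_array()
        samples = [dataclasses.replace(s, water_content=85.0 if yy else 60.0)
                   for s, yy in zip(samples, y)]
        t = FeatureTable(np.ones((12, 1)), samples, ["f"])
        res, scatter = water_content_model(t, y, FAST)
        assert res.auc == 1.0
        assert scatter.shape == (12, 2)

    def test_uninformative_water_is_near_chance(self):
        rng = np.random.default_rng(4)
        aucs = []
        for seed in range(5):
            samples = _dup_samples(8, 8, dup=False)
            y = merge_psc_groups(samples).as_array()
            samples = [dataclasses.replace(s, water_content=float(rng.uniform(60, 90)))
                       for s in samples]
            t = FeatureTable(np.ones((16, 1)), samples, ["f"])
            res, _ = water_content_model(
                t, y, dataclasses.replace(FAST, seed=seed, n_iterations=15))
            aucs.append(res.auc)
        assert abs(float(np.mean(aucs)) - 0.5) <= 0.15

    def test_constant_water_rejected(self):
        samples = _dup_samples(3, 3, dup=False)
        y = merge_psc_groups(samples).as_array()
        t = FeatureTable(np.ones((6, 1)), samples, ["f"])
        with pytest.raises(ValueError, match="no variation"):
            water_content_model(t, y, FAST)


def _block_proximity(n=20, blocks=True, seed=0):
    rng = np.random.default_rng(seed)
    if blocks:
        z = np.repeat([0.0, 1.0], n // 2)
        P = 0.2 + 0.6 * (z[:, None] == z[None, :]) + rng.uniform(0, 0.05, (n, n))
    else:
        z = rng.normal(size=n)
        P = 0.5 + rng.uniform(0, 0.05, (n, n))
    P = np.clip((P + P.T) / 2, 0, 1)
    np.fill_diagonal(P, 1.0)
    ids = tuple(f"s{i}" for i in range(n))
    return ProximityMatrix(P, ids), z


class TestProximityCovariateTest:
    def test_block_structure_detected(self):
        prox, z = _block_proximity()
        _, p = proximity_covariate_test(prox, z, n_perm=199, seed=1)
        assert p <= 0.01

    def test_p_floor_is_formula_bound(self):
        prox, z = _block_proximity()
        _, p = proximity_covariate_test(prox, z, n_perm=99, seed=1)
        assert p >= 1.0 / (1 + 99)

    def test_too_few_permutations_rejected(self):
        prox, z = _block_proximity()
        with pytest.raises(ValueError, match="n_perm"):
            proximity_covariate_test(prox, z, n_perm=50, seed=0)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for i in range(200):
            prox, _ = _block_proximity(n=15, blocks=False, seed=100 + i)
            z = rng.normal(size=15)
            _, p = proximity_covariate_test(prox, z, n_perm=99, seed=i)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestStratifiedAuc:
    def _result(self, seed=0):
        table, y = _separable_table(16)
        return fit_evaluate(table, y, [("a", "b")],
                            dataclasses.replace(FAST, seed=seed))

    def test_halves_partition_positives(self):
        res = self._result()
        sev = np.where(res.labels == 1, np.arange(len(res.labels), dtype=float), np.nan)
        out = stratified_auc(res, sev, [(0.0, 0.5), (0.5, 1.0)])
        assert set(out) == {(0.0, 0.5), (0.5, 1.0)}

    def test_uninformative_severity_leaves_auc_unchanged(self):
        res = self._result()
        rng = np.random.default_rng(1)
        sev = np.where(res.labels == 1, rng.normal(2, 0.5, len(res.labels)), np.nan)
        out = stratified_auc(res, sev, [(0.0, 0.5), (0.5, 1.0)])
        for auc in out.values():
            assert abs(auc - res.auc) <= 0.25

    def test_empty_stratum_rejected(self):
        res = self._result()
        sev = np.where(res.labels == 1, 1.0, np.nan)  # all positives tie at 1.0
        with pytest.raises(ValueError, match="empty"):
            stratified_auc(res, sev, [(0.5, 0.5)])  # zero-width band above min


class TestPcoa:
    def test_distances_reproduced_for_euclidean_input(self, rng):
        X = rng.normal(size=(10, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        coords, _ = pcoa(D)
        D2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(D, D2, atol=1e-8)

    def test_matches_skbio_eigenvalues(self, rng):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix

        X = rng.normal(size=(8, 4))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        _, eig = pcoa(D)
        ref = skbio_pcoa(DistanceMatrix(D)).eigvals.to_numpy()
        assert np.allclose(np.sort(eig)[::-1][:4], np.sort(ref)[::-1][:4], atol=1e-6)
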