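"""Duplicate-aware final model fitting, ROC metrics and sensitivity analyses.

The final classifier is an iterated random forest on the selected log-ratio
columns: per iteration, patients are subsampled class-wise (both duplicate
aliquots enter the training pool when their patient does — the extra rows
let trees grow deeper), held-out samples are predicted, and per-sample
probabilities are averaged across iterations.  An all-data forest supplies
the OOB proximity matrix, embedded by principal coordinates for
visualization.  Sensitivity analyses: a water-content-only model, a
severity-stratified AUC, and a permutation pseudo-F test for the effect of
a numeric covariate on the proximity structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from ._rf import fit_forest, gower_center, oob_proximity, pcoa
from .core import FeatureTable, Role
from .logratios import SelectionConfig, impute_missing, ratio_columns
from .sampling import duplicate_safe_split
from .simulate import rng_for

__all__ = [
    "ProximityMatrix",
    "RocSummary",
    "ModelResult",
    "split_duplicate_safe",
    "fit_evaluate",
    "fit_evaluate_features",
    "roc_metrics",
    "water_content_model",
    "proximity_covariate_test",
    "stratified_auc",
]


@dataclass(frozen=True)
class ProximityMatrix:
    values: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        V = self.values
        n = len(self.sample_ids)
        if V.shape != (n, n):
            raise ValueError("proximity matrix shape does not match sample_ids")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("proximity matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-10):
            raise ValueError("proximity diagonal must be 1")
        if V.min() < -1e-12 or V.max() > 1 + 1e-12:
            raise ValueError("proximity entries must lie in [0, 1]")


@dataclass(frozen=True)
class RocSummary:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ModelResult:
    sample_ids: tuple[str, ...]
    patient_ids: tuple[str, ...]
    labels: np.ndarray
    probabilities: np.ndarray
    selected_features: tuple[str, ...]
    proximity: ProximityMatrix
    pcoa_coordinates: np.ndarray
    roc: RocSummary

    @property
    def auc(self) -> float:
        return self.roc.auc


def roc_metrics(probabilities, labels) -> RocSummary:
    """Trapezoidal ROC AUC plus the Youden-optimal operating point.

    The reported sensitivity/specificity pair is taken at the threshold
    maximizing tpr - fpr (Youden's J); the full curve is returned for
    plotting.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("roc_metrics requires both classes present")
    fpr, tpr, thr = roc_curve(y, p)
    area = float(_trapezoid_auc(fpr, tpr))
    j = int(np.argmax(tpr - fpr))
    return RocSummary(auc=area, sensitivity=float(tpr[j]),
                      specificity=float(1.0 - fpr[j]), threshold=float(thr[j]),
                      fpr=fpr, tpr=tpr, thresholds=thr)


def split_duplicate_safe(samples: Sequence, config: SelectionConfig,
                         seed: int, labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Class-wise patient split with duplicates always on one side.

    ``labels`` defaults to the merged PSC-class labeling derived from the
    sample groups."""
    from .core import merge_psc_groups

    if labels is None:
        labels = merge_psc_groups(samples).as_array()
    pids = np.asarray([s.patient_id for s in samples])
    rng = np.random.default_rng(seed)
    return duplicate_safe_split(pids, np.asarray(labels, int),
                                config.psc_subsample, config.ibd_subsample, rng)


def _iterated_probabilities(X_builder, table: FeatureTable, y: np.ndarray,
                            config: SelectionConfig) -> np.ndarray:
    """Average held-out class-1 probabilities over duplicate-safe iterations.

    ``X_builder(seed)`` realizes the design matrix for one iteration
    (re-imputation happens inside it when the table has missing entries).
    """
    pids = np.asarray([s.patient_id for s in table.samples])
    root = rng_for(config.seed, "fit_evaluate")
    prob_sum = np.zeros(table.n_samples)
    prob_cnt = np.zeros(table.n_samples)
    for _ in range(config.n_iterations):
        it_seed = int(root.integers(2**31))
        rng = np.random.default_rng(it_seed)
        X = X_builder(it_seed)
        train_idx, test_idx = duplicate_safe_split(
            pids, y, config.psc_subsample, config.ibd_subsample, rng)
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("single-class training pool; check the design")
        if test_idx.size == 0:
            continue
        model = fit_forest(X[train_idx], y[train_idx], config.rf_trees, it_seed)
        prob = model.predict_proba(X[test_idx])[:, list(model.classes_).index(1)]
        prob_sum[test_idx] += prob
        prob_cnt[test_idx] += 1
    if np.any(prob_cnt == 0):
        # unpredicted samples (can happen at tiny iteration counts): fall
        # back to the uninformative probability rather than dropping them
        prob_sum[prob_cnt == 0] = 0.5
        prob_cnt[prob_cnt == 0] = 1
    return prob_sum / prob_cnt


def fit_evaluate(table: FeatureTable, labels, selected_pairs,
                 config: SelectionConfig) -> ModelResult:
    """Fit and internally validate the final log-ratio forest.

    ``selected_pairs`` are (numerator, denominator) compound pairs from the
    stability selection.  Returns averaged held-out probabilities, ROC
    metrics at the Youden point, the OOB proximity of an all-data model and
    its 2-D principal-coordinate embedding.
    """
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != table.n_samples:
        raise ValueError("labels must align with table samples")
    if not selected_pairs:
        raise ValueError("no selected ratio pairs given")

    def build(seed: int) -> np.ndarray:
        X = impute_missing(table, seed=seed)
        return ratio_columns(X, table.features, selected_pairs)

    probs = _iterated_probabilities(build, table, y, config)
    roc = roc_metrics(probs, y)

    final_seed = int(rng_for(config.seed, "final_model").integers(2**31))
    X_final = build(final_seed)
    final = fit_forest(X_final, y, config.rf_trees, final_seed)
    P = oob_proximity(final, X_final)
    coords, _ = pcoa(1.0 - P, n_components=2)
    feats = tuple(sorted({f for pair in selected_pairs for f in pair}))
    return ModelResult(
        sample_ids=tuple(table.sample_ids),
        patient_ids=tuple(s.patient_id for s in table.samples),
        labels=y,
        probabilities=probs,
        selected_features=feats,
        proximity=ProximityMatrix(P, tuple(table.sample_ids)),
        pcoa_coordinates=coords,
        roc=roc,
    )


def fit_evaluate_features(table: FeatureTable, labels, features,
                          config: SelectionConfig) -> ModelResult:
    """Final model on log intensities of an already-curated feature set.

    Used for the breath platform, which arrives as a curated compound
    panel rather than an untargeted table needing log-ratio treatment.
    Missing entries, if any, are re-imputed per iteration.
    """
    y = np.asarray(labels, dtype=int)
    sub = table.subset_features(list(features))

    def build(seed: int) -> np.ndarray:
        X = impute_missing(sub, seed=seed)
        return np.log(X)

    probs = _iterated_probabilities(build, sub, y, config)
    roc = roc_metrics(probs, y)
    final_seed = int(rng_for(config.seed, "final_model").integers(2**31))
    X_final = build(final_seed)
    final = fit_forest(X_final, y, config.rf_trees, final_seed)
    P = oob_proximity(final, X_final)
    coords, _ = pcoa(1.0 - P, n_components=2)
    return ModelResult(
        sample_ids=tuple(sub.sample_ids),
        patient_ids=tuple(s.patient_id for s in sub.samples),
        labels=y, probabilities=probs, selected_features=tuple(features),
        proximity=ProximityMatrix(P, tuple(sub.sample_ids)),
        pcoa_coordinates=coords, roc=roc)


def water_content_model(table: FeatureTable, labels,
                        config: SelectionConfig) -> tuple[ModelResult, np.ndarray]:
    """Forest on fecal water content alone (bias check).

    Returns the model result plus the per-sample scatter of averaged
    probability against |water - cohort mean water| (columns: deviation,
    probability)."""
    y = np.asarray(labels, dtype=int)
    missing = [s.sample_id for s in table.samples
               if s.role is Role.BIOLOGICAL and s.water_content is None]
    if missing:
        raise ValueError(f"samples without water content: {missing}")
    water = np.asarray([s.water_content for s in table.samples], dtype=float)
    if np.ptp(water) == 0:
        raise ValueError("no variation: water content is constant")
    X_water = water[:, None]
    probs = _iterated_probabilities(lambda seed: X_water, table, y, config)
    roc = roc_metrics(probs, y)
    final_seed = int(rng_for(config.seed, "final_model").integers(2**31))
    final = fit_forest(X_water, y, config.rf_trees, final_seed)
    P = oob_proximity(final, X_water)
    coords, _ = pcoa(1.0 - P, n_components=2)
    result = ModelResult(
        sample_ids=tuple(table.sample_ids),
        patient_ids=tuple(s.patient_id for s in table.samples),
        labels=y, probabilities=probs, selected_features=("water_content",),
        proximity=ProximityMatrix(P, tuple(table.sample_ids)),
        pcoa_coordinates=coords, roc=roc)
    scatter = np.column_stack([np.abs(water - water.mean()), probs])
    return result, scatter


def proximity_covariate_test(proximity: ProximityMatrix, covariate,
                             n_perm: int, seed: int) -> tuple[float, float]:
    """Permutation pseudo-F of a numeric covariate on 1 - proximity.

    Distance-based redundancy pseudo-F: with G the Gower-centered squared
    distance matrix and H the hat matrix of [1, covariate],
    F = tr(H G H) / 1  ÷  tr((I-H) G (I-H)) / (n - 2).
    The null distribution is obtained by permuting the covariate;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful p-value")
    z = np.asarray(covariate, dtype=float)
    n = z.shape[0]
    if proximity.values.shape[0] != n:
        raise ValueError("covariate length must match proximity size")
    D = 1.0 - proximity.values
    G = gower_center(D)

    def pseudo_f(zv: np.ndarray) -> float:
        X = np.column_stack([np.ones(n), zv])
        H = X @ np.linalg.pinv(X)
        R = np.eye(n) - H
        num = float(np.trace(H @ G @ H))
        den = float(np.trace(R @ G @ R))
        if den <= 0:
            return np.inf
        return (num / 1.0) / (den / (n - 2))

    f_obs = pseudo_f(z)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(z[rng.permutation(n)]) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return f_obs, p


def stratified_auc(result: ModelResult, severity, fractions) -> dict[tuple[float, float], float]:
    """AUC restricted to positive samples inside severity-quantile bands.

    ``severity`` aligns with the result's samples (values required for
    positives); ``fractions`` is a list of (lo, hi] quantile bands over the
    positive-class severity distribution.  Each band's AUC uses the band's
    positives against all negatives."""
    y = result.labels
    p = result.probabilities
    sev = np.asarray(severity, dtype=float)
    pos = y == 1
    if np.any(np.isnan(sev[pos])):
        raise ValueError("severity scores required for all positive samples")
    sev_pos = sev[pos]
    out: dict[tuple[float, float], float] = {}
    for lo, hi in fractions:
        lo_q = np.quantile(sev_pos, lo)
        hi_q = np.quantile(sev_pos, hi)
        in_band = pos & ((sev > lo_q) if lo > 0 else (sev >= lo_q)) & (sev <= hi_q)
        if not in_band.any():
            raise ValueError(f"empty severity stratum ({lo}, {hi}]")
        mask = in_band | (y == 0)
        out[(lo, hi)] = roc_metrics(p[mask], y[mask]).auc
    return out
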