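"""Pairwise log-ratio expansion and shadow-feature stability selection.

Per-sample multiplicative dilution cancels inside a within-sample ratio of
two intensities, so classification on pairwise log ratios needs no
normalization.  The price is a p(p-1)/2-column feature space whose columns
must be mapped back to original compounds: that is done by iterated
random-forest importance frequencies thresholded against shadow features
(row-permuted copies of the real columns), accumulated in a square
compound × compound matrix whose column sums rank the original compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from ._rf import fit_forest, permutation_importance_fast
from .core import FeatureTable
from .sampling import duplicate_safe_split
from .simulate import rng_for

__all__ = [
    "SelectionConfig",
    "LogRatioMatrix",
    "ImportanceFrequencyMatrix",
    "SelectionResult",
    "impute_missing",
    "expand_logratios",
    "ratio_columns",
    "make_shadow",
    "importance_frequency",
    "rank_and_optimize",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Stability-selection parameters.

    Defaults are the procedure's published constants: 500 iterations, a
    76/24 train/validation split realized through class-wise patient
    subsampling (83% of the PSC class, 73% of the IBD class per iteration;
    the complement is that iteration's validation set), and an importance
    hit at >= 40% of the iteration's maximum importance.  ``n_iterations``
    and ``rf_trees`` are compute knobs callers scale to their problem size.
    """

    n_iterations: int = 500
    train_fraction: float = 0.76
    importance_threshold_fraction: float = 0.40
    psc_subsample: float = 0.83
    ibd_subsample: float = 0.73
    rf_trees: int = 500
    seed: int = 0
    n_eval_iterations: int = 20
    max_rank_evaluated: int = 20

    def __post_init__(self) -> None:
        for name in ("train_fraction", "importance_threshold_fraction",
                     "psc_subsample", "ibd_subsample"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class LogRatioMatrix:
    values: np.ndarray                       # n_samples × p(p-1)/2
    pair_index: tuple[tuple[str, str], ...]  # (numerator, denominator), i < j
    features: tuple[str, ...]

    @property
    def ratio_names(self) -> list[str]:
        return [f"{a}/{b}" for a, b in self.pair_index]


@dataclass(frozen=True)
class ImportanceFrequencyMatrix:
    """Square compound × compound selection-frequency matrix.

    ``freq[i, j]`` is the across-iteration hit frequency of the ratio
    between compounds i and j after shadow thresholding (entries at or
    below ``shadow_max`` zeroed); the matrix is filled symmetrically since
    tree splits are invariant to the orientation of log(a/b).  The
    diagonal is zero.  ``column_scores`` are column sums of the
    thresholded matrix and define the compound ranking.
    """

    features: tuple[str, ...]
    freq: np.ndarray
    shadow_max: float
    column_scores: np.ndarray
    raw_ratio_freq: np.ndarray = field(repr=False)
    pair_index: tuple[tuple[str, str], ...] = field(repr=False)

    @property
    def surviving_pairs(self) -> list[tuple[str, str]]:
        return [p for p, f in zip(self.pair_index, self.raw_ratio_freq)
                if f > self.shadow_max]


# -- imputation and expansion ------------------------------------------------


def impute_missing(table, seed: int) -> np.ndarray:
    """Replace missing entries by Uniform(0.5 * m_f, m_f) draws, m_f being
    the feature's minimum observed positive value.

    Accepts a :class:`FeatureTable` or a bare matrix; returns a complete,
    strictly positive matrix.  Seeded and reproducible.
    """
    if isinstance(table, FeatureTable):
        X = table.values
        names = table.features
    else:
        X = np.asarray(table, dtype=float)
        names = [f"f{j}" for j in range(X.shape[1])]
    out = X.copy()
    rng = np.random.default_rng(seed)
    for j in range(out.shape[1]):
        col = out[:, j]
        nan = np.isnan(col)
        pos = col[(~nan) & (col > 0)]
        if not nan.any():
            continue
        if pos.size == 0:
            raise ValueError(
                f"feature {names[j]!r} has no observed positive value to impute from"
            )
        m = float(pos.min())
        col[nan] = rng.uniform(0.5 * m, m, size=int(nan.sum()))
    if np.any(out <= 0) or np.any(np.isnan(out)):
        bad = [names[j] for j in np.unique(np.argwhere(~(out > 0))[:, 1])]
        raise ValueError(f"non-positive entries remain after imputation: {bad}")
    return out


def _pairs(p: int) -> np.ndarray:
    i, j = np.triu_indices(p, k=1)
    return np.column_stack([i, j])


def expand_logratios(matrix: np.ndarray, features) -> LogRatioMatrix:
    """All unordered pairwise log ratios, canonical orientation i < j.

    The ratio is computed as log(x_i / x_j) on the raw quotient, so a
    common per-row factor cancels exactly.
    """
    X = np.asarray(matrix, dtype=float)
    if np.any(~(X > 0)):
        raise ValueError("log-ratio expansion requires strictly positive entries")
    features = tuple(features)
    if X.shape[1] != len(features):
        raise ValueError("feature names must match matrix columns")
    idx = _pairs(X.shape[1])
    values = np.log(X[:, idx[:, 0]] / X[:, idx[:, 1]])
    pair_index = tuple((features[i], features[j]) for i, j in idx)
    return LogRatioMatrix(values=values, pair_index=pair_index, features=features)


def ratio_columns(matrix: np.ndarray, features, pairs) -> np.ndarray:
    """Log-ratio columns for a subset of (numerator, denominator) pairs."""
    X = np.asarray(matrix, dtype=float)
    pos = {f: j for j, f in enumerate(features)}
    cols = [np.log(X[:, pos[a]] / X[:, pos[b]]) for a, b in pairs]
    return np.column_stack(cols) if cols else np.empty((X.shape[0], 0))


def make_shadow(matrix: np.ndarray, seed: int) -> np.ndarray:
    """Shadow copy: each column independently row-permuted.

    Column-wise marginals are preserved; any association with labels or
    other columns is destroyed."""
    X = np.asarray(matrix)
    if X.shape[0] < 2:
        raise ValueError("shadow features need >= 2 rows")
    rng = np.random.default_rng(seed)
    return np.column_stack([X[rng.permutation(X.shape[0]), j]
                            for j in range(X.shape[1])])


# -- stability selection -----------------------------------------------------


def _patient_arrays(table: FeatureTable, labels) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != table.n_samples:
        raise ValueError("labels must align with table samples")
    pids = np.asarray([s.patient_id for s in table.samples])
    return pids, y


def patient_permutation_indices(patient_ids, rng: np.random.Generator) -> np.ndarray:
    """Row index map realizing a patient-block permutation.

    Patients are permuted as units and a patient's duplicate rows draw from
    the target patient's rows (cycling when duplicate counts differ), so a
    shadow column built with this map preserves the duplicate structure of
    the real data.  Preserving that structure matters: spurious
    associations of real features with the class label live at the patient
    level (duplicates share biology), and shadows must carry null
    associations of the same magnitude to calibrate the frequency
    threshold.
    """
    pids = np.asarray(patient_ids)
    pats = list(dict.fromkeys(pids.tolist()))
    rows = {p: np.flatnonzero(pids == p) for p in pats}
    sigma = rng.permutation(len(pats))
    out = np.empty(len(pids), dtype=int)
    for k, p in enumerate(pats):
        src = rows[pats[sigma[k]]]
        for i, r in enumerate(rows[p]):
            out[r] = src[i % len(src)]
    return out


def importance_frequency(table: FeatureTable, labels,
                         config: SelectionConfig) -> ImportanceFrequencyMatrix:
    """Iterated shadow-thresholded importance frequencies of all log ratios.

    Per iteration: subsample patients class-wise (duplicates follow their
    patient; only one randomly chosen duplicate per patient enters the
    importance model, to decorrelate trees), impute missing values, expand
    log ratios, append shadow features, fit a forest, and score a "hit"
    for every column whose permutation importance on the iteration's
    held-out patients reaches the threshold fraction of that iteration's
    maximum importance.  Frequencies at or below the maximum shadow
    frequency are zeroed.

    The shadow permutation is drawn once per run (not refreshed per
    iteration) and permutes patient blocks: iterations share most of the
    cohort, so a null feature's spurious association persists across
    iterations, and only a frozen, duplicate-structure-preserving shadow
    carries the same persistence — a per-iteration reshuffle would
    systematically understate the null frequency ceiling.
    """
    pids, y = _patient_arrays(table, labels)
    for cls in (0, 1):
        if np.unique(pids[y == cls]).size < 2:
            raise ValueError("each class needs >= 2 patients for stability selection")
    p = table.n_features
    features = tuple(table.features)
    idx = _pairs(p)
    n_ratios = idx.shape[0]
    hits_real = np.zeros(n_ratios)
    hits_shadow = np.zeros(n_ratios)
    root = rng_for(config.seed, "importance_frequency")
    shadow_rng = rng_for(config.seed, "shadow_perm")
    perm_idx = np.column_stack(
        [patient_permutation_indices(pids, shadow_rng) for _ in range(n_ratios)])

    for it in range(config.n_iterations):
        it_seed = int(root.integers(2**31))
        rng = np.random.default_rng(it_seed)
        X = impute_missing(table, seed=it_seed)
        ratios = np.log(X[:, idx[:, 0]] / X[:, idx[:, 1]])
        shadow = np.take_along_axis(ratios, perm_idx, axis=0)
        full = np.hstack([ratios, shadow])

        train_idx, test_idx = duplicate_safe_split(
            pids, y, config.psc_subsample, config.ibd_subsample, rng)
        # one duplicate per pooled patient for the importance model
        chosen: list[int] = []
        for pat in np.unique(pids[train_idx]):
            rows = train_idx[pids[train_idx] == pat]
            chosen.append(int(rng.choice(rows)))
        chosen_arr = np.sort(np.asarray(chosen))
        if np.unique(y[chosen_arr]).size < 2 or np.unique(y[test_idx]).size < 2:
            continue  # degenerate draw; skip iteration
        model = fit_forest(full[chosen_arr], y[chosen_arr], config.rf_trees, it_seed)
        imp = permutation_importance_fast(model, full[test_idx], y[test_idx], rng)
        max_imp = imp.max()
        if max_imp <= 0:
            continue
        hit = imp >= config.importance_threshold_fraction * max_imp
        hits_real += hit[:n_ratios]
        hits_shadow += hit[n_ratios:]

    freq_real = hits_real / config.n_iterations
    freq_shadow = hits_shadow / config.n_iterations
    shadow_max = float(freq_shadow.max()) if freq_shadow.size else 0.0
    thresholded = np.where(freq_real > shadow_max, freq_real, 0.0)
    square = np.zeros((p, p))
    square[idx[:, 0], idx[:, 1]] = thresholded
    square[idx[:, 1], idx[:, 0]] = thresholded
    np.fill_diagonal(square, 0.0)
    return ImportanceFrequencyMatrix(
        features=features,
        freq=square,
        shadow_max=shadow_max,
        column_scores=square.sum(axis=0),
        raw_ratio_freq=freq_real,
        pair_index=tuple((features[i], features[j]) for i, j in idx),
    )


@dataclass(frozen=True)
class SelectionResult:
    selected_features: tuple[str, ...]
    selected_pairs: tuple[tuple[str, str], ...]
    k: int
    auc_by_k: tuple[tuple[int, float], ...]


def _eval_pairs_auc(table: FeatureTable, labels, pairs,
                    config: SelectionConfig, seed: int) -> float:
    """Mean internal-validation AUC of a forest on the given ratio columns."""
    pids, y = _patient_arrays(table, labels)
    root = np.random.default_rng(seed)
    prob_sum = np.zeros(table.n_samples)
    prob_cnt = np.zeros(table.n_samples)
    for it in range(config.n_eval_iterations):
        it_seed = int(root.integers(2**31))
        rng = np.random.default_rng(it_seed)
        X = impute_missing(table, seed=it_seed)
        cols = ratio_columns(X, table.features, pairs)
        train_idx, test_idx = duplicate_safe_split(
            pids, y, config.psc_subsample, config.ibd_subsample, rng)
        if np.unique(y[train_idx]).size < 2 or np.unique(y[test_idx]).size < 2:
            continue
        model = fit_forest(cols[train_idx], y[train_idx], config.rf_trees, it_seed)
        prob = model.predict_proba(cols[test_idx])[:, list(model.classes_).index(1)]
        prob_sum[test_idx] += prob
        prob_cnt[test_idx] += 1
    seen = prob_cnt > 0
    if np.unique(y[seen]).size < 2:
        return 0.5
    return float(roc_auc_score(y[seen], prob_sum[seen] / prob_cnt[seen]))


def rank_and_optimize(freq: ImportanceFrequencyMatrix, table: FeatureTable,
                      labels, config: SelectionConfig) -> SelectionResult:
    """Rank compounds by thresholded column sums; pick the top-k whose
    surviving ratios maximize internal-validation AUC (ties → smallest k).
    """
    scores = freq.column_scores
    if not np.any(scores > 0):
        warnings.warn("all importance frequencies zero; empty selection")
        return SelectionResult((), (), 0, ())
    order = np.argsort(-scores, kind="stable")
    ranked = [freq.features[i] for i in order if scores[i] > 0]
    surviving = freq.surviving_pairs
    K = min(len(ranked), config.max_rank_evaluated)
    eval_root = rng_for(config.seed, "rank_and_optimize")
    auc_by_k: list[tuple[int, float]] = []
    best_k, best_auc = 0, -np.inf
    for k in range(1, K + 1):
        top = set(ranked[:k])
        pairs = [p for p in surviving if p[0] in top or p[1] in top]
        if not pairs:
            auc_by_k.append((k, float("nan")))
            continue
        auc = _eval_pairs_auc(table, labels, pairs, config,
                              seed=int(eval_root.integers(2**31)))
        auc_by_k.append((k, auc))
        if auc > best_auc + 1e-12:  # strict improvement → ties keep smallest k
            best_k, best_auc = k, auc
    if best_k == 0:
        warnings.warn("no ratio set achieved a defined validation AUC")
        return SelectionResult((), (), 0, tuple(auc_by_k))
    top = set(ranked[:best_k])
    pairs = tuple(p for p in surviving if p[0] in top or p[1] in top)
    return SelectionResult(tuple(ranked[:best_k]), pairs, best_k, tuple(auc_by_k))
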