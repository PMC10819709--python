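"""Iterated cross-platform correlation: CCA + RFE + permutation screening.

Because the fecal platform needs randomized imputation before its log
ratios exist, correlations between platforms are computed across many
imputation iterations.  Per iteration the platforms are related by the
first canonical variate of a CCA with recursive feature elimination run
until permutation significance; across iterations a chi-square screen
keeps only features selected significantly more often on real than on
row-permuted data; finally first-canonical and univariate Pearson
correlations are averaged on the Fisher-z scale and the frequency of
significance is reported.  The same machinery correlates either platform
with the four blood liver markers within the PSC-class population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FeatureTable, BLOOD_MARKERS
from .logratios import impute_missing, ratio_columns
from .simulate import rng_for

__all__ = [
    "CorrelationConfig",
    "CorrelationResult",
    "PlatformView",
    "cca_first_variate",
    "rfe_to_significance",
    "permutation_screen",
    "averaged_correlations",
    "blood_association",
    "fisher_z_mean",
]


@dataclass(frozen=True)
class CorrelationConfig:
    n_iterations: int = 5000
    alpha: float = 0.05
    n_permutations: int = 199
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_permutations < int(np.ceil(1.0 / self.alpha)) - 1:
            raise ValueError(
                "n_permutations too small to resolve p-values at alpha")


@dataclass(frozen=True)
class PlatformView:
    """One platform's data as it enters the correlation machinery.

    ``matrix`` may contain missing entries (imputed per iteration).  When
    ``ratio_pairs`` is given, the matrix is the raw positive intensity
    table and each iteration realizes the listed log-ratio columns — the
    form in which selected fecal features enter, making the procedure
    invariant to per-sample multiplicative scaling of the raw rows.
    """

    matrix: np.ndarray
    feature_names: tuple[str, ...]
    ratio_pairs: tuple[tuple[str, str], ...] | None = None

    @property
    def column_names(self) -> tuple[str, ...]:
        if self.ratio_pairs is not None:
            return tuple(f"{a}/{b}" for a, b in self.ratio_pairs)
        return self.feature_names

    def realize(self, seed: int) -> np.ndarray:
        X = self.matrix
        if np.isnan(X).any():
            X = impute_missing(X, seed=seed)
        if self.ratio_pairs is not None:
            return ratio_columns(X, self.feature_names, self.ratio_pairs)
        return np.asarray(X, dtype=float)

    def subset(self, names) -> "PlatformView":
        names = list(names)
        if self.ratio_pairs is not None:
            keep = tuple(p for p in self.ratio_pairs if f"{p[0]}/{p[1]}" in set(names))
            return PlatformView(self.matrix, self.feature_names, keep)
        pos = {f: j for j, f in enumerate(self.feature_names)}
        cols = [pos[n] for n in names]
        return PlatformView(self.matrix[:, cols], tuple(names), None)


# -- canonical correlation ---------------------------------------------------


def _standardize(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column; cannot standardize for CCA")
    return (M - mu) / sd


def _inv_sqrt(S: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    w = np.maximum(w, eps)
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def _cca_r1(Xs: np.ndarray, Ys: np.ndarray, ridge: float = 0.0):
    n = Xs.shape[0]
    Sxx = Xs.T @ Xs / (n - 1) + ridge * np.eye(Xs.shape[1])
    Syy = Ys.T @ Ys / (n - 1) + ridge * np.eye(Ys.shape[1])
    Sxy = Xs.T @ Ys / (n - 1)
    Wx = _inv_sqrt(Sxx)
    Wy = _inv_sqrt(Syy)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    r1 = float(min(s[0], 1.0)) if s.size else 0.0
    wx = Wx @ U[:, 0]
    wy = Wy @ Vt[0]
    return r1, wx, wy


def cca_first_variate(X: np.ndarray, Y: np.ndarray, n_permutations: int = 199,
                      seed: int = 0) -> tuple[float, np.ndarray, np.ndarray, float]:
    """First canonical correlation with a permutation p-value.

    Returns (r1, loadings_x, loadings_y, p).  Loadings are structure
    correlations (correlation of each standardized column with its side's
    canonical score).  Near-singular covariance triggers a warned
    ridge-regularized fallback.  The p-value permutes the row order of Y:
    p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n = X.shape[0]
    if n <= max(X.shape[1], Y.shape[1]) + 2:
        raise ValueError(
            f"need n > max(p, q) + 2 samples for CCA (n={n}, p={X.shape[1]}, q={Y.shape[1]})")
    Xs, Ys = _standardize(X), _standardize(Y)
    ridge = 0.0
    for M in (Xs, Ys):
        S = M.T @ M / (n - 1)
        if np.linalg.eigvalsh((S + S.T) / 2).min() < 1e-10:
            ridge = 1e-6
    if ridge:
        warnings.warn("rank-deficient covariance; using ridge-regularized CCA")
    r1, wx, wy = _cca_r1(Xs, Ys, ridge)
    xs = Xs @ wx
    ys = Ys @ wy
    lx = np.array([np.corrcoef(Xs[:, j], xs)[0, 1] for j in range(Xs.shape[1])])
    ly = np.array([np.corrcoef(Ys[:, j], ys)[0, 1] for j in range(Ys.shape[1])])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        rp, _, _ = _cca_r1(Xs, Ys[rng.permutation(n)], ridge)
        if rp >= r1:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return r1, lx, ly, p


def rfe_to_significance(X: np.ndarray, Y: np.ndarray, config: CorrelationConfig,
                        x_names=None, y_names=None, seed: int | None = None
                        ) -> tuple[list, list, float, float, bool]:
    """Recursive feature elimination until permutation significance.

    Repeatedly drops the feature (from either platform) with the smallest
    absolute structure loading, stopping when p <= alpha or when both
    sides are down to 2 features.  Returns (selected_x, selected_y, r1, p,
    significant)."""
    X = np.atleast_2d(np.asarray(X, float)).copy()
    Y = np.atleast_2d(np.asarray(Y, float)).copy()
    x_names = list(x_names) if x_names is not None else [f"x{j}" for j in range(X.shape[1])]
    y_names = list(y_names) if y_names is not None else [f"y{j}" for j in range(Y.shape[1])]
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    while True:
        r1, lx, ly, p = cca_first_variate(
            X, Y, n_permutations=config.n_permutations, seed=int(rng.integers(2**31)))
        if p <= config.alpha:
            return x_names, y_names, r1, p, True
        can_x = X.shape[1] > 2
        can_y = Y.shape[1] > 2
        if not (can_x or can_y):
            return x_names, y_names, r1, p, False
        cand = []
        if can_x:
            j = int(np.argmin(np.abs(lx)))
            cand.append((abs(lx[j]), "x", j))
        if can_y:
            j = int(np.argmin(np.abs(ly)))
            cand.append((abs(ly[j]), "y", j))
        _, side, j = min(cand)
        if side == "x":
            X = np.delete(X, j, axis=1)
            del x_names[j]
        else:
            Y = np.delete(Y, j, axis=1)
            del y_names[j]


# -- screening and averaging -------------------------------------------------


@dataclass(frozen=True)
class ScreenResult:
    selected_x: tuple[str, ...]
    selected_y: tuple[str, ...]
    counts: pd.DataFrame = field(repr=False)


def permutation_screen(x_view: PlatformView, y_view: PlatformView,
                       config: CorrelationConfig) -> ScreenResult:
    """Chi-square screen of RFE selection counts, real vs. permuted.

    Across ``n_iterations`` imputations, features are counted as selected
    by :func:`rfe_to_significance` on the real pairing and on a pairing
    with row-permuted Y.  A feature passes when its real count exceeds the
    permuted one and the 2×2 chi-square (Yates-corrected, as selection
    tables are sparse) reaches ``alpha``.
    """
    if config.n_iterations < 2:
        raise ValueError("insufficient iterations for screening (need >= 2)")
    xn, yn = list(x_view.column_names), list(y_view.column_names)
    counts = {("real", n): 0 for n in xn + yn}
    counts.update({("perm", n): 0 for n in xn + yn})
    root = rng_for(config.seed, "permutation_screen")
    n_rows = x_view.matrix.shape[0]
    for _ in range(config.n_iterations):
        it_seed = int(root.integers(2**31))
        rng = np.random.default_rng(it_seed)
        X = x_view.realize(it_seed)
        Y = y_view.realize(it_seed + 1)
        sx, sy, _, _, sig = rfe_to_significance(
            X, Y, config, x_names=xn, y_names=yn, seed=it_seed + 2)
        if sig:
            for nme in sx + sy:
                counts[("real", nme)] += 1
        Yp = Y[rng.permutation(n_rows)]
        sx, sy, _, _, sig = rfe_to_significance(
            X, Yp, config, x_names=xn, y_names=yn, seed=it_seed + 3)
        if sig:
            for nme in sx + sy:
                counts[("perm", nme)] += 1
    rows = []
    N = config.n_iterations
    for nme in xn + yn:
        a, b = counts[("real", nme)], counts[("perm", nme)]
        table = np.array([[a, N - a], [b, N - b]])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            pval = 1.0
        else:
            pval = float(stats.chi2_contingency(table, correction=True)[1])
        rows.append({"feature": nme, "real": a, "perm": b, "p": pval,
                     "kept": bool(pval < config.alpha and a > b)})
    frame = pd.DataFrame(rows).set_index("feature")
    kept = set(frame.index[frame["kept"]])
    return ScreenResult(
        selected_x=tuple(n for n in xn if n in kept),
        selected_y=tuple(n for n in yn if n in kept),
        counts=frame,
    )


def fisher_z_mean(r_values) -> float:
    """Average correlations on the Fisher-z scale (atanh → mean → tanh)."""
    r = np.clip(np.asarray(r_values, float), -1 + 1e-15, 1 - 1e-15)
    return float(np.tanh(np.mean(np.arctanh(r))))


def _pearson_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Ys = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    R = Xs.T @ Ys / (n - 1)
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1 - R**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return R, p


@dataclass(frozen=True)
class CorrelationResult:
    selected_x: tuple[str, ...]
    selected_y: tuple[str, ...]
    canonical_r: float
    mean_p: float
    frac_significant: float
    univariate_r: pd.DataFrame
    univariate_p: pd.DataFrame
    univariate_p_adj: pd.DataFrame
    significant: bool


def averaged_correlations(x_view: PlatformView, y_view: PlatformView,
                          screened_x, screened_y,
                          config: CorrelationConfig) -> CorrelationResult:
    """Fisher-z-averaged canonical and univariate correlations.

    Across iterations: first canonical correlation (with permutation p)
    and the univariate Pearson matrix on the screened feature sets;
    r values averaged via Fisher z, p-values averaged arithmetically,
    ``frac_significant`` is the share of iterations with p < alpha.  BH
    adjustment is applied to the averaged univariate p matrix."""
    screened_x, screened_y = list(screened_x), list(screened_y)
    if not screened_x or not screened_y:
        raise ValueError("screened feature sets must be non-empty")
    xv = x_view.subset(screened_x)
    yv = y_view.subset(screened_y)
    root = rng_for(config.seed, "averaged_correlations")
    r1s, ps = [], []
    R_sum_z = np.zeros((len(screened_x), len(screened_y)))
    P_sum = np.zeros_like(R_sum_z)
    for _ in range(config.n_iterations):
        it_seed = int(root.integers(2**31))
        X = xv.realize(it_seed)
        Y = yv.realize(it_seed + 1)
        r1, _, _, p = cca_first_variate(
            X, Y, n_permutations=config.n_permutations, seed=it_seed + 2)
        r1s.append(r1)
        ps.append(p)
        R, Pu = _pearson_matrix(X, Y)
        R_sum_z += np.arctanh(np.clip(R, -1 + 1e-15, 1 - 1e-15))
        P_sum += Pu
    N = config.n_iterations
    canonical_r = fisher_z_mean(r1s)
    mean_p = float(np.mean(ps))
    frac = float(np.mean(np.asarray(ps) < config.alpha))
    R_avg = np.tanh(R_sum_z / N)
    P_avg = P_sum / N
    adj = multipletests(P_avg.ravel(), method="fdr_bh")[1].reshape(P_avg.shape)
    idx, cols = list(screened_x), list(screened_y)
    return CorrelationResult(
        selected_x=tuple(screened_x), selected_y=tuple(screened_y),
        canonical_r=canonical_r, mean_p=mean_p, frac_significant=frac,
        univariate_r=pd.DataFrame(R_avg, index=idx, columns=cols),
        univariate_p=pd.DataFrame(P_avg, index=idx, columns=cols),
        univariate_p_adj=pd.DataFrame(adj, index=idx, columns=cols),
        significant=bool(mean_p <= config.alpha),
    )


def blood_association(platform_view: PlatformView, table: FeatureTable,
                      labels, config: CorrelationConfig) -> CorrelationResult:
    """Correlate a platform with the four blood liver markers, PSC class only.

    Only the positive (PSC-class) population is used: blood parameters are
    expected to vary meaningfully there.  Constant blood columns are
    dropped with a warning; fewer than 6 patients with complete blood data
    is an error."""
    y = np.asarray(labels, int)
    pos = np.flatnonzero(y == 1)
    blood_rows, keep_rows = [], []
    for i in pos:
        s = table.samples[i]
        if all(m in s.blood for m in BLOOD_MARKERS):
            blood_rows.append([s.blood[m] for m in BLOOD_MARKERS])
            keep_rows.append(i)
    if len({table.samples[i].patient_id for i in keep_rows}) < 6:
        raise ValueError("fewer than 6 patients with complete blood data")
    B = np.asarray(blood_rows, float)
    names = list(BLOOD_MARKERS)
    const = [j for j in range(B.shape[1]) if np.ptp(B[:, j]) == 0]
    if const:
        warnings.warn(f"dropping constant blood columns: {[names[j] for j in const]}")
        keep_cols = [j for j in range(B.shape[1]) if j not in const]
        B = B[:, keep_cols]
        names = [names[j] for j in keep_cols]
    xv = PlatformView(platform_view.matrix[keep_rows], platform_view.feature_names,
                      platform_view.ratio_pairs)
    yv = PlatformView(B, tuple(names), None)
    screen = permutation_screen(xv, yv, config)
    # CCA needs a multivariate side: an over-aggressive screen (common at
    # small iteration counts) falls back to the full feature set
    sel_x = screen.selected_x if len(screen.selected_x) >= 2 else xv.column_names
    sel_y = screen.selected_y if len(screen.selected_y) >= 2 else yv.column_names
    return averaged_correlations(xv, yv, sel_x, sel_y, config)
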