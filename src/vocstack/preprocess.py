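"""Blank-based feature retention and the unsupervised random-forest screen.

A feature is considered to truly originate from the fecal headspace when
its median over biological samples strictly exceeds the median over
microchamber blanks plus three times the interquartile range over those
blanks.  Instrument blanks and QC runs are excluded from both sides of the
rule: QC samples only monitor instrument performance, and the retention
rule is defined against the sampling-device background.

The unsupervised screen contrasts the real table against a column-wise
permuted copy (Breiman-style synthetic class), yielding proximities,
a principal-coordinate embedding and a silhouette of the sample roles —
the standard check that biological samples separate from blanks and that
no unwanted batch structure dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.metrics import silhouette_samples

from ._rf import fit_forest, oob_proximity, pcoa
from .core import FeatureTable, Role

__all__ = ["BlankFilterRecord", "BlankFilterResult", "blank_filter", "unsupervised_rf_screen"]

ALL_MISSING = "all-missing"


@dataclass(frozen=True)
class BlankFilterRecord:
    sample_median: float
    blank_median: float
    blank_iqr: float
    threshold: float
    kept: bool
    reason: str = ""


@dataclass(frozen=True)
class BlankFilterResult:
    retained: list[str]
    per_feature: Mapping[str, BlankFilterRecord]

    def report_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "feature": f,
                    "sample_median": r.sample_median,
                    "blank_median": r.blank_median,
                    "blank_iqr": r.blank_iqr,
                    "threshold": r.threshold,
                    "kept": r.kept,
                    "reason": r.reason,
                }
                for f, r in self.per_feature.items()
            ]
        )


def _nan_median(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(np.median(x)) if x.size else float("nan")


def _nan_iqr(x: np.ndarray) -> float:
    """Q3 - Q1 with linear-interpolation quantiles (missing excluded)."""
    x = x[~np.isnan(x)]
    if x.size == 0:
        return float("nan")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    return float(q3 - q1)


def blank_filter(table: FeatureTable) -> BlankFilterResult:
    """Retain features whose biological median strictly exceeds the
    microchamber-blank median plus 3 × blank IQR.

    Missing entries are excluded from every order statistic.  A feature
    missing in all biological samples is dropped with reason
    ``"all-missing"``.
    """
    bio = table.role_mask(Role.BIOLOGICAL)
    mc = table.role_mask(Role.MC_BLANK)
    if bio.sum() < 1:
        raise ValueError("blank_filter requires at least one biological sample")
    if mc.sum() < 2:
        raise ValueError(
            f"blank_filter requires >= 2 microchamber blanks, found {int(mc.sum())}"
        )
    retained: list[str] = []
    per_feature: dict[str, BlankFilterRecord] = {}
    for j, feat in enumerate(table.features):
        bio_vals = table.values[bio, j]
        blank_vals = table.values[mc, j]
        s_med = _nan_median(bio_vals)
        b_med = _nan_median(blank_vals)
        b_iqr = _nan_iqr(blank_vals)
        threshold = b_med + 3.0 * b_iqr
        if np.isnan(s_med):
            per_feature[feat] = BlankFilterRecord(s_med, b_med, b_iqr, threshold,
                                                  kept=False, reason=ALL_MISSING)
            continue
        kept = bool(s_med > threshold)  # strict inequality
        per_feature[feat] = BlankFilterRecord(s_med, b_med, b_iqr, threshold, kept)
        if kept:
            retained.append(feat)
    return BlankFilterResult(retained=retained, per_feature=per_feature)


@dataclass(frozen=True)
class ScreenResult:
    proximity: np.ndarray
    sample_ids: list[str]
    coordinates: np.ndarray  # n × 2
    eigenvalues: np.ndarray
    silhouette_roles: float
    roles: list[str]


def unsupervised_rf_screen(table: FeatureTable, seed: int,
                           n_trees: int = 500) -> ScreenResult:
    """Unsupervised random forest: real rows vs column-permuted copies.

    Missing entries are filled with half the feature minimum (a
    detection-limit convention; the screen is exploratory and trees only
    see within-feature order).  Returns OOB proximities among the real
    samples, a 2-D principal-coordinate embedding of 1 - proximity and the
    silhouette separating biological samples from blanks/QC.
    """
    if table.n_samples < 3:
        raise ValueError("unsupervised screen requires >= 3 samples")
    X = table.values.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        nan = np.isnan(col)
        if nan.all():
            raise ValueError(f"feature {table.features[j]!r} entirely missing")
        if nan.any():
            col[nan] = 0.5 * np.nanmin(col)
    if np.all(X == X[0]):
        raise ValueError("no variation: constant matrix")
    rng = np.random.default_rng(seed)
    X_perm = np.column_stack([X[rng.permutation(X.shape[0]), j]
                              for j in range(X.shape[1])])
    Xc = np.vstack([X, X_perm])
    y = np.r_[np.ones(X.shape[0], int), np.zeros(X.shape[0], int)]
    model = fit_forest(Xc, y, n_trees, seed)
    P = oob_proximity(model, Xc)[: X.shape[0], : X.shape[0]]
    np.fill_diagonal(P, 1.0)
    D = 1.0 - P
    coords, eigvals = pcoa(D, n_components=2)
    roles = [s.role.value for s in table.samples]
    is_bio = np.array([r == Role.BIOLOGICAL.value for r in roles])
    is_blank = np.array([r in (Role.MC_BLANK.value, Role.INSTRUMENT_BLANK.value)
                         for r in roles])
    # Blank-side silhouette of the biological-vs-blank partition (QC
    # excluded): biological profiles are legitimately heterogeneous (strong
    # per-sample dilution), so the overall mean silhouette is dominated by
    # within-class spread; whether *blanks* sit in their own tight cluster
    # away from the samples is the actual screening question.
    sil = float("nan")
    if is_bio.any() and is_blank.any():
        sub = np.flatnonzero(is_bio | is_blank)
        widths = silhouette_samples(D[np.ix_(sub, sub)],
                                    is_bio[sub].astype(int), metric="precomputed")
        sil = float(widths[is_blank[sub]].mean())
    return ScreenResult(
        proximity=P,
        sample_ids=table.sample_ids,
        coordinates=coords,
        eigenvalues=eigvals,
        silhouette_roles=sil,
        roles=roles,
    )
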