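"""Duplicate-aware, class-wise patient subsampling.

Duplicate aliquots of one patient must never straddle a train/test
boundary: sampling is done at the patient level and all of a patient's
samples follow the patient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["duplicate_safe_split"]


def duplicate_safe_split(
    patient_ids: np.ndarray,
    labels: np.ndarray,
    pos_fraction: float,
    neg_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into (train, test) by sampling patients.

    ``pos_fraction`` of positive-class patients and ``neg_fraction`` of
    negative-class patients go to the training side (rounded; clipped so
    both sides keep at least one patient per class when possible).
    Returns sample index arrays.
    """
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels)
    if patient_ids.shape != labels.shape:
        raise ValueError("patient_ids and labels must align")
    train_patients: list = []
    for cls, frac in ((1, pos_fraction), (0, neg_fraction)):
        pats = np.unique(patient_ids[labels == cls])
        if pats.size == 0:
            continue
        n_take = int(round(frac * pats.size))
        if pats.size >= 2:
            n_take = min(max(n_take, 1), pats.size - 1)
        else:
            n_take = min(n_take, pats.size)
        train_patients.extend(rng.choice(pats, size=n_take, replace=False).tolist())
    train_set = set(train_patients)
    in_train = np.array([p in train_set for p in patient_ids])
    return np.flatnonzero(in_train), np.flatnonzero(~in_train)
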