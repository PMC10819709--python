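"""Core data model for two-platform VOC studies.

Feature tables are sample × compound intensity matrices (missing entries
allowed, encoded as empty cells on disk — zero is a meaningful intensity and
is never conflated with "not detected").  Sample metadata carries the cohort
structure the downstream statistics depend on: patient identity, duplicate
index, clinical group (PSC / PSC with IBD / IBD), sample role (biological
vs. the several kinds of blank), fecal water content, blood liver markers
and an optional precomputed severity score.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Role",
    "VOCPanel",
    "SampleMeta",
    "FeatureTable",
    "BinaryLabeling",
    "CohortDesign",
    "GroupDesign",
    "fecal_panel",
    "breath_panel",
    "packaged_cohort_design",
    "merge_psc_groups",
    "read_feature_table",
    "write_feature_table",
]

BLOOD_MARKERS = ("ALP", "AST", "ALT", "bilirubin")


class Group(str, enum.Enum):
    """Clinical group of a biological sample."""

    PSC = "PSC"
    PSC_IBD = "PSC_IBD"
    IBD = "IBD"


class Role(str, enum.Enum):
    """Measurement role: biological sample, blank, or quality control."""

    BIOLOGICAL = "biological"
    MC_BLANK = "mc_blank"
    INSTRUMENT_BLANK = "instrument_blank"
    QC = "qc"


@dataclass(frozen=True)
class VOCPanel:
    """An ordered, named list of compound identities."""

    name: str
    compounds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.compounds)) != len(self.compounds):
            dupes = sorted({c for c in self.compounds if list(self.compounds).count(c) > 1})
            raise ValueError(f"panel {self.name!r} has duplicate compounds: {dupes}")
        if any((not isinstance(c, str)) or not c for c in self.compounds):
            raise ValueError(f"panel {self.name!r} contains empty compound names")

    def __len__(self) -> int:
        return len(self.compounds)


def _load_panel(resource: str, name: str) -> VOCPanel:
    text = importlib.resources.files("vocstack.data").joinpath(resource).read_text()
    compounds = tuple(line.strip().lower() for line in text.splitlines() if line.strip())
    return VOCPanel(name=name, compounds=compounds)


def fecal_panel() -> VOCPanel:
    """The 62-compound targeted fecal-headspace panel.

    Stored verbatim (lower-cased, punctuation preserved) including the
    near-synonym pair "methyl formate" / "formic acid methyl ester": the
    printed panel is the contract, identities are not resolved here.
    """
    return _load_panel("fecal_panel.txt", "fecal_targeted")


def breath_panel() -> VOCPanel:
    """The 20-compound curated exhaled-breath panel."""
    return _load_panel("breath_panel.txt", "breath")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    ``duplicate_index`` is 1-based; two fecal aliquots of one patient share
    ``patient_id`` and differ in ``duplicate_index``.  Blood markers are a
    mapping over :data:`BLOOD_MARKERS`; absent markers are simply missing
    keys.
    """

    sample_id: str
    patient_id: str
    role: Role = Role.BIOLOGICAL
    group: Group | None = None
    duplicate_index: int = 1
    water_content: float | None = None
    blood: Mapping[str, float] = field(default_factory=dict)
    severity_score: float | None = None

    def __post_init__(self) -> None:
        if self.role is Role.BIOLOGICAL and self.group is None:
            raise ValueError(f"biological sample {self.sample_id!r} has no group")
        if self.role is not Role.BIOLOGICAL and self.group is not None:
            raise ValueError(
                f"{self.role.value} sample {self.sample_id!r} must not carry a group"
            )
        if self.duplicate_index < 1:
            raise ValueError("duplicate_index must be >= 1")
        if self.water_content is not None and not (0.0 <= self.water_content <= 100.0):
            raise ValueError(
                f"water_content of {self.sample_id!r} outside [0, 100]: {self.water_content}"
            )
        for k, v in self.blood.items():
            if k not in BLOOD_MARKERS:
                raise ValueError(f"unknown blood marker {k!r}")
            if v < 0:
                raise ValueError(f"negative blood marker {k}={v} on {self.sample_id!r}")


class FeatureTable:
    """Sample × feature intensity matrix with aligned metadata.

    ``values`` is float with NaN marking missing entries; present entries
    must be non-negative.
    """

    def __init__(
        self,
        values: np.ndarray,
        samples: Sequence[SampleMeta],
        features: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if values.shape[0] != len(samples):
            raise ValueError(
                f"{values.shape[0]} rows but {len(samples)} sample metadata records"
            )
        if values.shape[1] != len(features):
            raise ValueError(
                f"{values.shape[1]} columns but {len(features)} feature names"
            )
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values are not unique")
        if len(set(features)) != len(features):
            raise ValueError("feature names are not unique")
        present = values[~np.isnan(values)]
        if present.size and present.min() < 0:
            raise ValueError("negative intensities are not allowed")
        self.values = values
        self.samples = list(samples)
        self.features = list(features)

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def role_mask(self, role: Role) -> np.ndarray:
        return np.array([s.role is role for s in self.samples], dtype=bool)

    def subset_samples(self, mask_or_idx) -> "FeatureTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureTable(
            self.values[idx], [self.samples[i] for i in idx], list(self.features)
        )

    def subset_features(self, names: Iterable[str]) -> "FeatureTable":
        names = list(names)
        pos = {f: j for j, f in enumerate(self.features)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        cols = [pos[n] for n in names]
        return FeatureTable(self.values[:, cols], list(self.samples), names)

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if self.features != other.features:
            raise ValueError("feature lists differ; cannot concatenate")
        return FeatureTable(
            np.vstack([self.values, other.values]),
            self.samples + other.samples,
            list(self.features),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.features)

    def meta_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "role": s.role.value,
                "group": s.group.value if s.group is not None else "",
                "duplicate_index": s.duplicate_index,
                "water_content": s.water_content,
                "severity_score": s.severity_score,
            }
            for m in BLOOD_MARKERS:
                row[m] = s.blood.get(m)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class BinaryLabeling:
    """PSC-vs-IBD labeling after merging PSC and PSC/IBD into one class."""

    labels: tuple[int, ...]  # aligned with sample order, 1 = PSC class
    sample_ids: tuple[str, ...]
    n_positive_patients: int
    n_negative_patients: int

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)


def merge_psc_groups(samples: Sequence[SampleMeta]) -> BinaryLabeling:
    """Merge PSC and PSC/IBD into the positive class; IBD is negative.

    Returns per-sample binary labels and unique-patient counts per class.
    Only biological samples may be passed.
    """
    labels: list[int] = []
    pos_patients: set[str] = set()
    neg_patients: set[str] = set()
    for s in samples:
        if s.role is not Role.BIOLOGICAL:
            raise ValueError(f"non-biological sample {s.sample_id!r} in labeling")
        if s.group is None:
            raise ValueError(f"unlabeled biological sample {s.sample_id!r}")
        if s.group in (Group.PSC, Group.PSC_IBD):
            labels.append(1)
            pos_patients.add(s.patient_id)
        else:
            labels.append(0)
            neg_patients.add(s.patient_id)
    return BinaryLabeling(
        labels=tuple(labels),
        sample_ids=tuple(s.sample_id for s in samples),
        n_positive_patients=len(pos_patients),
        n_negative_patients=len(neg_patients),
    )


@dataclass(frozen=True)
class GroupDesign:
    """Per-group cohort bookkeeping: unique patients, duplicate-expanded
    fecal sample count, breath participants, mean fecal water content."""

    n_patients_fecal: int
    n_samples_fecal: int
    n_patients_breath: int
    water_mean: float


@dataclass(frozen=True)
class CohortDesign:
    groups: Mapping[Group, GroupDesign]

    @property
    def n_fecal_patients(self) -> int:
        return sum(g.n_patients_fecal for g in self.groups.values())

    @property
    def n_breath_patients(self) -> int:
        return sum(g.n_patients_breath for g in self.groups.values())

    @property
    def n_positive_patients(self) -> int:
        return (
            self.groups[Group.PSC].n_patients_fecal
            + self.groups[Group.PSC_IBD].n_patients_fecal
        )

    @property
    def n_positive_samples(self) -> int:
        return (
            self.groups[Group.PSC].n_samples_fecal
            + self.groups[Group.PSC_IBD].n_samples_fecal
        )

    @property
    def n_negative_samples(self) -> int:
        return self.groups[Group.IBD].n_samples_fecal


def packaged_cohort_design() -> CohortDesign:
    """The study's cohort design.

    Fecal platform: PSC 8 patients / 16 duplicate-expanded samples,
    PSC/IBD 16 / 31, IBD 49 / 93.  Breath platform (one sample per
    participant): 16 / 47 / 53.  Water-content means per group are the
    cohort table values (percent).
    """
    return CohortDesign(
        groups={
            Group.PSC: GroupDesign(8, 16, 16, 74.02),
            Group.PSC_IBD: GroupDesign(16, 31, 47, 80.33),
            Group.IBD: GroupDesign(49, 93, 53, 73.79),
        }
    )


# -- delimited-text I/O ------------------------------------------------------


def _meta_from_row(row: pd.Series) -> SampleMeta:
    def _opt(x):
        return None if pd.isna(x) or x == "" else float(x)

    def _str(key, default=""):
        val = row.get(key, default)
        return default if pd.isna(val) else str(val).strip()

    group = _str("group")
    blood = {m: float(row[m]) for m in BLOOD_MARKERS if m in row and pd.notna(row[m])}
    dup = row.get("duplicate_index", 1)
    return SampleMeta(
        sample_id=str(row["sample_id"]),
        patient_id=str(row["patient_id"]),
        role=Role(_str("role", "biological") or "biological"),
        group=Group(group) if group else None,
        duplicate_index=1 if pd.isna(dup) else int(dup),
        water_content=_opt(row.get("water_content")),
        blood=blood,
        severity_score=_opt(row.get("severity_score")),
    )


def read_feature_table(path, meta_path) -> FeatureTable:
    """Read a CSV intensity table plus its metadata CSV.

    The table has a ``sample_id`` index column and one column per compound;
    empty cells mean "missing", not zero.  The metadata file is keyed by
    ``sample_id`` and must cover every row of the table exactly.
    """
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    meta = pd.read_csv(meta_path, dtype={"sample_id": str, "patient_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError(f"metadata file {meta_path} lacks a sample_id column")
    meta = meta.set_index("sample_id", drop=False)
    missing_meta = [sid for sid in frame.index if sid not in meta.index]
    extra_meta = [sid for sid in meta.index if sid not in frame.index]
    if missing_meta or extra_meta:
        raise ValueError(
            "sample IDs disagree between table and metadata; "
            f"missing from metadata: {missing_meta}; missing from table: {extra_meta}"
        )
    samples = [_meta_from_row(meta.loc[sid]) for sid in frame.index]
    return FeatureTable(frame.to_numpy(dtype=float), samples, [str(c) for c in frame.columns])


def write_feature_table(table: FeatureTable, path, meta_path) -> None:
    """Write a FeatureTable as a pair of CSVs (missing entries → empty cells).

    ``read_feature_table`` of the written pair reproduces the table up to
    float formatting (values are written with full repr precision, so the
    round trip is exact)."""
    frame = table.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, float_format="%.17g")
    table.meta_frame().to_csv(meta_path, index=False, float_format="%.17g")
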