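"""Synthetic two-platform VOC cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
three-group cohort (PSC, PSC/IBD, IBD) measured on a fecal-headspace
platform (duplicate aliquots per patient, microchamber/instrument blanks,
QC runs, strong per-sample dilution effects, detection-limit-like
missingness) and an exhaled-breath platform (one curated sample per
patient, complete), with planted discriminatory compounds shared at the
patient level and blood liver markers linearly linked to a subset of the
breath markers.

Intensities are log-normal: GC-MS peak areas are positive and right-skewed,
and the analysis operates on log ratios.  Missingness is biased toward
low-intensity cells (censoring-like), the standard mechanism in
volatolomics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import FeatureTable, Group, Role, SampleMeta, BLOOD_MARKERS

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_cohort", "generate_blanks", "rng_for"]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Named substream of a root seed (stable across runs and platforms)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Patient counts and water-content means default to the study design
    (8 / 16 / 49 patients; group water means 74.02 / 80.33 / 73.79 %).
    ``effect_size`` is the mean between-class difference of planted markers
    on the natural-log intensity scale; ``dilution_sd`` the SD of the
    per-sample multiplicative log-scale factor.
    """

    seed: int = 0
    n_psc: int = 8
    n_psc_ibd: int = 16
    n_ibd: int = 49
    duplicate_rate: float = 0.9
    n_features_fecal: int = 24
    n_features_breath: int = 20
    n_markers: int = 5
    effect_size: float = 2.0
    dilution_sd: float = 1.0
    missing_rate: float = 0.10
    n_mc_blanks: int = 8
    n_instrument_blanks: int = 4
    n_qc: int = 3
    blank_leak: float = 0.15
    water_mean_by_group: tuple[float, float, float] = (74.02, 80.33, 73.79)
    water_sd: float = 6.0
    blood_link_strength: float = 0.9
    bio_sd: float = 1.0          # patient-level biological log-SD
    meas_sd: float = 0.3         # duplicate-level measurement log-SD

    def __post_init__(self) -> None:
        for name in ("n_psc", "n_psc_ibd", "n_ibd", "n_features_fecal",
                     "n_features_breath", "n_markers", "n_mc_blanks",
                     "n_instrument_blanks", "n_qc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("duplicate_rate", "missing_rate", "blank_leak"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dilution_sd < 0:
            raise ValueError("dilution_sd must be >= 0")
        if self.n_markers > min(self.n_features_fecal, self.n_features_breath):
            raise ValueError("n_markers exceeds the platform feature count")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    fecal_markers: tuple[str, ...]
    breath_markers: tuple[str, ...]
    fecal_marker_idx: tuple[int, ...]
    breath_marker_idx: tuple[int, ...]
    fecal_effects: tuple[float, ...]
    breath_effects: tuple[float, ...]
    blood_linked_breath: tuple[str, ...]
    leak_features: tuple[str, ...]
    patient_class: dict = field(default_factory=dict)  # patient_id -> 0/1


# -- deterministic per-config structural draws (shared by cohort and blanks) --


def _fecal_feature_names(config: SimulationConfig) -> list[str]:
    return [f"voc{j:03d}" for j in range(config.n_features_fecal)]


def _breath_feature_names(config: SimulationConfig) -> list[str]:
    return [f"breath{j:03d}" for j in range(config.n_features_breath)]


def _baselines(config: SimulationConfig, platform: str, p: int) -> np.ndarray:
    return rng_for(config.seed, f"{platform}_baselines").normal(2.0, 0.8, size=p)


def _marker_idx(config: SimulationConfig, platform: str, p: int) -> np.ndarray:
    rng = rng_for(config.seed, f"{platform}_markers")
    return np.sort(rng.choice(p, size=config.n_markers, replace=False))


def _leak_idx(config: SimulationConfig) -> np.ndarray:
    """Features also present in blanks at sample-comparable level.

    Drawn from the non-marker set so the blank filter never removes a
    planted discriminatory compound."""
    p = config.n_features_fecal
    markers = set(_marker_idx(config, "fecal", p).tolist())
    pool = np.array([j for j in range(p) if j not in markers])
    n_leak = int(round(config.blank_leak * p))
    n_leak = min(n_leak, pool.size)
    rng = rng_for(config.seed, "fecal_leak")
    return np.sort(rng.choice(pool, size=n_leak, replace=False)) if n_leak else np.array([], int)


def _marker_effects(config: SimulationConfig, platform: str) -> np.ndarray:
    rng = rng_for(config.seed, f"{platform}_effects")
    if config.effect_size == 0:
        return np.zeros(config.n_markers)
    return rng.normal(config.effect_size, abs(config.effect_size) / 4, size=config.n_markers)


# -- cohort generation -------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    bad = (x < lo) | (x > hi)
    while bad.any():  # pragma: no branch - converges in a few passes
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def _inject_missing(values: np.ndarray, rate: float, rng) -> np.ndarray:
    """Set entries to NaN preferentially in low-intensity cells.

    Per feature, the missingness probability decreases linearly with the
    within-feature intensity rank (mean = ``rate``); at least one entry per
    feature is always kept."""
    if rate <= 0:
        return values
    out = values.copy()
    n = out.shape[0]
    for j in range(out.shape[1]):
        ranks = np.argsort(np.argsort(out[:, j]))  # 0 = smallest
        prob = np.clip(2.0 * rate * (1.0 - (ranks + 0.5) / n), 0.0, 1.0)
        drop = rng.random(n) < prob
        if drop.all():
            drop[np.argmax(out[:, j])] = False
        out[drop, j] = np.nan
    return out


def generate_blanks(config: SimulationConfig, fecal_features: list[str]) -> FeatureTable:
    """Microchamber and instrument blank samples for the fecal platform.

    Non-leak features sit near zero intensity in blanks; the ``blank_leak``
    fraction is drawn at sample-comparable level so the downstream blank
    filter removes exactly those.  Microchamber and instrument blank
    distributions overlap (instrument blanks are marginally cleaner)."""
    p = len(fecal_features)
    if p != config.n_features_fecal:
        raise ValueError("fecal_features length disagrees with config")
    base = _baselines(config, "fecal", p)
    leak = _leak_idx(config)
    rng = rng_for(config.seed, "blanks")
    rows, meta = [], []
    for kind, n, shift in ((Role.MC_BLANK, config.n_mc_blanks, 0.0),
                           (Role.INSTRUMENT_BLANK, config.n_instrument_blanks, -0.2)):
        for i in range(n):
            log_row = rng.normal(-3.0 + shift, 0.5, size=p)  # background haze
            log_row[leak] = base[leak] + rng.normal(0.3, 0.3, size=leak.size)
            rows.append(np.exp(log_row))
            sid = f"{kind.value}{i:02d}"
            meta.append(SampleMeta(sample_id=sid, patient_id=sid, role=kind))
    if not rows:
        return FeatureTable(np.empty((0, p)), [], list(fecal_features))
    return FeatureTable(np.vstack(rows), meta, list(fecal_features))


def generate_cohort(config: SimulationConfig) -> tuple[FeatureTable, FeatureTable, SyntheticTruth]:
    """Generate (fecal table incl. blanks and QC, breath table, truth).

    Duplicate fecal aliquots share the patient-level biological signal and
    differ only by measurement noise and their own dilution factor; planted
    marker shifts are applied at the patient level, hence consistent across
    duplicates.  The breath table has one complete sample per patient.
    """
    cfg = config
    fecal_features = _fecal_feature_names(cfg)
    breath_features = _breath_feature_names(cfg)
    pf, pb = cfg.n_features_fecal, cfg.n_features_breath

    base_f = _baselines(cfg, "fecal", pf)
    base_b = _baselines(cfg, "breath", pb)
    midx_f = _marker_idx(cfg, "fecal", pf)
    midx_b = _marker_idx(cfg, "breath", pb)
    eff_f = _marker_effects(cfg, "fecal")
    eff_b = _marker_effects(cfg, "breath")
    leak = _leak_idx(cfg)

    rng = rng_for(cfg.seed, "cohort")
    groups = ([Group.PSC] * cfg.n_psc + [Group.PSC_IBD] * cfg.n_psc_ibd
              + [Group.IBD] * cfg.n_ibd)
    water_mean = {Group.PSC: cfg.water_mean_by_group[0],
                  Group.PSC_IBD: cfg.water_mean_by_group[1],
                  Group.IBD: cfg.water_mean_by_group[2]}

    fecal_rows, fecal_meta = [], []
    breath_rows, breath_meta = [], []
    patient_class: dict[str, int] = {}
    n_blood_link = min(4, cfg.n_markers)
    blood_linked = midx_b[:n_blood_link]

    for i, grp in enumerate(groups):
        pid = f"P{i:03d}"
        y = 1 if grp in (Group.PSC, Group.PSC_IBD) else 0
        patient_class[pid] = y
        water = float(_truncated_normal(rng, water_mean[grp], cfg.water_sd, 0, 100, 1)[0])

        # patient-level biology (shared by duplicates)
        lat_f = base_f + rng.normal(0, cfg.bio_sd, size=pf)
        lat_b = base_b + rng.normal(0, cfg.bio_sd, size=pb)
        if y == 1:
            lat_f[midx_f] += eff_f
            lat_b[midx_b] += eff_b

        # blood markers: blood_link_strength-correlated with designated
        # breath markers, elevated in the positive class
        z = (lat_b[blood_linked] - base_b[blood_linked])
        z = z / np.sqrt(cfg.bio_sd**2 + (cfg.effect_size / 4) ** 2) if z.size else z
        rho = cfg.blood_link_strength
        blood = {}
        scales = {"ALP": (90.0, 60.0), "AST": (30.0, 15.0),
                  "ALT": (35.0, 18.0), "bilirubin": (10.0, 5.0)}
        for k, m in enumerate(BLOOD_MARKERS):
            zz = z[k % max(z.size, 1)] if z.size else 0.0
            raw = rho * zz + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal()
            mu, sc = scales[m]
            blood[m] = float(max(1.0, mu + 0.6 * mu * y + sc * raw))
        severity = float(rng.normal(2.0, 0.5)) if y == 1 else None

        # breath: one curated, complete sample per patient
        breath_rows.append(np.exp(lat_b + rng.normal(0, cfg.meas_sd, size=pb)))
        breath_meta.append(SampleMeta(
            sample_id=f"{pid}_B", patient_id=pid, role=Role.BIOLOGICAL, group=grp,
            water_content=None, blood=blood, severity_score=severity))

        # fecal: duplicate aliquots share lat_f, each with its own dilution
        n_dup = 2 if rng.random() < cfg.duplicate_rate else 1
        for d in range(1, n_dup + 1):
            dilution = rng.normal(0, cfg.dilution_sd)
            log_row = lat_f + rng.normal(0, cfg.meas_sd, size=pf) + dilution
            fecal_rows.append(np.exp(log_row))
            fecal_meta.append(SampleMeta(
                sample_id=f"{pid}_F{d}", patient_id=pid, role=Role.BIOLOGICAL,
                group=grp, duplicate_index=d, water_content=water,
                blood=blood, severity_score=severity))

    fecal_values = np.vstack(fecal_rows)
    fecal_values = _inject_missing(fecal_values, cfg.missing_rate, rng_for(cfg.seed, "missing"))
    fecal = FeatureTable(fecal_values, fecal_meta, fecal_features)

    blanks = generate_blanks(cfg, fecal_features)
    if blanks.n_samples:
        fecal = fecal.concat(blanks)
    if cfg.n_qc:
        qc_rng = rng_for(cfg.seed, "qc")
        pooled = np.nanmean(np.log(fecal_values), axis=0)
        qc_rows = [np.exp(pooled + qc_rng.normal(0, 0.1, size=pf)) for _ in range(cfg.n_qc)]
        qc_meta = [SampleMeta(sample_id=f"qc{i:02d}", patient_id=f"qc{i:02d}", role=Role.QC)
                   for i in range(cfg.n_qc)]
        fecal = fecal.concat(FeatureTable(np.vstack(qc_rows), qc_meta, fecal_features))

    breath = FeatureTable(np.vstack(breath_rows), breath_meta, breath_features)
    truth = SyntheticTruth(
        fecal_markers=tuple(fecal_features[j] for j in midx_f),
        breath_markers=tuple(breath_features[j] for j in midx_b),
        fecal_marker_idx=tuple(int(j) for j in midx_f),
        breath_marker_idx=tuple(int(j) for j in midx_b),
        fecal_effects=tuple(float(e) for e in eff_f),
        breath_effects=tuple(float(e) for e in eff_b),
        blood_linked_breath=tuple(breath_features[j] for j in blood_linked),
        leak_features=tuple(fecal_features[j] for j in leak),
        patient_class=patient_class,
    )
    return fecal, breath, truth
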