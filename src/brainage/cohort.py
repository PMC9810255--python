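"""Synthetic case-control cohorts with a planted brain-aging signal.

The generator emulates the tabular inputs of a structural brain-age study:
per-participant demographics/clinical scores and three per-modality feature
tables (subcortical/global volumes, cortical thicknesses, white-matter
fractional anisotropy).  Every participant carries a latent *brain age*:
chronological age for healthy controls, chronological age plus a
duration-of-illness-dependent deviation for patients.  Features load
linearly on that latent age (plus independent Gaussian noise), so a
regressor trained on controls can recover chronological age, and the
planted patient deviations reappear downstream as brain-age gaps.

Feature names are synthetic placeholders; no spatial structure or
between-feature covariance beyond the shared latent age is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MODALITIES",
    "ConfigurationError",
    "SimulationConfig",
    "ParticipantRecord",
    "FeatureTable",
    "default_deviation_profiles",
    "planted_loadings",
    "generate_cohort",
]

#: canonical modality order; also fixes the per-modality random substreams
MODALITIES = ("volume", "thickness", "fa")


class ConfigurationError(ValueError):
    """A :class:`SimulationConfig` field is outside its valid range."""


def default_deviation_profiles() -> dict[str, Callable]:
    """Per-modality patient brain-age deviation as a function of illness duration.

    Returns a mapping ``modality -> f(duration_years) -> deviation_years``.
    The default shapes encode the qualitative trajectory the pipeline is
    designed to detect:

    * ``thickness`` — a large positive offset right after disease onset
      (≈6 y) that saturates towards ≈7.5 y: cortical thinning dominates the
      early illness course.
    * ``volume`` — a moderate onset offset (1.5 y) with a slow drift that
      accelerates roughly two decades after onset; the volume curve
      overtakes the thickness curve in the mid-twenties of illness duration.
    * ``fa`` — identically zero: white-matter anisotropy shows no group
      deviation at any duration.

    All profiles are continuous in duration and accept scalars or arrays.
    """

    def thickness(duration):
        d = np.asarray(duration, dtype=float)
        out = 6.0 + 1.5 * (1.0 - np.exp(-d / 8.0))
        return out if out.ndim else float(out)

    def volume(duration):
        d = np.asarray(duration, dtype=float)
        out = 1.5 + 0.05 * d + 0.7 * np.maximum(0.0, d - 20.0)
        return out if out.ndim else float(out)

    def fa(duration):
        d = np.asarray(duration, dtype=float)
        out = 0.0 * d
        return out if out.ndim else float(out)

    return {"volume": volume, "thickness": thickness, "fa": fa}


def _default_n_features() -> dict[str, int]:
    return {"volume": 57, "thickness": 70, "fa": 49}


def _default_slopes() -> dict[str, float]:
    # negative: brain structure declines with (latent) age, in feature units/year
    return {"volume": -1.0, "thickness": -1.0, "fa": -1.0}


def _default_noise() -> dict[str, float]:
    # per-feature noise SD, scaled so model accuracy orders volume > fa > thickness
    return {"volume": 25.0, "thickness": 45.0, "fa": 35.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the reference cohort structure: 330 controls aged
    20–84 (ages drawn from the reference decade-bin histogram), 194
    patients aged 20–70 with illness durations 0–38 years (drawn from the
    reference duration histogram; adult onset enforced), and 57/70/49
    features for the volume/thickness/FA modalities.
    """

    n_controls: int = 330
    n_patients: int = 194
    control_age_range: tuple[float, float] = (20.0, 84.0)
    patient_age_range: tuple[float, float] = (20.0, 70.0)
    duration_range: tuple[float, float] = (0.0, 38.0)
    n_features: Mapping[str, int] = field(default_factory=_default_n_features)
    aging_slopes: Mapping[str, float] = field(default_factory=_default_slopes)
    deviation_profiles: Mapping[str, Callable] | None = None
    noise_sd: Mapping[str, float] = field(default_factory=_default_noise)
    loading_fraction: float = 0.8
    #: optional coupling of symptom scores to the planted deviation (0 = independent)
    clinical_bag_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls <= 0:
            raise ConfigurationError("n_controls must be > 0")
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be > 0")
        for name in ("control_age_range", "patient_age_range", "duration_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name} must be non-degenerate (lo < hi)")
        for mod, count in self.n_features.items():
            if mod not in MODALITIES:
                raise ConfigurationError(f"n_features: unknown modality {mod!r}")
            if count <= 0:
                raise ConfigurationError(f"n_features[{mod!r}] must be > 0")
        for mod in self.n_features:
            if mod not in self.noise_sd:
                raise ConfigurationError(f"noise_sd missing modality {mod!r}")
            if self.noise_sd[mod] < 0:
                raise ConfigurationError(f"noise_sd[{mod!r}] must be >= 0")
            if mod not in self.aging_slopes:
                raise ConfigurationError(f"aging_slopes missing modality {mod!r}")
        if not 0 < self.loading_fraction <= 1:
            raise ConfigurationError("loading_fraction must be in (0, 1]")
        lo, hi = self.patient_age_range
        if hi - 18.0 <= self.duration_range[0]:
            raise ConfigurationError(
                "patient_age_range upper bound leaves no feasible illness duration "
                "(onset is constrained to adulthood)"
            )

    def profiles(self) -> dict[str, Callable]:
        """Resolved deviation profiles (defaults if none configured)."""
        if self.deviation_profiles is None:
            return default_deviation_profiles()
        return dict(self.deviation_profiles)

    def modalities(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITIES if m in self.n_features)


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's demographics, diagnosis and clinical scores.

    ``duration`` (years since illness onset) and the PANSS/CPZ fields are
    present only for patients; ``cpz`` may additionally be absent for
    patients without a verified medication record.
    """

    participant_id: str
    diagnosis: str  # "control" | "patient"
    age: float
    sex: str  # "male" | "female"
    education: float
    mmse: float
    duration: float | None = None
    panss_total: float | None = None
    panss_pos: float | None = None
    panss_neg: float | None = None
    panss_gen: float | None = None
    cpz: float | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in ("control", "patient"):
            raise ValueError(f"diagnosis must be 'control' or 'patient', got {self.diagnosis!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if (self.duration is None) != (self.diagnosis == "control"):
            raise ValueError(
                f"participant {self.participant_id}: duration must be present iff patient"
            )
        if not 0.0 <= self.mmse <= 30.0:
            raise ValueError(f"participant {self.participant_id}: mmse must be in [0, 30]")
        if self.duration is not None and self.duration < 0:
            raise ValueError(f"participant {self.participant_id}: duration must be >= 0")

    @property
    def is_patient(self) -> bool:
        return self.diagnosis == "patient"


@dataclass
class FeatureTable:
    """Participants × named features for one modality (dense, no missing values)."""

    modality: str
    participant_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.participant_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.participant_ids)} participants x {len(self.feature_names)} features"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if len(set(self.participant_ids)) != len(self.participant_ids):
            raise ValueError("participant_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (no missing entries)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "participant_id", self.participant_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str) -> "FeatureTable":
        if "participant_id" not in df.columns:
            raise ValueError("feature table must have a participant_id column")
        ids = df["participant_id"].astype(str).tolist()
        names = [c for c in df.columns if c != "participant_id"]
        return cls(modality, ids, names, df[names].to_numpy(dtype=float))

    def restrict(self, ids: list[str]) -> "FeatureTable":
        """Row subset in the given id order."""
        index = {pid: i for i, pid in enumerate(self.participant_ids)}
        missing = [pid for pid in ids if pid not in index]
        if missing:
            raise KeyError(f"ids not present in feature table: {missing[:5]}")
        rows = [index[pid] for pid in ids]
        return FeatureTable(self.modality, list(ids), list(self.feature_names),
                            self.values[rows])


def planted_loadings(config: SimulationConfig, modality: str) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-feature loadings and baselines for one modality.

    A ``loading_fraction`` of features carry the latent-age signal with
    loading ``aging_slope * U(0.5, 1.5)``; the remainder have loading 0.
    Recomputable without generating the cohort, so tests can check that
    near-noiseless feature tables regress back onto the planted loadings.
    """
    if modality not in MODALITIES:
        raise ConfigurationError(f"unknown modality {modality!r}")
    idx = MODALITIES.index(modality)
    p = int(config.n_features[modality])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 200 + idx]))
    n_carrying = max(1, int(round(config.loading_fraction * p)))
    carriers = np.zeros(p, dtype=bool)
    carriers[rng.choice(p, size=n_carrying, replace=False)] = True
    loadings = config.aging_slopes[modality] * rng.uniform(0.5, 1.5, size=p)
    loadings[~carriers] = 0.0
    intercepts = rng.normal(100.0, 20.0, size=p)
    return loadings, intercepts


# Illness-duration histogram of the reference cohort (bin edges in years,
# patient counts): <1, 1-5, 6-10, 11-20, >20 of 194.
_DURATION_BINS = (
    ((0.0, 1.0), 10.0),
    ((1.0, 6.0), 28.0),
    ((6.0, 11.0), 44.0),
    ((11.0, 21.0), 46.0),
    ((21.0, 38.0), 66.0),
)

# Control age histogram of the reference cohort (decade bins, counts of 330);
# mean ~43.5, SD ~15.5, balanced against the patient group.
_CONTROL_AGE_BINS = (
    ((20.0, 30.0), 92.0),
    ((30.0, 40.0), 50.0),
    ((40.0, 50.0), 55.0),
    ((50.0, 60.0), 68.0),
    ((60.0, 70.0), 58.0),
    ((70.0, 80.0), 3.0),
    ((80.0, 84.0), 4.0),
)


def _sample_piecewise(rng: np.random.Generator, bins, n: int, lo: float,
                      hi: float) -> np.ndarray:
    """Piecewise-uniform draw from a binned histogram, clipped to [lo, hi]."""
    segments = []
    weights = []
    for (b_lo, b_hi), count in bins:
        s_lo, s_hi = max(b_lo, lo), min(b_hi, hi)
        if s_hi > s_lo:
            segments.append((s_lo, s_hi))
            weights.append(count * (s_hi - s_lo) / (b_hi - b_lo))
    if not segments:  # configured range outside the reference histogram
        return rng.uniform(lo, hi, n)
    p = np.asarray(weights) / np.sum(weights)
    picks = rng.choice(len(segments), size=n, p=p)
    u = rng.uniform(size=n)
    return np.array([segments[k][0] + u[i] * (segments[k][1] - segments[k][0])
                     for i, k in enumerate(picks)])


def _fixed_sex_labels(rng: np.random.Generator, n: int,
                      female_fraction: float) -> np.ndarray:
    """Fixed-composition sex labels (emulating enrollment counts), shuffled."""
    n_female = int(round(female_fraction * n))
    labels = np.array(["female"] * n_female + ["male"] * (n - n_female))
    return labels[rng.permutation(n)]


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[ParticipantRecord], dict[str, FeatureTable]]:
    """Generate participants and per-modality feature tables.

    Deterministic given ``config.seed``.  Controls' latent brain age equals
    their chronological age; patients' latent brain age is chronological age
    plus the modality's deviation profile evaluated at their illness
    duration.  Illness onset is constrained to adulthood
    (``duration <= age - 18``) by sampling duration first and then age from
    the jointly feasible range.
    """
    profiles = config.profiles()
    for mod in config.modalities():
        if mod not in profiles:
            raise ConfigurationError(f"deviation_profiles missing modality {mod!r}")

    records: list[ParticipantRecord] = []

    # -- controls ---------------------------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_controls
    ages = _sample_piecewise(rng, _CONTROL_AGE_BINS, n,
                             *config.control_age_range)
    sexes = _fixed_sex_labels(rng, n, 0.609)
    edu = np.clip(rng.normal(15.85, 3.85, n), 0.0, 25.0)
    mmse = np.clip(np.rint(rng.normal(28.96, 1.01, n)), 0.0, 30.0)
    for i in range(n):
        records.append(ParticipantRecord(
            participant_id=f"HC{i + 1:04d}",
            diagnosis="control",
            age=float(ages[i]),
            sex=str(sexes[i]),
            education=float(edu[i]),
            mmse=float(mmse[i]),
        ))

    # -- patients ---------------------------------------------------------
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_patients
    lo_d, hi_d = config.duration_range
    age_lo, age_hi = config.patient_age_range
    cap = min(hi_d, age_hi - 18.0)
    durations = _sample_piecewise(rng, _DURATION_BINS, n, lo_d, cap)
    # age = onset + duration; onset ~ N(27.7, 6) truncated to the jointly
    # feasible range (adult onset, age within the configured bounds)
    ages = np.empty(n)
    for i, d in enumerate(durations):
        onset_lo = max(18.0, age_lo - d)
        onset_hi = age_hi - d
        for _ in range(100):
            onset = rng.normal(27.7, 6.0)
            if onset_lo <= onset <= onset_hi:
                break
        else:
            onset = rng.uniform(onset_lo, onset_hi)
        ages[i] = onset + d
    sexes = _fixed_sex_labels(rng, n, 0.562)
    edu = np.clip(rng.normal(12.50, 3.55, n), 0.0, 25.0)
    mmse = np.clip(np.rint(rng.normal(26.81, 3.39, n)), 0.0, 30.0)
    pos = np.clip(rng.normal(10.74, 3.37, n), 7.0, 49.0)
    neg = np.clip(rng.normal(10.04, 3.76, n), 7.0, 49.0)
    gen = np.clip(rng.normal(21.26, 5.18, n), 16.0, 112.0)
    if config.clinical_bag_coupling != 0.0 and "thickness" in profiles:
        gen = gen + config.clinical_bag_coupling * np.asarray(
            profiles["thickness"](durations), dtype=float
        )
    has_cpz = rng.random(n) < (161.0 / 194.0)
    cpz = np.clip(rng.normal(402.42, 324.27, n), 0.0, None)
    for i in range(n):
        records.append(ParticipantRecord(
            participant_id=f"SZ{i + 1:04d}",
            diagnosis="patient",
            age=float(ages[i]),
            sex=str(sexes[i]),
            education=float(edu[i]),
            mmse=float(mmse[i]),
            duration=float(durations[i]),
            panss_total=float(pos[i] + neg[i] + gen[i]),
            panss_pos=float(pos[i]),
            panss_neg=float(neg[i]),
            panss_gen=float(gen[i]),
            cpz=float(cpz[i]) if has_cpz[i] else None,
        ))

    # -- feature tables ---------------------------------------------------
    all_ids = [r.participant_id for r in records]
    all_ages = np.array([r.age for r in records])
    tables: dict[str, FeatureTable] = {}
    for mod in config.modalities():
        loadings, intercepts = planted_loadings(config, mod)
        profile = profiles[mod]
        deviation = np.array([
            float(profile(r.duration)) if r.is_patient else 0.0 for r in records
        ])
        latent = all_ages + deviation
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 100 + MODALITIES.index(mod)])
        )
        noise = rng.normal(0.0, config.noise_sd[mod], (len(records), loadings.size))
        values = intercepts[None, :] + latent[:, None] * loadings[None, :] + noise
        names = [f"{mod}_f{j:03d}" for j in range(loadings.size)]
        tables[mod] = FeatureTable(mod, all_ids, names, values)

    return records, tables
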