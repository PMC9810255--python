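"""Linear age-bias correction and brain-age gaps.

Brain-age regressors systematically over-predict young subjects and
under-predict old ones.  The standard remedy fits, on a reference set,

    raw brain age = alpha * age + beta            (OLS)

and then corrects every prediction by the fitted age trend,

    corrected = raw + [age - (alpha * age + beta)].

On the fitting set this makes the regression of corrected brain age on
chronological age the identity, so the mean brain-age gap

    BAG = corrected - age

is zero there and uncorrelated with age.  The correction is fitted once on
control training data (out-of-fold predictions) and then frozen: refitting
on patients would absorb the disease signal the gap is meant to expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "BiasCorrection",
    "BAGRecord",
    "fit_bias",
    "apply_correction",
    "compute_bag",
    "make_bag_records",
]


@dataclass(frozen=True)
class BiasCorrection:
    """OLS fit of raw brain age on chronological age (slope alpha, intercept beta)."""

    alpha: float
    beta: float
    fit_n: int
    fit_source: str = "training_oof"  # or "training_refit"

    def __post_init__(self) -> None:
        if self.fit_n < 2:
            raise ValueError("fit_n must be >= 2")
        if not np.isfinite(self.alpha) or not np.isfinite(self.beta):
            raise ValueError("bias coefficients must be finite")


@dataclass(frozen=True)
class BAGRecord:
    """Per-subject raw brain age, corrected brain age and brain-age gap (years)."""

    participant_id: str
    raw_brain_age: float
    corrected_brain_age: float
    bag: float
    modality: str


def fit_bias(
    raw_brain_ages: Mapping[str, float],
    ages: Mapping[str, float],
    fit_source: str = "training_oof",
) -> BiasCorrection:
    """Ordinary-least-squares fit of raw brain age on chronological age."""
    if set(raw_brain_ages) != set(ages):
        raise ValueError("raw_brain_ages and ages must cover the same participants")
    ids = sorted(raw_brain_ages)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 subjects to fit the age bias")
    x = np.array([ages[i] for i in ids], dtype=float)
    y = np.array([raw_brain_ages[i] for i in ids], dtype=float)
    if np.var(x) == 0:
        raise ValueError("zero age variance: bias fit undefined")
    alpha, beta = np.polyfit(x, y, 1)
    return BiasCorrection(alpha=float(alpha), beta=float(beta), fit_n=n,
                          fit_source=fit_source)


def apply_correction(raw, age, bc: BiasCorrection):
    """Corrected brain age: raw + [age - (alpha*age + beta)]. Scalar or array."""
    raw = np.asarray(raw, dtype=float)
    age = np.asarray(age, dtype=float)
    out = raw + (age - (bc.alpha * age + bc.beta))
    return out if out.ndim else float(out)


def compute_bag(corrected, age):
    """Brain-age gap: corrected brain age minus chronological age."""
    out = np.asarray(corrected, dtype=float) - np.asarray(age, dtype=float)
    return out if out.ndim else float(out)


def make_bag_records(
    raw_brain_ages: Mapping[str, float],
    ages: Mapping[str, float],
    bc: BiasCorrection,
    modality: str,
) -> list[BAGRecord]:
    """Apply a frozen correction to raw predictions and package BAG records."""
    records = []
    for pid in sorted(raw_brain_ages):
        raw = float(raw_brain_ages[pid])
        corrected = apply_correction(raw, ages[pid], bc)
        records.append(BAGRecord(
            participant_id=pid,
            raw_brain_age=raw,
            corrected_brain_age=corrected,
            bag=compute_bag(corrected, ages[pid]),
            modality=modality,
        ))
    return records
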