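"""Illness-duration sliding windows, matched-control sampling, outlier fences.

Patients are grouped by years since illness onset into overlapping windows
(default 5-year width, 1-year step), with a merged tail window for the
longest durations where samples get sparse.  Each window's patients are
compared against an equally sized set of age- and sex-matched healthy
controls drawn from the hold-out test set: matching is greedy
nearest-age within sex with random tie-breaking, without replacement
within a window but with replacement across windows.  Before group
comparison, patient brain-age gaps are screened with Tukey's boxplot
fences [Q1 - 1.5*IQR, Q3 + 1.5*IQR].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cohort import ParticipantRecord

__all__ = [
    "MatchingError",
    "WindowSpec",
    "IllnessWindow",
    "build_windows",
    "match_controls",
    "remove_outliers_tukey",
]


class MatchingError(ValueError):
    """Not enough same-sex hold-out controls to match a window."""


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout over illness duration (years)."""

    width: int = 5
    step: int = 1
    tail_merge_start: int = 31
    duration_max: float | None = None  # observed maximum if None

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.tail_merge_start < self.width:
            raise ValueError("tail_merge_start must be >= width")


@dataclass(frozen=True)
class IllnessWindow:
    """One duration window: its patients and (once matched) control sample.

    Membership is ``duration_lo <= duration < duration_lo + width`` for
    regular windows (the label's ``duration_hi`` is the inclusive integer
    upper edge) and ``duration_lo <= duration <= duration_hi`` for the
    merged tail.
    """

    label: str
    duration_lo: float
    duration_hi: float
    patient_ids: tuple[str, ...]
    matched_control_ids: tuple[str, ...] = ()
    seed_used: int | None = None
    mean_age_diff: float | None = None
    is_tail: bool = False

    @property
    def is_empty(self) -> bool:
        return len(self.patient_ids) == 0


def build_windows(
    patients: Sequence[ParticipantRecord], spec: WindowSpec | None = None
) -> list[IllnessWindow]:
    """Assign patients to overlapping duration windows (controls left empty).

    Regular windows start at 0, step, 2*step, ... while the window's
    inclusive upper edge stays below ``tail_merge_start``; one final merged
    window spans [tail_merge_start, duration_max].  A patient may appear in
    several windows.  Windows with no patients are retained (callers
    exclude them downstream via ``is_empty``).
    """
    spec = spec or WindowSpec()
    if any(not p.is_patient or p.duration is None for p in patients):
        raise ValueError("build_windows expects patient records with durations")
    durations = {p.participant_id: float(p.duration) for p in patients}
    observed_max = max(durations.values()) if durations else float(spec.tail_merge_start)
    duration_max = float(spec.duration_max if spec.duration_max is not None else
                         np.ceil(observed_max))

    windows: list[IllnessWindow] = []
    start = 0
    while start + spec.width - 1 < spec.tail_merge_start:
        lo, hi = float(start), float(start + spec.width - 1)
        members = tuple(pid for pid, d in durations.items() if lo <= d < lo + spec.width)
        windows.append(IllnessWindow(
            label=f"{start}-{start + spec.width - 1}",
            duration_lo=lo, duration_hi=hi, patient_ids=members,
        ))
        start += spec.step
    tail_lo = float(spec.tail_merge_start)
    members = tuple(pid for pid, d in durations.items() if tail_lo <= d <= duration_max)
    windows.append(IllnessWindow(
        label=f"{spec.tail_merge_start}-{int(duration_max)}",
        duration_lo=tail_lo, duration_hi=duration_max, patient_ids=members,
        is_tail=True,
    ))
    return windows


def match_controls(
    window: IllnessWindow,
    patients: Mapping[str, ParticipantRecord],
    holdout: Sequence[ParticipantRecord],
    seed: int = 0,
    mode: str = "greedy",
    caliper: float = 5.0,
) -> IllnessWindow:
    """Sample one age/sex-matched hold-out control per window patient.

    ``mode="greedy"`` (default): patients are visited in random order and
    each takes the unused same-sex control with the smallest absolute age
    difference, ties broken at random.  ``mode="random"``: a uniformly
    random unused same-sex control within ``caliper`` years of age (falling
    back to the nearest if none is within the caliper).  Sampling is
    without replacement within the window; deterministic per seed.
    """
    if mode not in ("greedy", "random"):
        raise ValueError("mode must be 'greedy' or 'random'")
    window_patients = [patients[pid] for pid in window.patient_ids]

    need = {"male": 0, "female": 0}
    for p in window_patients:
        need[p.sex] += 1
    avail = {"male": 0, "female": 0}
    for c in holdout:
        avail[c.sex] += 1
    deficits = {s: need[s] - avail[s] for s in need if need[s] > avail[s]}
    if deficits:
        raise MatchingError(
            f"window {window.label}: insufficient same-sex hold-out controls "
            f"(deficit {deficits})"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = rng.permutation(len(window_patients))
    used: set[str] = set()
    matched: list[str] = []
    diffs: list[float] = []
    for i in order:
        p = window_patients[i]
        candidates = [c for c in holdout
                      if c.sex == p.sex and c.participant_id not in used]
        gaps = np.array([abs(c.age - p.age) for c in candidates])
        if mode == "greedy":
            pool = np.flatnonzero(gaps <= gaps.min() + 1e-12)
        else:
            pool = np.flatnonzero(gaps <= caliper)
            if pool.size == 0:
                pool = np.flatnonzero(gaps <= gaps.min() + 1e-12)
        pick = candidates[int(rng.choice(pool))]
        used.add(pick.participant_id)
        matched.append(pick.participant_id)
        diffs.append(abs(pick.age - p.age))

    return replace(
        window,
        matched_control_ids=tuple(matched),
        seed_used=seed,
        mean_age_diff=float(np.mean(diffs)) if diffs else None,
    )


def remove_outliers_tukey(
    values: Sequence[float],
) -> tuple[np.ndarray, np.ndarray, tuple[float, float] | None]:
    """Single-pass Tukey boxplot screen.

    Q1/Q3 are the 25th/75th percentiles under numpy's linear-interpolation
    convention; values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are removed.
    With fewer than 4 values the screen is skipped with a warning and
    ``fences`` is None.  Returns (kept, removed, fences) preserving order.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        warnings.warn(
            f"Tukey outlier screen skipped: only {arr.size} values (< 4)",
            stacklevel=2,
        )
        return arr.copy(), np.array([]), None
    q1, q3 = np.percentile(arr, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (arr >= lo) & (arr <= hi)
    return arr[keep], arr[~keep], (float(lo), float(hi))
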