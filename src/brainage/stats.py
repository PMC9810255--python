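"""Group-comparison statistics: ANCOVA, effect sizes, demographics, correlations.

The central comparison is an ANCOVA per illness-duration window and
modality: brain-age gap as dependent variable, diagnosis (patient vs.
matched control) as the 2-level grouping factor, with chronological age,
sex, MMSE and education as covariates.  The group effect is tested by its
partial (Type-III-equivalent) sum of squares; for a 2-level factor the
partial F equals the squared t of the group coefficient in the linear
model.  Effect size is partial eta squared, SS_group/(SS_group+SS_error).
Multiplicity is controlled by Bonferroni (family alpha / m; the reference
setting alpha=0.05, m=5 gives the 0.01 threshold).

Demographic tables use the independent two-sample t-test (pooled or
Welch, computed from summary statistics) and Pearson's chi-square without
continuity correction; brain-age-gap/clinical associations use Pearson
correlations with pairwise deletion of missing clinical values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import ParticipantRecord

__all__ = [
    "AncovaResult",
    "ancova_bag",
    "bonferroni_alpha",
    "two_sample_t",
    "chi_square_2x2",
    "bag_clinical_correlations",
    "cohort_stats",
]

CLINICAL_VARIABLES = ("panss_total", "panss_pos", "panss_neg", "panss_gen", "cpz")


@dataclass(frozen=True)
class AncovaResult:
    """One window's ANCOVA: group F test and partial eta squared."""

    window_label: str
    n_patients_after_outliers: int
    n_controls: int
    group_F: float
    group_p: float
    partial_eta_sq: float
    ss_group: float
    ss_error: float
    adjusted_alpha: float
    significant: bool
    covariates_used: tuple[str, ...]


def _encode_covariate(data: pd.DataFrame, name: str) -> np.ndarray:
    col = data[name]
    if name == "sex" or col.dtype == object:
        levels = sorted(col.astype(str).unique())
        if len(levels) > 2:
            raise ValueError(f"covariate {name!r} has more than 2 levels")
        return (col.astype(str) == levels[-1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def ancova_bag(
    data: pd.DataFrame,
    window_label: str = "",
    adjusted_alpha: float = 0.01,
    covariates: Sequence[str] = ("age", "sex", "mmse", "education"),
) -> AncovaResult:
    """ANCOVA of BAG on diagnosis with covariate adjustment.

    ``data`` needs columns ``bag`` and ``group`` ("patient"/"control") plus
    the covariate columns.  Covariates that are constant or collinear in
    this window (e.g. sex in a single-sex window) are dropped with a
    recorded reduction in ``covariates_used``.
    """
    groups = set(data["group"])
    if groups != {"patient", "control"}:
        raise ValueError("both groups must be non-empty")
    y = data["bag"].to_numpy(dtype=float)
    g = (data["group"] == "patient").to_numpy(dtype=float)

    X = pd.DataFrame({"const": np.ones(len(data)), "group": g})
    used: list[str] = []
    for name in covariates:
        col = _encode_covariate(data, name)
        if np.unique(col).size < 2:
            continue
        candidate = X.assign(**{name: col})
        if np.linalg.matrix_rank(candidate.to_numpy()) == candidate.shape[1]:
            X = candidate
            used.append(name)

    if len(data) <= X.shape[1]:
        raise ValueError("too few subjects for the ANCOVA design")
    fit = sm.OLS(y, X.to_numpy()).fit()
    j = list(X.columns).index("group")
    t = float(fit.tvalues[j])
    F = t * t
    p = float(fit.pvalues[j])
    ss_error = float(fit.ssr)
    mse = ss_error / fit.df_resid
    ss_group = F * mse
    eta = ss_group / (ss_group + ss_error)
    return AncovaResult(
        window_label=window_label,
        n_patients_after_outliers=int((data["group"] == "patient").sum()),
        n_controls=int((data["group"] == "control").sum()),
        group_F=F,
        group_p=p,
        partial_eta_sq=eta,
        ss_group=ss_group,
        ss_error=ss_error,
        adjusted_alpha=adjusted_alpha,
        significant=bool(p < adjusted_alpha),
        covariates_used=tuple(used),
    )


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test alpha: family_alpha / m."""
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def two_sample_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "welch",
) -> tuple[float, float]:
    """Independent two-sample t from summary statistics; returns (t, df).

    ``pooled`` uses the pooled-variance statistic with df = n1 + n2 - 2;
    ``welch`` the unequal-variance statistic with Welch–Satterthwaite df.
    The sign follows mean1 - mean2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    delta = mean1 - mean2
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        denom = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)) if denom > 0 else 0.0
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    if denom == 0:
        raise ZeroDivisionError("t statistic undefined: zero pooled variance")
    return float(delta / denom), float(df)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int]:
    """Pearson chi-square (no continuity correction) for a 2x2 table; df = 1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or table.sum() <= 0:
        raise ValueError("counts must be >= 0 with a positive total")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero marginal")
    chi2 = sps.chi2_contingency(table, correction=False).statistic
    return float(chi2), 1


def bag_clinical_correlations(
    bags: Mapping[str, Mapping[str, float]],
    clinical: pd.DataFrame,
    variables: Sequence[str] = CLINICAL_VARIABLES,
) -> pd.DataFrame:
    """Pearson r between patient BAGs and clinical scores, per (modality, variable).

    ``bags`` maps modality -> participant_id -> BAG; ``clinical`` is indexed
    by participant_id with the clinical columns.  Missing clinical values
    (e.g. patients without a verified medication record for ``cpz``) are
    dropped pairwise, so each cell has its own n.  Cells with n < 3 or zero
    variance are marked undefined (NaN r and p).
    """
    rows = []
    for modality, bag_map in bags.items():
        bag = pd.Series(bag_map, dtype=float)
        for var in variables:
            joined = pd.concat([bag.rename("bag"), clinical[var]], axis=1,
                               join="inner").dropna()
            n = len(joined)
            if n < 3 or joined["bag"].std() == 0 or joined[var].std() == 0:
                rows.append((modality, var, n, np.nan, np.nan))
                continue
            res = sps.pearsonr(joined["bag"], joined[var])
            rows.append((modality, var, n, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["modality", "variable", "n", "r", "p"])


def cohort_stats(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Patient-vs-control demographic tests (Table-1 style).

    Continuous variables (age, education, MMSE) get the independent t-test
    in both pooled and Welch variants; sex gets the chi-square test.
    """
    patients = [r for r in records if r.is_patient]
    controls = [r for r in records if not r.is_patient]
    if len(patients) < 2 or len(controls) < 2:
        raise ValueError("need >= 2 patients and >= 2 controls")
    rows = []
    for var in ("age", "education", "mmse"):
        x = np.array([getattr(r, var) for r in patients], dtype=float)
        y = np.array([getattr(r, var) for r in controls], dtype=float)
        for variant in ("pooled", "welch"):
            t, df = two_sample_t(
                x.mean(), x.std(ddof=1), x.size,
                y.mean(), y.std(ddof=1), y.size,
                variant=variant,
            )
            p = 2.0 * sps.t.sf(abs(t), df)
            rows.append((var, f"t_{variant}", t, df, p, None))
    a = sum(r.sex == "male" for r in patients)
    b = sum(r.sex == "female" for r in patients)
    c = sum(r.sex == "male" for r in controls)
    d = sum(r.sex == "female" for r in controls)
    chi2, df = chi_square_2x2(a, b, c, d)
    p = sps.chi2.sf(chi2, df)
    rows.append(("sex", "chi_square", chi2, float(df), p, f"{a}/{b} vs {c}/{d}"))
    return pd.DataFrame(
        rows, columns=["variable", "test", "statistic", "df", "p", "counts"]
    )
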