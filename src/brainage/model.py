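"""Gaussian-process brain-age regression.

The brain-age model is a GP regressor with an exponential (Ornstein–
Uhlenbeck) kernel on standardized features,

    k(x, x') = sigma_f^2 * exp(-||x - x'|| / ell),

a constant mean ``c`` and i.i.d. observation noise ``sigma_n``.  The
posterior-mean prediction at a query ``x*`` is the closed form

    f(x*) = c + k*^T (K + sigma_n^2 I)^{-1} (y - c).

Hyperparameters (ell, sigma_f, sigma_n) maximize the log marginal
likelihood with the constant mean profiled out (its GLS estimate is
closed-form given the other parameters); optimization is multi-start
L-BFGS-B in log space.  A small relative jitter on the kernel diagonal
keeps the Cholesky factorization conditioned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .cohort import FeatureTable, ParticipantRecord

__all__ = [
    "ValidationError",
    "InsufficientDataError",
    "SchemaError",
    "NumericalError",
    "GPRSpec",
    "TrainedBrainAgeModel",
    "CVReport",
    "split_controls",
    "fit_gpr",
    "predict_brain_age",
    "kfold_oof",
    "repeated_cv",
    "evaluate",
]


class ValidationError(ValueError):
    """Invalid model inputs (constant features, bad hyperparameters, ...)."""


class InsufficientDataError(ValueError):
    """Too few subjects for the requested operation."""


class SchemaError(KeyError):
    """Feature table does not match the model's expected columns."""


class NumericalError(RuntimeError):
    """Linear-algebra failure (e.g. singular kernel matrix with zero noise)."""


@dataclass(frozen=True)
class GPRSpec:
    """Configuration of the GP regressor.

    ``hyperparameter_init`` may fix ``lengthscale``, ``signal_sd``,
    ``noise_sd`` and optionally ``mean``; with ``optimize=False`` those
    values are used as-is (an absent ``mean`` is profiled from the data).
    ``jitter`` is a relative diagonal inflation (units of sigma_f^2).
    """

    standardize: bool = True
    hyperparameter_init: Mapping[str, float] | None = None
    optimize: bool = True
    n_restarts: int = 2
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        init = self.hyperparameter_init
        if init is not None:
            if "lengthscale" in init and not init["lengthscale"] > 0:
                raise ValidationError("lengthscale must be > 0")
            if "signal_sd" in init and not init["signal_sd"] > 0:
                raise ValidationError("signal_sd must be > 0")
            if "noise_sd" in init and init["noise_sd"] < 0:
                raise ValidationError("noise_sd must be >= 0")
        if not self.optimize and init is None:
            raise ValidationError("optimize=False requires hyperparameter_init")
        if self.jitter < 0:
            raise ValidationError("jitter must be >= 0")


def split_controls(
    records: Sequence[ParticipantRecord], ratio: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Randomly split control ids into training and hold-out sets.

    The training size is ``floor(ratio * N)`` evaluated in floating point
    (so 330 controls at ratio 0.7 give the conventional 230/100 split).
    Deterministic per seed; the two sets are disjoint and exhaustive.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if any(r.diagnosis != "control" for r in records):
        raise ValueError("split_controls expects control records only")
    ids = [r.participant_id for r in records]
    n = len(ids)
    if n < 2:
        raise InsufficientDataError("need at least 2 controls to split")
    n_train = int(ratio * n)
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(n)
    train = [ids[i] for i in perm[:n_train]]
    holdout = [ids[i] for i in perm[n_train:]]
    return train, holdout


# ---------------------------------------------------------------------------
# GP internals


def _kernel(D: np.ndarray, lengthscale: float, signal_var: float) -> np.ndarray:
    return signal_var * np.exp(-D / lengthscale)


def _nll(
    theta: np.ndarray, D: np.ndarray, y: np.ndarray, jitter: float
) -> tuple[float, float]:
    """Negative log marginal likelihood with the constant mean profiled out.

    ``theta`` is (log ell, log sigma_f^2, log sigma_n^2).  Returns (nll, c).
    """
    ell, sf2, sn2 = np.exp(theta)
    n = y.size
    A = _kernel(D, ell, sf2)
    A[np.diag_indices_from(A)] += sn2 + jitter * sf2
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf, 0.0
    ones = np.ones(n)
    u = cho_solve((L, True), y)
    v = cho_solve((L, True), ones)
    c = float(ones @ u) / float(ones @ v)
    r = y - c
    a = u - c * v  # A^{-1} (y - c*1)
    nll = 0.5 * float(r @ a) + float(np.log(np.diag(L)).sum()) + 0.5 * n * np.log(2 * np.pi)
    return nll, c


def _optimize_hyperparameters(
    D: np.ndarray, y: np.ndarray, spec: GPRSpec
) -> tuple[dict[str, float], float]:
    off_diag = D[np.triu_indices_from(D, k=1)]
    positive = off_diag[off_diag > 0]
    d_med = float(np.median(positive)) if positive.size else 1.0
    y_var = max(float(np.var(y)), 1e-12)

    starts = [
        (d_med, y_var, 0.1 * y_var),
        (2.0 * d_med, y_var, 0.5 * y_var),
        (0.5 * d_med, 2.0 * y_var, 0.01 * y_var),
        (d_med, 0.5 * y_var, y_var),
    ]
    init = dict(spec.hyperparameter_init or {})
    if {"lengthscale", "signal_sd", "noise_sd"} <= set(init):
        starts.insert(0, (init["lengthscale"], init["signal_sd"] ** 2,
                          max(init["noise_sd"] ** 2, 1e-10 * y_var)))
    starts = starts[: max(1, spec.n_restarts + 1)]

    bounds = [
        (np.log(1e-3 * d_med), np.log(1e3 * d_med)),
        (np.log(1e-4 * y_var), np.log(1e4 * y_var)),
        (np.log(1e-8 * y_var), np.log(1e2 * y_var)),
    ]
    best = None
    for ell0, sf20, sn20 in starts:
        x0 = np.log([ell0, sf20, sn20])
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            lambda th: _nll(th, D, y, spec.jitter)[0],
            x0,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    ell, sf2, sn2 = np.exp(best.x)
    nll, c = _nll(best.x, D, y, spec.jitter)
    params = {
        "lengthscale": float(ell),
        "signal_sd": float(np.sqrt(sf2)),
        "noise_sd": float(np.sqrt(sn2)),
        "mean": c,
    }
    return params, -nll


@dataclass
class TrainedBrainAgeModel:
    """A fitted GP brain-age regressor.

    Stores the raw training design matrix and targets (needed for kernel
    prediction), per-feature standardization statistics, the fitted
    hyperparameters, and optionally the frozen linear age-bias correction.
    """

    modality: str
    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    lengthscale: float
    signal_sd: float
    noise_sd: float
    mean: float
    jitter: float
    X_train: np.ndarray
    y_train: np.ndarray
    log_marginal_likelihood: float | None = None
    bias_correction: "object | None" = None  # age_bias.BiasCorrection
    _alpha: np.ndarray | None = field(default=None, repr=False, compare=False)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_sd

    def _ensure_alpha(self) -> np.ndarray:
        if self._alpha is None:
            Xs = self._standardize(self.X_train)
            D = cdist(Xs, Xs)
            A = _kernel(D, self.lengthscale, self.signal_sd**2)
            A[np.diag_indices_from(A)] += self.noise_sd**2 + self.jitter * self.signal_sd**2
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(
                    "kernel matrix is singular (duplicate inputs with zero noise?); "
                    "add observation noise or a diagonal jitter"
                ) from exc
            self._alpha = cho_solve((L, True), self.y_train - self.mean)
        return self._alpha

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Posterior-mean brain age for raw (unstandardized) feature rows."""
        alpha = self._ensure_alpha()
        Xs_train = self._standardize(self.X_train)
        Xs = self._standardize(np.asarray(X, dtype=float))
        Kstar = _kernel(cdist(Xs, Xs_train), self.lengthscale, self.signal_sd**2)
        return self.mean + Kstar @ alpha

    def align(self, features: FeatureTable) -> np.ndarray:
        """Reorder feature columns by name to match the training layout."""
        index = {name: j for j, name in enumerate(features.feature_names)}
        missing = [name for name in self.feature_names if name not in index]
        if missing:
            raise SchemaError(f"feature table is missing columns: {missing[:5]}")
        cols = [index[name] for name in self.feature_names]
        return features.values[:, cols]

    def predict(self, features: FeatureTable) -> dict[str, float]:
        preds = self.predict_matrix(self.align(features))
        if not np.all(np.isfinite(preds)):
            raise NumericalError("non-finite predictions")
        return {pid: float(p) for pid, p in zip(features.participant_ids, preds)}

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        from .bias import BiasCorrection  # local import to avoid a cycle

        bc = None
        if self.bias_correction is not None:
            bc = {
                "alpha": self.bias_correction.alpha,
                "beta": self.bias_correction.beta,
                "fit_n": self.bias_correction.fit_n,
                "fit_source": self.bias_correction.fit_source,
            }
        return {
            "modality": self.modality,
            "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "hyperparameters": {
                "lengthscale": self.lengthscale,
                "signal_sd": self.signal_sd,
                "noise_sd": self.noise_sd,
                "mean": self.mean,
            },
            "jitter": self.jitter,
            "X_train": self.X_train.tolist(),
            "y_train": self.y_train.tolist(),
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "bias_correction": bc,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TrainedBrainAgeModel":
        from .bias import BiasCorrection

        hp = payload["hyperparameters"]
        bc = payload.get("bias_correction")
        return cls(
            modality=payload["modality"],
            feature_names=list(payload["feature_names"]),
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            x_sd=np.asarray(payload["x_sd"], dtype=float),
            lengthscale=float(hp["lengthscale"]),
            signal_sd=float(hp["signal_sd"]),
            noise_sd=float(hp["noise_sd"]),
            mean=float(hp["mean"]),
            jitter=float(payload.get("jitter", 1e-8)),
            X_train=np.asarray(payload["X_train"], dtype=float),
            y_train=np.asarray(payload["y_train"], dtype=float),
            log_marginal_likelihood=payload.get("log_marginal_likelihood"),
            bias_correction=None if bc is None else BiasCorrection(**bc),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedBrainAgeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_gpr(
    features: FeatureTable,
    ages: Mapping[str, float],
    spec: GPRSpec | None = None,
) -> TrainedBrainAgeModel:
    """Fit the GP brain-age regressor on a (training) feature table.

    ``ages`` must cover every participant in ``features``.  With
    ``spec.optimize`` the hyperparameters maximize the profile log marginal
    likelihood (multi-start L-BFGS-B); otherwise the fixed values from
    ``spec.hyperparameter_init`` are used.
    """
    spec = spec or GPRSpec()
    missing = [pid for pid in features.participant_ids if pid not in ages]
    if missing:
        raise ValidationError(f"ages missing for participants: {missing[:5]}")
    y = np.array([float(ages[pid]) for pid in features.participant_ids])
    n = y.size
    if spec.optimize and n < 5:
        raise InsufficientDataError(
            f"hyperparameter optimization needs >= 5 training subjects, got {n}"
        )

    X = features.values
    if spec.standardize:
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0, ddof=0)
        constant = np.flatnonzero(x_sd == 0)
        if constant.size:
            bad = [features.feature_names[j] for j in constant[:5]]
            raise ValidationError(f"constant feature(s) in training data: {bad}")
    else:
        x_mean = np.zeros(X.shape[1])
        x_sd = np.ones(X.shape[1])
    Xs = (X - x_mean) / x_sd
    D = cdist(Xs, Xs)

    if spec.optimize:
        params, lml = _optimize_hyperparameters(D, y, spec)
    else:
        init = dict(spec.hyperparameter_init)
        theta = np.log([
            init["lengthscale"],
            init["signal_sd"] ** 2,
            max(init["noise_sd"], 0.0) ** 2 if init["noise_sd"] > 0 else 1e-300,
        ])
        if "mean" in init and init["mean"] is not None:
            c = float(init["mean"])
        elif n == 1:
            c = float(y[0])
        else:
            _, c = _nll(theta, D, y, spec.jitter)
        params = {
            "lengthscale": float(init["lengthscale"]),
            "signal_sd": float(init["signal_sd"]),
            "noise_sd": float(init["noise_sd"]),
            "mean": c,
        }
        lml = None

    return TrainedBrainAgeModel(
        modality=features.modality,
        feature_names=list(features.feature_names),
        x_mean=x_mean,
        x_sd=x_sd,
        lengthscale=params["lengthscale"],
        signal_sd=params["signal_sd"],
        noise_sd=params["noise_sd"],
        mean=params["mean"],
        jitter=spec.jitter,
        X_train=X.copy(),
        y_train=y,
        log_marginal_likelihood=lml,
    )


def predict_brain_age(
    model: TrainedBrainAgeModel, features: FeatureTable
) -> dict[str, float]:
    """Raw (uncorrected) brain age per participant id."""
    return model.predict(features)


def evaluate(
    predictions: Mapping[str, float], ages: Mapping[str, float]
) -> tuple[float, float]:
    """MAE and Pearson r between predictions and chronological ages."""
    if set(predictions) != set(ages):
        raise ValueError("predictions and ages must cover the same participants")
    ids = sorted(predictions)
    pred = np.array([predictions[i] for i in ids], dtype=float)
    age = np.array([ages[i] for i in ids], dtype=float)
    if pred.size < 3:
        raise InsufficientDataError("need >= 3 subjects for Pearson r")
    mae = float(np.mean(np.abs(pred - age)))
    if np.std(pred) == 0 or np.std(age) == 0:
        raise ValueError("Pearson r undefined: zero variance")
    r = float(pearsonr(pred, age).statistic)
    return mae, r


def kfold_oof(
    features: FeatureTable,
    ages: Mapping[str, float],
    spec: GPRSpec | None = None,
    n_folds: int = 5,
    seed=0,
) -> dict[str, float]:
    """Out-of-fold predictions from one k-fold run (random near-equal folds)."""
    spec = spec or GPRSpec()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = len(features.participant_ids)
    if n < n_folds:
        raise InsufficientDataError(f"{n} subjects cannot fill {n_folds} folds")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(n)
    oof: dict[str, float] = {}
    for fold in np.array_split(perm, n_folds):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        train_ids = [features.participant_ids[i] for i in np.flatnonzero(mask)]
        test_ids = [features.participant_ids[i] for i in fold]
        model = fit_gpr(features.restrict(train_ids), ages, spec)
        oof.update(model.predict(features.restrict(test_ids)))
    return oof


@dataclass
class CVReport:
    """Repeated k-fold CV metrics (one MAE and Pearson r per repeat)."""

    n_folds: int
    n_repeats: int
    maes: list[float]
    rs: list[float]

    def summary(self) -> dict[str, dict[str, float]]:
        """Mean, SD and normal-approximation 95% CI of each repeat metric."""
        out = {}
        for name, values in (("mae", self.maes), ("r", self.rs)):
            arr = np.asarray(values, dtype=float)
            mean = float(arr.mean())
            sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
            half = 1.96 * sd / np.sqrt(arr.size)
            out[name] = {
                "mean": mean,
                "sd": sd,
                "ci_low": mean - half,
                "ci_high": mean + half,
            }
        return out


def repeated_cv(
    features: FeatureTable,
    ages: Mapping[str, float],
    spec: GPRSpec | None = None,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> CVReport:
    """Repeat k-fold CV with reshuffled folds; pool out-of-fold predictions per repeat.

    Repeat ``r`` uses the fold seed ``SeedSequence([seed, r])``, so
    ``n_repeats=1`` reproduces a single ``kfold_oof`` run with seed
    ``[seed, 0]``.
    """
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    sub_ages = {pid: float(ages[pid]) for pid in features.participant_ids}
    maes, rs = [], []
    for r in range(n_repeats):
        oof = kfold_oof(features, sub_ages, spec, n_folds=n_folds, seed=[seed, r])
        mae, rho = evaluate(oof, sub_ages)
        maes.append(mae)
        rs.append(rho)
    return CVReport(n_folds=n_folds, n_repeats=n_repeats, maes=maes, rs=rs)
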