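"""GP brain-age model: splits, posterior-mean oracle equivalence, CV harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainage import (FeatureTable, GPRSpec, InsufficientDataError, evaluate,
                      fit_gpr, kfold_oof, predict_brain_age, repeated_cv,
                      split_controls)
from brainage.model import NumericalError, SchemaError, ValidationError, _nll
from tests.conftest import mk_control


def _table(X, modality="volume", ids=None):
    X = np.asarray(X, dtype=float)
    ids = ids or [f"S{i:03d}" for i in range(X.shape[0])]
    names = [f"{modality}_f{j:03d}" for j in range(X.shape[1])]
    return FeatureTable(modality, ids, names, X)


def _fixed_spec(lengthscale, signal_sd, noise_sd, mean=None, **kw):
    return GPRSpec(
        standardize=False, optimize=False, jitter=0.0,
        hyperparameter_init={
            "lengthscale": lengthscale, "signal_sd": signal_sd,
            "noise_sd": noise_sd, **({"mean": mean} if mean is not None else {}),
        }, **kw,
    )


def _oracle_posterior_mean(X, y, Xq, lengthscale, signal_sd, noise_sd, mean):
    """Dense linear-algebra GP posterior mean, independent of the model code."""
    from scipy.spatial.distance import cdist

    K = signal_sd**2 * np.exp(-cdist(X, X) / lengthscale)
    A = K + noise_sd**2 * np.eye(len(y))
    Kq = signal_sd**2 * np.exp(-cdist(Xq, X) / lengthscale)
    return mean + Kq @ np.linalg.solve(A, np.asarray(y) - mean)


# --------------------------------------------------------------------------
# split_controls


def test_split_reproduces_conventional_230_100():
    controls = [mk_control(f"C{i}", 30 + i % 40) for i in range(330)]
    train, hold = split_controls(controls, ratio=0.7, seed=0)
    assert (len(train), len(hold)) == (230, 100)


def test_split_disjoint_exhaustive():
    controls = [mk_control(f"C{i}", 25 + i) for i in range(10)]
    train, hold = split_controls(controls, ratio=0.5, seed=3)
    assert (len(train), len(hold)) == (5, 5)
    assert set(train) | set(hold) == {c.participant_id for c in controls}
    assert set(train) & set(hold) == set()


def test_split_deterministic_per_seed():
    controls = [mk_control(f"C{i}", 25 + i) for i in range(50)]
    assert split_controls(controls, 0.7, seed=4) == split_controls(controls, 0.7, seed=4)
    assert split_controls(controls, 0.7, seed=4) != split_controls(controls, 0.7, seed=5)


def test_split_rejects_tiny_or_mixed_input():
    with pytest.raises(InsufficientDataError):
        split_controls([mk_control("C0", 30)], 0.5, 0)
    from tests.conftest import mk_patient

    with pytest.raises(ValueError, match="control"):
        split_controls([mk_control("C0", 30), mk_patient("P0", 40, 5.0)], 0.5, 0)


# --------------------------------------------------------------------------
# posterior mean


def test_single_noiseless_point_interpolates():
    table = _table([[1.0, 2.0]])
    model = fit_gpr(table, {"S000": 55.0}, _fixed_spec(1.0, 1.0, 0.0))
    assert model.predict(table)["S000"] == pytest.approx(55.0, abs=1e-6)


def test_posterior_mean_matches_dense_oracle_small():
    rng = np.random.default_rng(0)
    X, y = rng.normal(size=(6, 2)), rng.uniform(20, 80, 6)
    table = _table(X)
    model = fit_gpr(table, dict(zip(table.participant_ids, y)),
                    _fixed_spec(1.5, 3.0, 0.5, mean=40.0))
    Xq = rng.normal(size=(4, 2))
    expected = _oracle_posterior_mean(X, y, Xq, 1.5, 3.0, 0.5, 40.0)
    np.testing.assert_allclose(model.predict_matrix(Xq), expected, atol=1e-8)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 50),
    p=st.integers(1, 5),
    lengthscale=st.floats(0.3, 10.0),
    signal_sd=st.floats(0.5, 10.0),
    noise_sd=st.floats(0.05, 5.0),
    data_seed=st.integers(0, 10_000),
)
def test_posterior_mean_oracle_property(n, p, lengthscale, signal_sd, noise_sd,
                                        data_seed):
    """Closed-form predictor equals a dense independent evaluation, any instance."""
    rng = np.random.default_rng(data_seed)
    X, y = rng.normal(size=(n, p)), rng.uniform(20, 80, n)
    table = _table(X)
    model = fit_gpr(table, dict(zip(table.participant_ids, y)),
                    _fixed_spec(lengthscale, signal_sd, noise_sd, mean=50.0))
    Xq = rng.normal(size=(3, p))
    expected = _oracle_posterior_mean(X, y, Xq, lengthscale, signal_sd,
                                      noise_sd, 50.0)
    np.testing.assert_allclose(model.predict_matrix(Xq), expected,
                               rtol=1e-8, atol=1e-8)


def test_posterior_mean_matches_sklearn_gp():
    sklearn = pytest.importorskip("sklearn.gaussian_process")
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

    rng = np.random.default_rng(3)
    X, y = rng.normal(size=(25, 3)), rng.uniform(20, 80, 25)
    ell, sf, sn = 2.0, 4.0, 1.0
    table = _table(X)
    model = fit_gpr(table, dict(zip(table.participant_ids, y)),
                    _fixed_spec(ell, sf, sn, mean=0.0))
    # Matern nu=1/2 is the exponential kernel sf^2 * exp(-d/ell)
    kernel = ConstantKernel(sf**2, "fixed") * Matern(ell, "fixed", nu=0.5) \
        + WhiteKernel(sn**2, "fixed")
    gp = GaussianProcessRegressor(kernel=kernel, alpha=0.0, optimizer=None)
    gp.fit(X, y)
    Xq = rng.normal(size=(5, 3))
    np.testing.assert_allclose(model.predict_matrix(Xq), gp.predict(Xq), atol=1e-8)


def test_prediction_invariant_to_feature_column_order():
    rng = np.random.default_rng(5)
    X, y = rng.normal(size=(12, 4)), rng.uniform(20, 80, 12)
    table = _table(X)
    model = fit_gpr(table, dict(zip(table.participant_ids, y)),
                    _fixed_spec(2.0, 3.0, 0.7))
    perm = [2, 0, 3, 1]
    shuffled = FeatureTable(
        table.modality, table.participant_ids,
        [table.feature_names[j] for j in perm], X[:, perm],
    )
    assert model.predict(shuffled) == model.predict(table)


def test_missing_feature_column_is_named():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(8, 3))
    table = _table(X)
    model = fit_gpr(table, {pid: 50.0 + i for i, pid in
                            enumerate(table.participant_ids)},
                    _fixed_spec(1.0, 1.0, 0.5))
    truncated = FeatureTable(table.modality, table.participant_ids,
                             table.feature_names[:2], X[:, :2])
    with pytest.raises(SchemaError, match="volume_f002"):
        model.predict(truncated)


def test_duplicate_inputs_with_zero_noise_advise_jitter():
    X = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
    table = _table(X)
    model = fit_gpr(table, {pid: 40.0 for pid in table.participant_ids},
                    _fixed_spec(1.0, 1.0, 0.0, mean=0.0))
    with pytest.raises(NumericalError, match="jitter"):
        model.predict(table)


def test_constant_feature_rejected():
    X = np.column_stack([np.arange(8.0), np.full(8, 3.0)])
    table = _table(X)
    with pytest.raises(ValidationError, match="volume_f001"):
        fit_gpr(table, {pid: 40.0 + i for i, pid in
                        enumerate(table.participant_ids)}, GPRSpec(optimize=False,
                        hyperparameter_init={"lengthscale": 1, "signal_sd": 1,
                                             "noise_sd": 1}))


def test_identical_queries_get_identical_predictions():
    rng = np.random.default_rng(8)
    X, y = rng.normal(size=(10, 2)), rng.uniform(20, 80, 10)
    table = _table(X)
    model = fit_gpr(table, dict(zip(table.participant_ids, y)),
                    _fixed_spec(1.0, 2.0, 1.0))
    q = rng.normal(size=(1, 2))
    twice = model.predict_matrix(np.vstack([q, q]))
    assert twice[0] == twice[1]


def test_optimizer_improves_marginal_likelihood():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(30, 3))
    y = 40 + 5 * X[:, 0] + rng.normal(0, 1, 30)
    table = _table(X)
    model = fit_gpr(table, dict(zip(table.participant_ids, y)), GPRSpec())
    from scipy.spatial.distance import cdist

    Xs = (X - model.x_mean) / model.x_sd
    D = cdist(Xs, Xs)
    start = np.log([np.median(D[D > 0]), np.var(y), 0.1 * np.var(y)])
    nll_start, _ = _nll(start, D, y, model.jitter)
    assert model.log_marginal_likelihood >= -nll_start - 1e-9


# --------------------------------------------------------------------------
# evaluate / repeated CV


@pytest.mark.parametrize(
    "ages, preds, mae, r",
    [
        ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 0.0, 1.0),
        ((1.0, 2.0, 3.0), (2.0, 3.0, 4.0), 1.0, 1.0),
        ((1.0, 2.0, 3.0, 4.0), (4.0, 3.0, 2.0, 1.0), 2.0, -1.0),
    ],
)
def test_evaluate_known_cases(ages, preds, mae, r):
    ids = [f"S{i}" for i in range(len(ages))]
    got_mae, got_r = evaluate(dict(zip(ids, preds)), dict(zip(ids, ages)))
    assert got_mae == pytest.approx(mae, abs=1e-12)
    assert got_r == pytest.approx(r, abs=1e-12)


def test_evaluate_zero_variance_is_an_error():
    ids = ["a", "b", "c"]
    with pytest.raises(ValueError, match="variance"):
        evaluate(dict.fromkeys(ids, 50.0), dict(zip(ids, [40.0, 50.0, 60.0])))


def _affine_cohort(n=40, seed=11):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 80, n)
    X = np.column_stack([ages * s + o for s, o in ((-0.8, 90), (0.5, 10), (-1.2, 150))])
    table = _table(X)
    return table, dict(zip(table.participant_ids, ages))


def test_noiseless_affine_cv_is_nearly_perfect():
    table, ages = _affine_cohort()
    report = repeated_cv(table, ages, GPRSpec(n_restarts=1), n_folds=5,
                         n_repeats=2, seed=0)
    assert max(report.maes) < 0.5
    assert min(report.rs) > 0.99


def test_holdout_prediction_on_noiseless_affine_data():
    table, ages = _affine_cohort(n=60)
    train_ids = table.participant_ids[:45]
    test_ids = table.participant_ids[45:]
    model = fit_gpr(table.restrict(train_ids), ages, GPRSpec(n_restarts=1))
    preds = predict_brain_age(model, table.restrict(test_ids))
    mae = np.mean([abs(preds[i] - ages[i]) for i in test_ids])
    assert mae < 0.5


def test_repeated_cv_deterministic_and_ci_consistent():
    table, ages = _affine_cohort(n=30, seed=21)
    spec = _fixed_spec(5.0, 20.0, 1.0)
    rep_a = repeated_cv(table, ages, spec, n_folds=5, n_repeats=3, seed=7)
    rep_b = repeated_cv(table, ages, spec, n_folds=5, n_repeats=3, seed=7)
    assert rep_a.maes == rep_b.maes and rep_a.rs == rep_b.rs
    s = rep_a.summary()
    arr = np.asarray(rep_a.maes)
    half = 1.96 * arr.std(ddof=1) / np.sqrt(arr.size)
    assert s["mae"]["ci_low"] == pytest.approx(arr.mean() - half, abs=1e-12)
    assert s["mae"]["ci_high"] == pytest.approx(arr.mean() + half, abs=1e-12)


def test_single_repeat_equals_single_kfold_run():
    table, ages = _affine_cohort(n=25, seed=31)
    spec = GPRSpec(standardize=False, optimize=False, jitter=0.0,
                   hyperparameter_init={"lengthscale": 5.0, "signal_sd": 20.0,
                                        "noise_sd": 1.0})
    report = repeated_cv(table, ages, spec, n_folds=5, n_repeats=1, seed=13)
    oof = kfold_oof(table, ages, spec, n_folds=5, seed=[13, 0])
    mae, r = evaluate(oof, ages)
    assert report.maes[0] == pytest.approx(mae, abs=1e-12)
    assert report.rs[0] == pytest.approx(r, abs=1e-12)
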