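"""NIPALS PLS-DA core: OLS equivalences, quality indices, VIP identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gaitbattery import plsda
from gaitbattery.types import GaitError


def _random_problem(seed, n=30, p=6, separation=0.0):
    rng = np.random.default_rng(seed)
    labels = np.array(["PD"] * (n // 2) + ["CL"] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[labels == "PD", :2] += separation
    return X, labels


def test_single_predictor_equals_univariate_ols():
    X, labels = _random_problem(0, p=1)
    Y = plsda.one_hot(labels)
    model = plsda.fit_nipals(X, Y, 1)
    yhat, _ = plsda.predict(model, X)
    # univariate least squares on the scaled predictor
    xs = (X[:, 0] - X[:, 0].mean()) / X[:, 0].std(ddof=1)
    Yc = Y - Y.mean(axis=0)
    beta = xs @ Yc / (xs @ xs)
    ols = np.outer(xs, beta) + Y.mean(axis=0)
    assert np.max(np.abs(yhat - ols)) < 1e-10


def test_full_rank_fit_equals_ols():
    X, labels = _random_problem(1, n=20, p=5)
    Y = plsda.one_hot(labels)
    model = plsda.fit_nipals(X, Y, 5)
    yhat, _ = plsda.predict(model, X)
    ones = np.ones((len(X), 1))
    design = np.hstack([ones, X])
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    assert np.max(np.abs(yhat - design @ beta)) < 1e-8


def test_score_columns_orthogonal():
    X, labels = _random_problem(2, n=40, p=12)
    model = plsda.fit_nipals(X, plsda.one_hot(labels), 5)
    gram = model.T.T @ model.T
    off = gram - np.diag(np.diag(gram))
    assert np.max(np.abs(off)) < 1e-8
    # weight vectors are unit norm
    assert np.linalg.norm(model.W, axis=0) == pytest.approx(1.0, abs=1e-10)


def test_predict_reproduces_training_rows():
    X, labels = _random_problem(3, n=25, p=8)
    model = plsda.fit_nipals(X, plsda.one_hot(labels), 3)
    yhat_all, _ = plsda.predict(model, X)
    yhat_row, _ = plsda.predict(model, X[7:8])
    assert yhat_row[0] == pytest.approx(yhat_all[7], abs=1e-12)


def test_mean_row_predicts_class_proportions():
    X, labels = _random_problem(4, n=30, p=5)
    model = plsda.fit_nipals(X, plsda.one_hot(labels), 3)
    mean_row = model.x_scaler.means[None, :]
    yhat, _ = plsda.predict(model, mean_row)
    props = plsda.one_hot(labels).mean(axis=0)
    assert yhat[0] == pytest.approx(props, abs=1e-10)


def test_zero_variance_column_error_names_column():
    X, labels = _random_problem(5, n=20, p=4)
    X[:, 2] = 7.0
    with pytest.raises(GaitError, match="f2"):
        plsda.fit_nipals(X, plsda.one_hot(labels), 2,
                         columns=[f"f{j}" for j in range(4)])


def test_missing_values_imputed_by_training_median(caplog):
    X, labels = _random_problem(6, n=30, p=4)
    X[3, 1] = np.nan
    with caplog.at_level("INFO"):
        model = plsda.fit_nipals(X, plsda.one_hot(labels), 2,
                                 columns=list("abcd"))
    assert any("imputed" in r.message for r in caplog.records)
    imputed = model.x_scaler.impute(X)
    others = np.delete(X[:, 1], 3)
    assert imputed[3, 1] == pytest.approx(np.median(others))


def test_autoscale_round_trip():
    X, _ = _random_problem(7, n=40, p=6)
    scaler = plsda.Scaler().fit(X)
    Z = scaler.transform(X)
    assert np.max(np.abs(Z.mean(axis=0))) < 1e-9
    assert Z.std(axis=0, ddof=1) == pytest.approx(1.0, abs=1e-9)
    assert np.max(np.abs(scaler.inverse_transform(Z) - X)) < 1e-12


def test_null_labels_give_nonpositive_q2():
    neg = 0
    for seed in range(50):
        X, labels = _random_problem(seed + 100, n=40, p=10)
        q = plsda.cross_validated_quality(X, labels, A_max=3, k_folds=5,
                                          seed=seed)
        neg += np.all(q.q2 <= 0)
    assert neg / 50 >= 0.85


def test_separable_groups_give_high_q2():
    X, labels = _random_problem(8, n=60, p=10, separation=3.0)
    q = plsda.cross_validated_quality(X, labels, A_max=3, k_folds=7)
    assert q.q2[1] > 0.5


def test_quality_curve_shapes():
    X, labels = _random_problem(9, n=50, p=12, separation=1.0)
    q = plsda.cross_validated_quality(X, labels, A_max=5, k_folds=5)
    assert np.all(np.diff(q.r2y) >= -1e-12)
    assert np.all(np.diff(q.r2x) >= -1e-12)
    assert np.all((q.r2x >= 0) & (q.r2x <= 1))
    assert np.all((q.r2y >= 0) & (q.r2y <= 1))
    assert np.all(q.q2 <= q.r2y + 1e-6)


def test_component_selection_plateau_rule():
    mq = plsda.ModelQuality(q2=np.array([0.40, 0.55, 0.56, 0.56]),
                            r2x=np.zeros(4), r2y=np.zeros(4))
    assert plsda.select_components(mq) == 2
    rising = plsda.ModelQuality(q2=np.array([0.2, 0.4, 0.6]),
                                r2x=np.zeros(3), r2y=np.zeros(3))
    assert plsda.select_components(rising) == 3


def test_vip_identities():
    X, labels = _random_problem(10, n=40, p=9, separation=0.8)
    model = plsda.fit_nipals(X, plsda.one_hot(labels), 4)
    for a in range(1, 5):
        v = plsda.vip_scores(model, a)
        assert np.sum(v**2) == pytest.approx(9.0, abs=1e-8)
    # single predictor: VIP forced to exactly 1
    X1, lab1 = _random_problem(11, p=1)
    m1 = plsda.fit_nipals(X1, plsda.one_hot(lab1), 1)
    assert plsda.vip_scores(m1) == pytest.approx([1.0], abs=1e-12)


def test_vip_ranks_informative_features_first():
    rng = np.random.default_rng(12)
    n = 60
    labels = np.array(["PD"] * 30 + ["CL"] * 30)
    informative = rng.normal(size=(n, 5)) + \
        2.0 * (labels == "PD")[:, None]
    noise = rng.normal(size=(n, 20))
    X = np.hstack([informative, noise])
    names = [f"sig{j}" for j in range(5)] + [f"noise{j}" for j in range(20)]
    model = plsda.fit_nipals(X, plsda.one_hot(labels), 3, columns=names)
    table = plsda.vip_table(model, names)
    top5 = set(table.head(5)["feature"])
    assert sum(name.startswith("sig") for name in top5) >= 4


def test_column_mismatch_rejected():
    X, labels = _random_problem(13, n=20, p=3)
    model = plsda.fit_nipals(X, plsda.one_hot(labels), 2,
                             columns=["a", "b", "c"])
    with pytest.raises(GaitError, match="mismatch"):
        plsda.predict(model, X, columns=["a", "b", "z"])


def test_stratification_guard():
    X, _ = _random_problem(14, n=20, p=4)
    labels = np.array(["PD"] * 3 + ["CL"] * 17)
    with pytest.raises(Exception):
        plsda.cross_validated_quality(X, labels, A_max=2, k_folds=7)


def test_permuted_labels_classify_at_chance():
    """Permutation sanity: median pooled-CV accuracy near 50%."""
    from sklearn.model_selection import StratifiedKFold

    X, labels = _random_problem(15, n=56, p=15, separation=1.5)
    rng = np.random.default_rng(16)
    accs = []
    for _ in range(200):
        perm = rng.permutation(labels)
        skf = StratifiedKFold(n_splits=7, shuffle=True, random_state=1)
        correct = 0
        for train, test in skf.split(X, perm):
            model = plsda.fit_nipals(X[train], plsda.one_hot(perm[train]), 2)
            _, pred = plsda.predict(model, X[test])
            correct += int(np.sum(pred == perm[test]))
        accs.append(correct / len(labels))
    assert abs(np.median(accs) - 0.5) <= 0.05


def test_model_serialization_round_trip(tmp_path):
    X, labels = _random_problem(17, n=30, p=6, separation=1.0)
    model = plsda.fit_nipals(X, plsda.one_hot(labels), 3,
                             columns=[f"f{j}" for j in range(6)])
    plsda.save_model(model, tmp_path)
    back = plsda.load_model(tmp_path)
    yhat_a, _ = plsda.predict(model, X)
    yhat_b, _ = plsda.predict(back, X)
    assert np.max(np.abs(yhat_a - yhat_b)) < 1e-12
    assert back.columns == model.columns
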