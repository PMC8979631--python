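"""Battery evaluation: ROC/AUC, classification metrics, group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitbattery import evaluation as ev
from gaitbattery.features import registry
from gaitbattery.types import GaitError


def test_perfect_separation_gives_auc_one():
    scores = np.array([3.0, 2.5, 2.0, -1.0, -2.0])
    labels = np.array(["PD", "PD", "PD", "CL", "CL"])
    assert ev.roc_auc(scores, labels) == 1.0
    assert ev.roc_auc(-scores, labels) == 0.0


def test_random_scores_give_chance_auc():
    aucs = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        labels = np.where(rng.random(60) < 0.5, "PD", "CL")
        if len(set(labels)) < 2:
            continue
        aucs.append(ev.roc_auc(scores, labels))
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_auc_equals_mann_whitney_with_ties():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, size=40).astype(float)  # heavy ties
        labels = np.array(["PD"] * 22 + ["CL"] * 18)
        rng.shuffle(labels)
        auc = ev.roc_auc(scores, labels)
        u = stats.mannwhitneyu(scores[labels == "PD"],
                               scores[labels == "CL"],
                               alternative="two-sided").statistic
        assert auc == pytest.approx(u / (22 * 18), abs=1e-12)


def test_single_class_rejected():
    with pytest.raises(GaitError):
        ev.roc_auc(np.arange(4.0), np.array(["PD"] * 4))


def test_welch_t_matches_closed_form_from_summary_stats():
    rng = np.random.default_rng(21)
    x = rng.normal(1.0, 2.0, size=10)
    y = rng.normal(0.0, 1.0, size=10)
    df = pd.DataFrame({"f": np.concatenate([x, y])})
    labels = np.array(["PD"] * 10 + ["CL"] * 10)
    out = ev.group_compare(df, labels).iloc[0]
    # closed-form Welch statistic from the summary statistics
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    t_ref = (x.mean() - y.mean()) / np.sqrt(vx / 10 + vy / 10)
    nu = (vx / 10 + vy / 10) ** 2 / (
        (vx / 10) ** 2 / 9 + (vy / 10) ** 2 / 9)
    p_ref = 2 * stats.t.sf(abs(t_ref), nu)
    assert out["t"] == pytest.approx(t_ref, abs=1e-6)
    assert out["p"] == pytest.approx(p_ref, abs=1e-6)
    assert out["z_score"] == pytest.approx(
        (x.mean() - y.mean()) / y.std(ddof=1), abs=1e-10)


def test_identical_groups_are_null():
    vals = np.arange(10.0)
    df = pd.DataFrame({"f": np.concatenate([vals, vals])})
    labels = np.array(["PD"] * 10 + ["CL"] * 10)
    out = ev.group_compare(df, labels).iloc[0]
    assert out["t"] == pytest.approx(0.0, abs=1e-12)
    assert out["p"] == pytest.approx(1.0, abs=1e-12)
    assert out["z_score"] == pytest.approx(0.0, abs=1e-12)


def test_zero_control_sd_gives_missing_z(caplog):
    df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 5.0, 5.0, 5.0]})
    labels = np.array(["PD"] * 3 + ["CL"] * 3)
    with caplog.at_level("WARNING"):
        out = ev.group_compare(df, labels).iloc[0]
    assert np.isnan(out["z_score"])


def test_planted_one_sd_effect_recovers_unit_z():
    zs = []
    for seed in range(20):
        rng = np.random.default_rng(seed + 300)
        pd_vals = rng.normal(1.0, 1.0, size=81)
        cl_vals = rng.normal(0.0, 1.0, size=61)
        df = pd.DataFrame({"f": np.concatenate([pd_vals, cl_vals])})
        labels = np.array(["PD"] * 81 + ["CL"] * 61)
        zs.append(ev.group_compare(df, labels).iloc[0]["z_score"])
    assert np.mean(zs) == pytest.approx(1.0, abs=0.15)


def _dummy_features(n=4):
    rng = np.random.default_rng(0)
    data = rng.normal(size=(n, registry.N_GAIT_FEATURES))
    return pd.DataFrame(data, columns=list(registry.FEATURE_NAMES))


def _dummy_dem(n=4):
    return pd.DataFrame({
        "age": 70.0, "sex": [1.0, 0.0] * (n // 2), "height": 1.7,
        "weight": 75.0, "bmi": 75.0 / 1.7**2, "moca": 27.0,
    }, index=range(n))


@pytest.mark.parametrize("subset,expected", [
    ("spatiotemporal", 25), ("spatiotemporal_dem", 31),
    ("signal_based", 185), ("signal_based_dem", 191),
    ("all_gait", 210), ("all_gait_dem", 216),
])
def test_battery_subset_column_counts(subset, expected):
    X = ev.design_matrix(_dummy_features(), _dummy_dem(), subset)
    assert X.shape[1] == expected


def test_unknown_subset_rejected():
    with pytest.raises(GaitError, match="unknown model subset"):
        ev.design_matrix(_dummy_features(), _dummy_dem(), "everything")


def test_confusion_matrix_identities(small_cohort, small_cohort_features):
    from gaitbattery.pipeline import demographics_design

    feats = small_cohort_features
    dem = demographics_design(small_cohort.demographics_frame)
    labels = feats["group"].to_numpy()
    report = ev.run_battery(feats, dem, labels, subsets=["all_gait"],
                            k_folds=4, a_max=4)["all_gait"]
    n = len(labels)
    assert report.tp + report.fp + report.tn + report.fn == n
    assert report.accuracy == pytest.approx(
        100.0 * (report.tp + report.tn) / n, abs=1e-9)
    assert report.sensitivity == pytest.approx(
        100.0 * report.tp / (report.tp + report.fn), abs=1e-9)
    assert report.specificity == pytest.approx(
        100.0 * report.tn / (report.tn + report.fp), abs=1e-9)
    assert 0 <= report.auc <= 100


def test_battery_deterministic(small_cohort, small_cohort_features):
    from gaitbattery.pipeline import demographics_design

    feats = small_cohort_features
    dem = demographics_design(small_cohort.demographics_frame)
    labels = feats["group"].to_numpy()
    kw = dict(subsets=["spatiotemporal"], k_folds=4, a_max=3)
    a = ev.run_battery(feats, dem, labels, **kw)["spatiotemporal"]
    b = ev.run_battery(feats, dem, labels, **kw)["spatiotemporal"]
    assert ev.battery_frame({"m": a}).to_csv() == \
        ev.battery_frame({"m": b}).to_csv()


def test_holdout_mode_runs(small_cohort, small_cohort_features):
    from gaitbattery.pipeline import demographics_design

    feats = small_cohort_features
    dem = demographics_design(small_cohort.demographics_frame)
    labels = feats["group"].to_numpy()
    report = ev.evaluate_subset(
        ev.design_matrix(feats, dem, "all_gait"), labels, "all_gait",
        k_folds=4, a_max=3, mode="holdout", test_size=0.4)
    assert 0 <= report.accuracy <= 100


def test_correlation_matrix_shape():
    feats = _dummy_features(n=30)
    sel = list(registry.FEATURE_NAMES[:5])
    corr = ev.correlation_matrix(feats, sel)
    assert corr.shape == (5, 5)
    assert np.allclose(np.diag(corr), 1.0)
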