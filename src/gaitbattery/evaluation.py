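"""Model battery, classification metrics, and group statistics.

Six PLS-DA models are fitted on nested feature subsets (spatiotemporal
alone, signal-based alone, all gait characteristics, each with and
without the six demographic covariates).  Metrics are computed on pooled
out-of-fold cross-validated predictions: accuracy, sensitivity and
specificity with PD as the positive class, and the area under the ROC
curve.  A held-out-split mode is also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features.registry import DOMAIN_OF, features_in_domains
from .plsda import (
    CLASSES,
    DEFAULT_CV_SEED,
    DEFAULT_K_FOLDS,
    GaitError,
    PLSModel,
    cross_validated_quality,
    fit_nipals,
    one_hot,
    predict,
    select_components,
    vip_table,
)
from .types import DEMOGRAPHIC_COLUMNS

logger = logging.getLogger(__name__)

SIGNAL_DOMAINS = ("frequency", "regularity", "magnitude", "complexity")

MODEL_SUBSETS = {
    "spatiotemporal": {"domains": ("spatiotemporal",), "dem": False},
    "spatiotemporal_dem": {"domains": ("spatiotemporal",), "dem": True},
    "signal_based": {"domains": SIGNAL_DOMAINS, "dem": False},
    "signal_based_dem": {"domains": SIGNAL_DOMAINS, "dem": True},
    "all_gait": {"domains": ("spatiotemporal",) + SIGNAL_DOMAINS,
                 "dem": False},
    "all_gait_dem": {"domains": ("spatiotemporal",) + SIGNAL_DOMAINS,
                     "dem": True},
}


@dataclass
class ClassificationReport:
    model_name: str
    n_components: int
    accuracy: float  # %
    sensitivity: float  # %, PD positive
    specificity: float  # %
    auc: float  # %
    tp: int
    fp: int
    tn: int
    fn: int
    n_features: int
    roc_curve: pd.DataFrame = field(repr=False, default=None)

    def as_row(self) -> dict:
        return {
            "model": self.model_name, "n_features": self.n_features,
            "n_components": self.n_components,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity, "auc_pct": self.auc,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def roc_auc(scores: np.ndarray, labels,
            return_curve: bool = False):
    """Trapezoidal AUC over all thresholds; tied scores contribute half.

    Higher scores must indicate the positive (PD) class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == CLASSES[0]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise GaitError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted, pos_sorted = scores[order], pos[order]
    # cumulative counts at each unique threshold (descending)
    boundaries = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([boundaries, [len(s_sorted) - 1]])
    tp = np.concatenate([[0], np.cumsum(pos_sorted)[cut]])
    fp = np.concatenate([[0], np.cumsum(~pos_sorted)[cut]])
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    if return_curve:
        return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return auc


def _metrics(y_true, y_pred, scores) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == "PD") & (y_pred == "PD")))
    fn = int(np.sum((y_true == "PD") & (y_pred == "CL")))
    tn = int(np.sum((y_true == "CL") & (y_pred == "CL")))
    fp = int(np.sum((y_true == "CL") & (y_pred == "PD")))
    n = len(y_true)
    auc, curve = roc_auc(scores, y_true, return_curve=True)
    return {
        "accuracy": 100.0 * (tp + tn) / n,
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
        "auc": 100.0 * auc,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn, "roc": curve,
    }


def design_matrix(features: pd.DataFrame, demographics: pd.DataFrame | None,
                  subset: str) -> pd.DataFrame:
    """Column block for one of the six battery models."""
    if subset not in MODEL_SUBSETS:
        raise GaitError(f"unknown model subset {subset!r}; "
                        f"known: {sorted(MODEL_SUBSETS)}")
    spec = MODEL_SUBSETS[subset]
    cols = features_in_domains(spec["domains"])
    X = features[cols].copy()
    if spec["dem"]:
        if demographics is None:
            raise GaitError(f"subset {subset!r} needs demographics")
        dem = demographics[list(DEMOGRAPHIC_COLUMNS)]
        X = pd.concat([X.reset_index(drop=True),
                       dem.reset_index(drop=True)], axis=1)
    return X


def evaluate_subset(X: pd.DataFrame, labels, name: str,
                    k_folds: int = DEFAULT_K_FOLDS,
                    seed: int = DEFAULT_CV_SEED,
                    a_max: int = 10,
                    mode: str = "cv",
                    test_size: float = 0.3) -> ClassificationReport:
    """Fit/evaluate one battery model.

    mode='cv' (default): component count from the Q2 plateau, metrics on
    pooled out-of-fold predictions refitting scaling per fold.
    mode='holdout': single stratified train/test split.
    """
    labels = np.asarray(labels)
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    quality = cross_validated_quality(Xv, labels, A_max=a_max,
                                      k_folds=k_folds, seed=seed,
                                      columns=cols)
    a_star = select_components(quality)

    if mode == "holdout":
        idx_tr, idx_te = train_test_split(
            np.arange(len(labels)), test_size=test_size, random_state=seed,
            stratify=labels)
        model = fit_nipals(Xv[idx_tr], one_hot(labels[idx_tr]),
                           min(a_star, len(idx_tr) - 1), columns=cols)
        yhat, pred = predict(model, Xv[idx_te], a=model.n_components)
        m = _metrics(labels[idx_te], pred, yhat[:, 0] - yhat[:, 1])
    elif mode == "cv":
        scores = np.zeros(len(labels))
        pred = np.empty(len(labels), dtype=object)
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=seed)
        for train, test in skf.split(Xv, labels):
            a_fold = min(a_star, len(train) - 1)
            model = fit_nipals(Xv[train], one_hot(labels[train]), a_fold,
                               columns=cols)
            yhat, lab = predict(model, Xv[test], a=a_fold)
            scores[test] = yhat[:, 0] - yhat[:, 1]
            pred[test] = lab
        m = _metrics(labels, pred.astype(str), scores)
    else:
        raise GaitError(f"unknown evaluation mode {mode!r}")
    return ClassificationReport(
        model_name=name, n_components=a_star, accuracy=m["accuracy"],
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        auc=m["auc"], tp=m["tp"], fp=m["fp"], tn=m["tn"], fn=m["fn"],
        n_features=X.shape[1], roc_curve=m["roc"])


def run_battery(features: pd.DataFrame, demographics: pd.DataFrame,
                labels, subsets=None,
                k_folds: int = DEFAULT_K_FOLDS, seed: int = DEFAULT_CV_SEED,
                a_max: int = 10, mode: str = "cv"
                ) -> dict[str, ClassificationReport]:
    """Run the (up to six) subset models and return their reports."""
    subsets = list(subsets) if subsets is not None else list(MODEL_SUBSETS)
    reports = {}
    for name in subsets:
        X = design_matrix(features, demographics, name)
        reports[name] = evaluate_subset(X, labels, name, k_folds=k_folds,
                                        seed=seed, a_max=a_max, mode=mode)
        logger.info("model %-20s p=%3d A*=%d acc=%.1f%% auc=%.1f%%",
                    name, X.shape[1], reports[name].n_components,
                    reports[name].accuracy, reports[name].auc)
    return reports


def battery_frame(reports: dict[str, ClassificationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports.values()])


def fit_overall_model(features: pd.DataFrame, demographics: pd.DataFrame,
                      labels, subset: str = "all_gait_dem",
                      k_folds: int = DEFAULT_K_FOLDS,
                      seed: int = DEFAULT_CV_SEED, a_max: int = 10
                      ) -> tuple[PLSModel, pd.DataFrame]:
    """Full-data fit of one subset plus its VIP ranking table."""
    X = design_matrix(features, demographics, subset)
    quality = cross_validated_quality(X.to_numpy(float), labels, A_max=a_max,
                                      k_folds=k_folds, seed=seed,
                                      columns=list(X.columns))
    a_star = select_components(quality)
    model = fit_nipals(X.to_numpy(float), one_hot(labels), a_star,
                       columns=list(X.columns))
    domains = dict(DOMAIN_OF)
    domains.update({c: "demographics" for c in DEMOGRAPHIC_COLUMNS})
    return model, vip_table(model, list(X.columns), domains)


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def group_compare(features: pd.DataFrame, labels,
                  correction: str | None = None) -> pd.DataFrame:
    """Welch two-sample t-test per feature plus PD z-scores vs control.

    z = (mean_PD - mean_CL) / SD_CL.  No multiple-testing correction by
    default; correction='bh' applies Benjamini-Hochberg to the p-values.
    """
    labels = np.asarray(labels)
    pd_mask = labels == "PD"
    cl_mask = labels == "CL"
    if pd_mask.sum() < 2 or cl_mask.sum() < 2:
        raise GaitError("group_compare requires >= 2 subjects per group")
    rows = []
    for col in features.columns:
        x = features.loc[pd_mask, col].to_numpy(dtype=float)
        y = features.loc[cl_mask, col].to_numpy(dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if len(x) < 2 or len(y) < 2:
            rows.append({"feature": col, "mean_pd": np.nan, "sd_pd": np.nan,
                         "mean_cl": np.nan, "sd_cl": np.nan, "t": np.nan,
                         "p": np.nan, "z_score": np.nan})
            continue
        if np.allclose(x, x[0]) and np.allclose(y, y[0]) and x[0] == y[0]:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
        sd_cl = float(np.std(y, ddof=1))
        if sd_cl == 0:
            logger.warning("zero control SD for %s; z-score missing", col)
            z = np.nan
        else:
            z = (float(np.mean(x)) - float(np.mean(y))) / sd_cl
        rows.append({
            "feature": col,
            "mean_pd": float(np.mean(x)), "sd_pd": float(np.std(x, ddof=1)),
            "mean_cl": float(np.mean(y)), "sd_cl": sd_cl,
            "t": float(t), "p": float(p), "z_score": z,
        })
    df = pd.DataFrame(rows)
    if correction == "bh":
        p = df["p"].to_numpy()
        ok = np.isfinite(p)
        m = ok.sum()
        order = np.argsort(p[ok])
        adj = np.empty(m)
        ranked = p[ok][order] * m / (np.arange(m) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.full(len(p), np.nan)
        out[ok] = np.minimum(adj, 1.0)
        df["p_adj"] = out
    return df


def correlation_matrix(features: pd.DataFrame, selected) -> pd.DataFrame:
    """Pearson correlations among a set of (VIP-selected) features."""
    return features[list(selected)].corr(method="pearson")
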