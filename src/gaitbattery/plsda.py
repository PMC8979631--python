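"""Partial least squares discriminant analysis, implemented from scratch.

PLS-DA regresses a column-centred one-hot class matrix Y (n x 2, classes
PD and CL) on autoscaled predictors X via NIPALS, selects the number of
latent components from the cross-validated predictive index Q2, and
ranks predictors with the variable-importance-in-projection (VIP) score.
Only the cross-validation fold scaffolding comes from scikit-learn; the
decomposition, quality indices and VIP are implemented here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .types import GaitError

logger = logging.getLogger(__name__)

CLASSES = ("PD", "CL")
DEFAULT_K_FOLDS = 7
DEFAULT_CV_SEED = 20200214
Q2_PLATEAU_DELTA = 0.01
MAX_COMPONENTS = 10
NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


# --------------------------------------------------------------------------
# scaling / coding
# --------------------------------------------------------------------------

@dataclass
class Scaler:
    """Column mean/SD autoscaling with training-set median imputation."""

    means: np.ndarray = None
    sds: np.ndarray = None
    medians: np.ndarray = None
    columns: tuple = ()

    def fit(self, X: np.ndarray, columns=None) -> "Scaler":
        X = np.asarray(X, dtype=float)
        self.medians = np.nanmedian(X, axis=0)
        n_missing = np.isnan(X).sum(axis=0)
        for j in np.nonzero(n_missing)[0]:
            name = columns[j] if columns is not None else f"column {j}"
            logger.info("imputed %d missing values in %s by training median",
                        n_missing[j], name)
        Xf = self.impute(X)
        self.means = Xf.mean(axis=0)
        self.sds = Xf.std(axis=0, ddof=1)
        zero = np.nonzero(self.sds == 0)[0]
        if len(zero):
            names = ([columns[j] for j in zero] if columns is not None
                     else list(zero))
            raise GaitError(f"zero-variance column(s) in X: {names[:10]}")
        self.columns = tuple(columns) if columns is not None else ()
        return self

    def impute(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=float)
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.medians, X.shape)[nan]
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (self.impute(X) - self.means) / self.sds

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sds + self.means


def one_hot(labels) -> np.ndarray:
    """n x 2 one-hot coding in class order (PD, CL)."""
    labels = np.asarray(labels)
    unknown = set(labels) - set(CLASSES)
    if unknown:
        raise GaitError(f"unknown class labels: {sorted(unknown)}")
    return np.column_stack([(labels == c).astype(float) for c in CLASSES])


# --------------------------------------------------------------------------
# NIPALS fit / predict
# --------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted PLS-DA decomposition.

    W: p x A unit-norm X-weights; P: p x A X-loadings; Q: A x 2
    Y-loadings; T: n x A scores; ssy: per-component explained Y sum of
    squares (q_a'q_a * t_a't_a).
    """

    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    ssy: np.ndarray
    x_scaler: Scaler
    y_means: np.ndarray
    columns: tuple = ()
    ssx_total: float = 0.0
    ssy_total: float = 0.0
    ssx_per_component: np.ndarray = None

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def coefficients(self, a: int | None = None) -> np.ndarray:
        a = a or self.n_components
        W, P, Q = self.W[:, :a], self.P[:, :a], self.Q[:a, :]
        return W @ np.linalg.solve(P.T @ W, Q)


def fit_nipals(X: np.ndarray, Y: np.ndarray, A: int,
               scaler: Scaler | None = None,
               columns=None) -> PLSModel:
    """NIPALS PLS2 on autoscaled X and column-centred Y with A components.

    X is raw (possibly with NaNs): autoscaling and median imputation are
    fitted here unless a pre-fitted scaler is supplied.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if scaler is None:
        scaler = Scaler().fit(X, columns=columns)
    Xs = scaler.transform(X)
    y_means = Y.mean(axis=0)
    Yc = Y - y_means
    n, p = Xs.shape
    if A > min(n - 1, p):
        raise GaitError(f"A={A} exceeds the rank bound min(n-1, p)")

    ssx_total = float(np.sum(Xs**2))
    ssy_total = float(np.sum(Yc**2))
    Xa, Ya = Xs.copy(), Yc.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((A, Y.shape[1]))
    T = np.zeros((n, A))
    ssy = np.zeros(A)
    ssx = np.zeros(A)
    for a in range(A):
        u = Ya[:, int(np.argmax(Ya.var(axis=0)))]
        t_old = None
        for it in range(NIPALS_MAX_ITER):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise GaitError("NIPALS weight collapsed to zero "
                                f"at component {a + 1}")
            w /= nw
            t = Xa @ w
            q = Ya.T @ t / (t @ t)
            u = Ya @ q
            if t_old is not None and \
                    np.linalg.norm(t - t_old) <= NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise GaitError(
                f"NIPALS did not converge in {NIPALS_MAX_ITER} iterations "
                f"at component {a + 1}")
        pvec = Xa.T @ t / (t @ t)
        Xa = Xa - np.outer(t, pvec)
        Ya = Ya - np.outer(t, q)
        W[:, a], P[:, a], Q[a, :], T[:, a] = w, pvec, q, t
        ssy[a] = float((q @ q) * (t @ t))
        ssx[a] = float((pvec @ pvec) * (t @ t))
    return PLSModel(W=W, P=P, Q=Q, T=T, ssy=ssy, x_scaler=scaler,
                    y_means=y_means,
                    columns=tuple(columns) if columns is not None else (),
                    ssx_total=ssx_total, ssy_total=ssy_total,
                    ssx_per_component=ssx)


def predict(model: PLSModel, X_new: np.ndarray,
            a: int | None = None, columns=None):
    """Continuous two-column scores and argmax class labels.

    Ties go to PD (and are logged): the clinical cost of a missed case
    exceeds that of a false alarm.
    """
    if columns is not None and model.columns and \
            tuple(columns) != model.columns:
        missing = set(model.columns) - set(columns)
        extra = set(columns) - set(model.columns)
        raise GaitError(
            f"column mismatch: missing={sorted(missing)[:5]}, "
            f"unexpected={sorted(extra)[:5]}")
    Xs = model.x_scaler.transform(np.asarray(X_new, dtype=float))
    yhat = Xs @ model.coefficients(a) + model.y_means
    ties = yhat[:, 0] == yhat[:, 1]
    if ties.any():
        logger.info("%d tied predictions assigned to PD", int(ties.sum()))
    labels = np.where(yhat[:, 0] >= yhat[:, 1], CLASSES[0], CLASSES[1])
    return yhat, labels


# --------------------------------------------------------------------------
# cross-validated quality and component selection
# --------------------------------------------------------------------------

@dataclass
class ModelQuality:
    """Per-component cumulative quality curves (index 0 = 1 component)."""

    q2: np.ndarray
    r2x: np.ndarray
    r2y: np.ndarray


def cross_validated_quality(X: np.ndarray, labels, A_max: int,
                            k_folds: int = DEFAULT_K_FOLDS,
                            seed: int = DEFAULT_CV_SEED,
                            columns=None) -> ModelQuality:
    """Q2(a) from stratified k-fold PRESS, R2X/R2Y(a) from the full fit.

    Autoscaling and imputation are refitted inside every training fold.
    """
    if k_folds < 2:
        raise GaitError("k_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    Y = one_hot(labels)
    n = len(Y)
    min_train = n - int(np.ceil(n / k_folds))
    A_max = max(1, min(A_max, X.shape[1], min_train - 1))

    press = np.zeros(A_max)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, labels):
        if len(set(labels[train])) < 2 or len(set(labels[test])) < 2:
            raise GaitError("a fold lost one of the classes; "
                            "stratification failed (reduce k_folds)")
        A_fold = min(A_max, len(train) - 1)
        model = fit_nipals(X[train], Y[train], A_fold, columns=columns)
        for a in range(1, A_max + 1):
            yhat, _ = predict(model, X[test], a=min(a, A_fold))
            press[a - 1] += float(np.sum((Y[test] - yhat) ** 2))
    ssy_tot = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    q2 = 1.0 - press / ssy_tot

    full = fit_nipals(X, Y, A_max, columns=columns)
    r2x = np.cumsum(full.ssx_per_component) / full.ssx_total
    r2y = np.cumsum(full.ssy) / full.ssy_total
    return ModelQuality(q2=q2, r2x=r2x, r2y=r2y)


def select_components(quality: ModelQuality) -> int:
    """Smallest a whose Q2 gain over the next component is < 0.01
    (plateau rule), capped at 10."""
    q2 = quality.q2
    for a in range(1, len(q2)):
        gain = q2[a] - q2[a - 1]
        # a gain of exactly 0.01 counts as plateau (guard float noise)
        if gain < Q2_PLATEAU_DELTA or np.isclose(gain, Q2_PLATEAU_DELTA,
                                                 atol=1e-9):
            return min(a, MAX_COMPONENTS)
    return min(len(q2), MAX_COMPONENTS)


# --------------------------------------------------------------------------
# VIP
# --------------------------------------------------------------------------

def vip_scores(model: PLSModel, a: int | None = None) -> np.ndarray:
    """Cumulative-at-a VIP: sqrt(p * sum_b ssy_b w_jb^2 / sum_b ssy_b)."""
    a = a or model.n_components
    W = model.W[:, :a]
    ssy = model.ssy[:a]
    p = W.shape[0]
    w2 = W**2  # columns already unit norm
    return np.sqrt(p * (w2 @ ssy) / ssy.sum())


def vip_table(model: PLSModel, feature_names=None,
              domains: dict | None = None) -> pd.DataFrame:
    """Per-feature VIP at each component count plus the average VIP
    across components (the ranking criterion) and the resulting rank."""
    A = model.n_components
    names = list(feature_names) if feature_names is not None else \
        (list(model.columns) or [f"x{j}" for j in range(model.W.shape[0])])
    per_a = np.column_stack([vip_scores(model, a) for a in range(1, A + 1)])
    avg = per_a.mean(axis=1)
    df = pd.DataFrame(per_a, columns=[f"vip_comp{a}" for a in range(1, A + 1)])
    df.insert(0, "feature", names)
    if domains is not None:
        df.insert(1, "domain", [domains.get(n, "") for n in names])
    df["vip_average"] = avg
    df = df.sort_values("vip_average", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_model(model: PLSModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_components": model.n_components,
        "classes": list(CLASSES),
        "y_means": model.y_means.tolist(),
        "columns": list(model.columns),
        "scaler_means": model.x_scaler.means.tolist(),
        "scaler_sds": model.x_scaler.sds.tolist(),
        "scaler_medians": model.x_scaler.medians.tolist(),
        "ssy": model.ssy.tolist(),
        "ssx_per_component": model.ssx_per_component.tolist(),
        "ssx_total": model.ssx_total,
        "ssy_total": model.ssy_total,
    }
    with open(out / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    for name, arr in (("W", model.W), ("P", model.P), ("Q", model.Q),
                      ("T", model.T)):
        np.savetxt(out / f"{name}.csv", arr, delimiter=",")
    return out


def load_model(model_dir: str | Path) -> PLSModel:
    d = Path(model_dir)
    with open(d / "model.json") as fh:
        meta = json.load(fh)
    arrs = {name: np.atleast_2d(np.loadtxt(d / f"{name}.csv", delimiter=","))
            for name in ("W", "P", "Q", "T")}
    scaler = Scaler(means=np.array(meta["scaler_means"]),
                    sds=np.array(meta["scaler_sds"]),
                    medians=np.array(meta["scaler_medians"]),
                    columns=tuple(meta["columns"]))
    return PLSModel(W=arrs["W"], P=arrs["P"], Q=arrs["Q"], T=arrs["T"],
                    ssy=np.array(meta["ssy"]), x_scaler=scaler,
                    y_means=np.array(meta["y_means"]),
                    columns=tuple(meta["columns"]),
                    ssx_total=meta["ssx_total"],
                    ssy_total=meta["ssy_total"],
                    ssx_per_component=np.array(meta["ssx_per_component"]))
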