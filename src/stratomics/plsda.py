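"""Multi-class PLS-DA: NIPALS PLS2 on autoscaled predictors against a
one-hot class matrix, stratified repeated k-fold cross-validation with
one-standard-error component selection, and Variable Importance in
Projection (VIP) scores.

Preprocessing (zero-variance column removal, centering, unit-variance
scaling) is part of the model and is refit inside every training fold, so
cross-validated accuracies carry no information leakage from test samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConfigError, DesignError

log = logging.getLogger("stratomics")


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS2 discriminant model.

    Weights ``W`` (unit columns), X-loadings ``P``, Y-loadings ``Q`` and
    scores ``T`` are stored per component; ``kept`` lists predictor columns
    surviving zero-variance removal, with their training means and SDs.
    """

    A: int
    class_levels: list
    kept: np.ndarray          # indices of retained predictor columns
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray             # (p, A)
    P: np.ndarray             # (p, A)
    Q: np.ndarray             # (c, A)
    T: np.ndarray             # (n, A)
    feature_names: list | None = None

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients mapping scaled X to centered Y."""
        return self.W @ np.linalg.solve(self.P.T @ self.W, self.Q.T)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float)[:, self.kept] - self.x_mean) / self.x_sd
        return Xs @ self.coef + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        yhat = self.decision_values(X)
        return np.asarray(self.class_levels, dtype=object)[np.argmax(yhat, axis=1)]


@dataclass
class CVResult:
    """Cross-validation curve and the oneSE-selected component count."""

    accuracy: pd.DataFrame    # columns A, repeat, fold, accuracy
    mean_accuracy: pd.Series  # index A
    se_accuracy: pd.Series
    chosen_A: int
    best_A: int
    seed: int


def _one_hot(labels) -> tuple[np.ndarray, list]:
    levels = sorted(set(labels))
    Y = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        Y[i, levels.index(lab)] = 1.0
    return Y, levels


def fit_plsda(X, labels, A: int, tol: float = 1e-12, maxiter: int = 5000
              ) -> PLSDAModel:
    """Fit a PLS2 discriminant model with A components by NIPALS.

    X is samples x features with no missing values; labels is the class
    vector (at least two classes). Zero-variance columns are removed, the
    rest autoscaled; Y is the column-centered one-hot class matrix. Each
    component iterates ``w = X'u / ||X'u||, t = Xw, q = Y't/t't, u = Yq/q'q``
    to convergence, then deflates X and Y by ``t``.
    """
    X = np.asarray(X, dtype=float)
    feature_names = None
    if isinstance(labels, pd.Series):
        labels = labels.to_numpy()
    if np.isnan(X).any():
        raise ValueError("X contains missing values; PLS-DA needs complete cases")
    Y, levels = _one_hot(labels)
    if len(levels) < 2:
        raise DesignError("need at least 2 classes")
    counts = pd.Series(list(labels)).value_counts()
    if (counts == 1).any():
        log.warning("classes with a single sample: %s",
                    counts.index[counts == 1].tolist())

    sd = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    Xs = X[:, kept]
    x_mean = Xs.mean(axis=0)
    x_sd = Xs.std(axis=0, ddof=1)
    Xc = (Xs - x_mean) / x_sd
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    n, p = Xc.shape
    max_A = min(n - 1, p)
    if A > max_A:
        raise DesignError(f"A={A} exceeds the model rank bound {max_A}")

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((Y.shape[1], A))
    T = np.zeros((n, A))
    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(A):
        u = Yd[:, np.argmax(Yd.var(axis=0))].copy()
        t_old = np.zeros(n)
        for _ in range(maxiter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            nq = q @ q
            if nq == 0:
                break
            u = Yd @ q / nq
            if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        pa = Xd.T @ t / (t @ t)
        Xd = Xd - np.outer(t, pa)
        Yd = Yd - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pa, q, t

    return PLSDAModel(A=A, class_levels=levels, kept=kept, x_mean=x_mean,
                      x_sd=x_sd, y_mean=y_mean, W=W, P=P, Q=Q, T=T,
                      feature_names=feature_names)


def vip_scores(model: PLSDAModel, scale_0_100: bool = True) -> pd.DataFrame:
    """Variable Importance in Projection for every retained predictor.

    ``VIP_j = sqrt(P * sum_a SSY_a w_aj^2 / sum_a SSY_a)`` with
    ``SSY_a = (t_a . t_a)(q_a . q_a)`` and P the number of retained
    predictors; mean squared VIP is 1 by construction. The scaled score is
    ``100 * VIP / max(VIP)``.
    """
    ssy = np.einsum("na,na->a", model.T, model.T) * np.einsum(
        "ca,ca->a", model.Q, model.Q)
    if not np.any(ssy > 0):
        raise ValueError("degenerate model: no explained Y variance")
    p = model.W.shape[0]
    vip = np.sqrt(p * (model.W ** 2 @ ssy) / ssy.sum())
    out = pd.DataFrame({"predictor": model.kept, "vip": vip})
    if scale_0_100:
        out["vip_scaled"] = 100.0 * vip / vip.max() if vip.max() > 0 else 0.0
    return out


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator
                      ) -> list[np.ndarray]:
    """Round-robin stratified fold assignment after per-class shuffling."""
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for lev in sorted(set(labels)):
        idx = np.flatnonzero(labels == lev)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset += len(idx)
    return [np.array(sorted(f), dtype=int) for f in folds]


def cross_validate_plsda(X, labels, k: int = 3, repeats: int = 15,
                         A_grid=None, seed: int = 0) -> CVResult:
    """Stratified repeated k-fold cross-validation over component counts.

    Accuracy is the classification metric. The oneSE choice is the smallest
    A whose mean accuracy is within one standard error (computed across all
    fold x repeat accuracies of the best A) of the best mean accuracy.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(list(labels), dtype=object)
    n = X.shape[0]
    if A_grid is None:
        A_grid = list(range(1, min(n - int(np.ceil(n / k)) - 1, X.shape[1], 10) + 1))
    A_grid = sorted(A_grid)
    if not A_grid:
        raise ConfigError("empty A grid")
    smallest_class = pd.Series(labels).value_counts().min()
    if k > smallest_class:
        log.warning("k=%d exceeds the smallest class count %d; folds will miss "
                    "classes", k, smallest_class)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        folds = _stratified_folds(labels, k, rng)
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            a_cap = min(len(train_idx) - 1, X.shape[1])
            model_cache: dict[int, PLSDAModel] = {}
            for A in A_grid:
                A_eff = min(A, a_cap)
                if A_eff not in model_cache:
                    model_cache[A_eff] = fit_plsda(X[train_idx], labels[train_idx],
                                                   A_eff)
                pred = model_cache[A_eff].predict(X[test_idx])
                acc = float(np.mean(pred == labels[test_idx]))
                rows.append((A, rep, fi, acc))
    acc = pd.DataFrame(rows, columns=["A", "repeat", "fold", "accuracy"])
    mean_acc = acc.groupby("A")["accuracy"].mean()
    best_A = int(mean_acc.idxmax())
    best = acc.loc[acc["A"] == best_A, "accuracy"]
    se_best = float(best.std(ddof=1) / np.sqrt(len(best))) if len(best) > 1 else 0.0
    se_acc = acc.groupby("A")["accuracy"].apply(
        lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
    threshold = mean_acc.loc[best_A] - se_best
    chosen = int(min(a for a in A_grid if mean_acc.loc[a] >= threshold))
    return CVResult(accuracy=acc, mean_accuracy=mean_acc, se_accuracy=se_acc,
                    chosen_A=chosen, best_A=best_A, seed=seed)
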