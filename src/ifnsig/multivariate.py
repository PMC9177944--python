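"""Sample-level ordination: PCA screening and OPLS-DA class separation.

The OPLS implementation follows the NIPALS orthogonal-projection scheme
for a single response: variation in X orthogonal to the class vector y is
iteratively removed (n_ortho components), then a single predictive
component is regressed on the deflated matrix.  Features are mean-centered
and unit-variance scaled (autoscaling) before fitting, the convention of
discriminant-analysis use of the method.  Predictive performance Q2 is
estimated by stratified 7-fold cross-validation with a fixed fold seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["pca", "OplsModel", "opls_fit", "opls_scores_plot_table"]


def pca(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """SVD principal components of a samples x features matrix.

    Columns are mean-centered; returns (scores, loadings,
    explained-variance ratios).  Sign convention: the largest-|loading|
    element of each component is positive.
    """
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    if n_components > min(n, m):
        raise ValueError(f"n_components={n_components} exceeds min(n_samples, n_features)={min(n, m)}")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(n_components):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :n_components] * S[:n_components]
    total_var = np.square(S).sum()
    evr = np.square(S[:n_components]) / total_var if total_var > 0 else np.zeros(n_components)
    idx = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(n)
    cols = matrix.columns if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(m)
    pc = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=idx, columns=pc),
        pd.DataFrame(Vt[:n_components].T, index=cols, columns=pc),
        evr,
    )


@dataclass
class OplsModel:
    """Fitted two-class OPLS-DA model."""

    sample_ids: list[str]
    feature_ids: list[str]
    y: np.ndarray  # 0/1 class vector
    y_mean: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    w: np.ndarray  # predictive weights
    p: np.ndarray  # predictive loadings
    c: float  # inner regression coefficient
    t_pred: np.ndarray  # predictive scores
    w_ortho: list[np.ndarray] = field(default_factory=list)
    p_ortho: list[np.ndarray] = field(default_factory=list)
    t_ortho: list[np.ndarray] = field(default_factory=list)
    r2y: float = np.nan
    q2: float = np.nan

    @property
    def n_ortho(self) -> int:
        return len(self.w_ortho)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_sd

    def transform(self, X_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(predictive score, orthogonal scores) for new samples."""
        X = self._scale(np.asarray(X_raw, dtype=float))
        t_os = []
        for w_o, p_o in zip(self.w_ortho, self.p_ortho):
            t_o = X @ w_o
            X = X - np.outer(t_o, p_o)
            t_os.append(t_o)
        t = X @ self.w
        return t, np.column_stack(t_os) if t_os else np.empty((len(X), 0))

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        t, _ = self.transform(X_raw)
        return t * self.c + self.y_mean


def _fit_core(X: np.ndarray, y_c: np.ndarray, n_ortho: int):
    """NIPALS O-PLS on pre-scaled X and centered y."""
    w_os, p_os, t_os = [], [], []
    Xd = X.copy()
    for _ in range(n_ortho):
        w = Xd.T @ y_c
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
    w = Xd.T @ y_c
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = float(y_c @ t / (t @ t))
    return w, p, c, t, w_os, p_os, t_os


def opls_fit(
    X: pd.DataFrame,
    y,
    n_ortho: int = 1,
    cv_folds: int = 7,
    cv_seed: int = 0,
) -> OplsModel:
    """Fit OPLS-DA on a samples x features matrix and binary labels.

    ``y`` may be 0/1 or two string labels (sorted order maps to 0/1).
    """
    Xdf = pd.DataFrame(X)
    y_arr = pd.Series(list(y))
    classes = sorted(y_arr.unique().tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y01 = (y_arr == classes[1]).to_numpy(dtype=float)
    if min((y01 == 0).sum(), (y01 == 1).sum()) < 3:
        raise ValueError("each class needs at least 3 samples")

    Xv = Xdf.to_numpy(dtype=float)
    sd = Xv.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant feature(s)", stacklevel=2)
        Xdf = Xdf.loc[:, ~constant]
        Xv = Xdf.to_numpy(dtype=float)
        sd = sd[~constant]
    mean = Xv.mean(axis=0)
    Xs = (Xv - mean) / sd
    y_mean = float(y01.mean())
    y_c = y01 - y_mean

    w, p, c, t, w_os, p_os, t_os = _fit_core(Xs, y_c, n_ortho)
    y_hat = t * c
    ss_y = float(y_c @ y_c)
    r2y = 1.0 - float((y_c - y_hat) @ (y_c - y_hat)) / ss_y

    model = OplsModel(
        sample_ids=list(Xdf.index),
        feature_ids=list(Xdf.columns),
        y=y01,
        y_mean=y_mean,
        x_mean=mean,
        x_sd=sd,
        w=w,
        p=p,
        c=c,
        t_pred=t,
        w_ortho=w_os,
        p_ortho=p_os,
        t_ortho=t_os,
        r2y=r2y,
    )
    model.q2 = _q2_cv(Xv, y01, n_ortho, cv_folds, cv_seed)
    return model


def _q2_cv(Xv: np.ndarray, y01: np.ndarray, n_ortho: int, folds: int, seed: int) -> float:
    """Stratified k-fold cross-validated Q2 (1 - PRESS/SS)."""
    rng = np.random.default_rng(seed)
    folds = int(min(folds, (y01 == 0).sum(), (y01 == 1).sum()))
    if folds < 2:
        return np.nan
    assign = np.empty(len(y01), dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y01 == cls)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    press = 0.0
    ss = 0.0
    for f in range(folds):
        test = assign == f
        train = ~test
        Xtr = Xv[train]
        sd = Xtr.std(axis=0, ddof=1)
        keep = sd > 0
        mean = Xtr[:, keep].mean(axis=0)
        Xs = (Xtr[:, keep] - mean) / sd[keep]
        y_tr = y01[train]
        y_mean = y_tr.mean()
        w, p, c, t, w_os, p_os, _ = _fit_core(Xs, y_tr - y_mean, n_ortho)
        Xte = (Xv[test][:, keep] - mean) / sd[keep]
        for w_o, p_o in zip(w_os, p_os):
            t_o = Xte @ w_o
            Xte = Xte - np.outer(t_o, p_o)
        y_hat = (Xte @ w) * c + y_mean
        press += float(np.square(y01[test] - y_hat).sum())
        ss += float(np.square(y01[test] - y_mean).sum())
    return 1.0 - press / ss if ss > 0 else np.nan


def opls_scores_plot_table(model: OplsModel) -> pd.DataFrame:
    """Per-sample predictive and orthogonal scores, ready for plotting."""
    data = {"t_pred": model.t_pred, "y": model.y}
    for i, t_o in enumerate(model.t_ortho, start=1):
        data[f"t_ortho{i}"] = t_o
    return pd.DataFrame(data, index=model.sample_ids)
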