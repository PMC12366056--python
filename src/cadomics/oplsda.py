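"""Orthogonal partial least squares discriminant analysis (OPLS-DA).

NIPALS-style estimation for a single two-class response: orthogonal
components (systematic variation in X uncorrelated with y) are extracted and
removed first, then one predictive component is fitted on the deflated X.
R2Y is the fitted explained variance of the (centered) response; Q2 its
cross-validated analogue from stratified 7-fold CV, Q2 = 1 − PRESS/SSY.
Under label permutation Q2 is expected at or below zero.

The 95% Hotelling T² ellipse in 2-D score space uses the F-distribution
mapping T²crit = 2(n−1)/(n−2) · F(0.95; 2, n−2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import check_aligned, log


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (one predictive + n_ortho orthogonal components)."""

    w: np.ndarray  # predictive weights (unit norm)
    p: np.ndarray  # predictive loadings
    c: float  # y-loading of the predictive score
    w_ortho: np.ndarray  # n_ortho × p
    p_ortho: np.ndarray  # n_ortho × p
    scores: pd.DataFrame  # t_pred and t_ortho_i per training subject
    y_mean: float
    classes: tuple
    r2y: float
    q2: float
    n_ortho: int
    folds: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r2y": [self.r2y],
                "q2": [self.q2],
                "n_ortho": [self.n_ortho],
                "folds": [self.folds],
            }
        )

    def transform(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and first-orthogonal scores for (already scaled) rows."""
        xd = np.asarray(x, dtype=float).copy()
        t_os = []
        for wo, po in zip(self.w_ortho, self.p_ortho):
            t_o = xd @ wo
            xd -= np.outer(t_o, po)
            t_os.append(t_o)
        t = xd @ self.w
        t_o1 = t_os[0] if t_os else np.zeros_like(t)
        return t, t_o1

    def predict_value(self, x: np.ndarray) -> np.ndarray:
        t, _ = self.transform(x)
        return t * self.c + self.y_mean

    def predict_class(self, x: np.ndarray):
        yhat = self.predict_value(x)
        return np.where(yhat >= self.y_mean, self.classes[1], self.classes[0])


def _encode_response(y: pd.Series | np.ndarray) -> tuple[np.ndarray, tuple]:
    y = pd.Series(y)
    classes = tuple(sorted(y.unique()))
    if len(classes) != 2:
        raise ValueError(f"response must have exactly 2 classes, got {classes}")
    return (y == classes[1]).to_numpy(dtype=float), classes


def _fit_core(x: np.ndarray, yc: np.ndarray, n_ortho: int):
    """One OPLS fit on centered data; returns weights/loadings and scores."""
    xd = x.copy()
    w = xd.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response is orthogonal to every feature")
    w = w / nw
    w_os, p_os, t_os = [], [], []
    for _ in range(n_ortho):
        t = xd @ w
        p_load = xd.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = xd @ w_o
        p_o = xd.T @ t_o / (t_o @ t_o)
        xd -= np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
    t = xd @ w
    p_load = xd.T @ t / (t @ t)
    c = float((yc @ t) / (t @ t))
    p_dim = x.shape[1]
    w_arr = np.array(w_os) if w_os else np.empty((0, p_dim))
    p_arr = np.array(p_os) if p_os else np.empty((0, p_dim))
    return w, p_load, c, w_arr, p_arr, t, t_os


def _stratified_folds(y01: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold label per sample, class proportions preserved, seeded shuffle."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y01), dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def opls_fit(
    x,
    y: pd.Series | np.ndarray,
    n_ortho: int = 1,
    folds: int = 7,
    seed: int = 0,
) -> OplsModel:
    """Fit OPLS-DA with ``n_ortho`` orthogonal components and k-fold Q2.

    ``x`` is a unit-variance NormalizedMatrix or a DataFrame of scaled
    features; the two-class response is encoded as a single centered column.
    """
    frame = x.values if (not isinstance(x, pd.DataFrame)
                         and isinstance(getattr(x, "values", None), pd.DataFrame)) else x
    if not isinstance(frame, pd.DataFrame):
        frame = pd.DataFrame(np.asarray(frame, dtype=float))
    if isinstance(y, pd.Series):
        check_aligned(frame.index, y.index)
    arr = frame.to_numpy(dtype=float)
    n = arr.shape[0]
    if n_ortho >= min(arr.shape):
        raise ValueError("n_ortho must be below the rank of x")
    y01, classes = _encode_response(y)
    y_mean = float(y01.mean())
    yc = y01 - y_mean
    ssy = float(yc @ yc)
    if ssy == 0:
        raise ValueError("single-class response")

    xc_mean = arr.mean(axis=0)
    xc = arr - xc_mean
    w, p_load, c, w_os, p_os, t, t_os = _fit_core(xc, yc, n_ortho)
    resid = yc - t * c
    r2y = 1.0 - float(resid @ resid) / ssy

    # stratified k-fold PRESS
    fold_of = _stratified_folds(y01, folds, seed)
    press = 0.0
    for f in range(folds):
        train, test = fold_of != f, fold_of == f
        if y01[train].min() == y01[train].max():
            raise ValueError("degenerate CV fold: single-class training set")
        mu_x = arr[train].mean(axis=0)
        mu_y = float(y01[train].mean())
        wf, _, cf, wof, pof, _, _ = _fit_core(
            arr[train] - mu_x, y01[train] - mu_y, n_ortho
        )
        xt = arr[test] - mu_x
        for wo, po in zip(wof, pof):
            t_o = xt @ wo
            xt -= np.outer(t_o, po)
        yhat = (xt @ wf) * cf + mu_y
        press += float(((y01[test] - yhat) ** 2).sum())
    q2 = 1.0 - press / ssy

    score_cols = {"t_pred": t}
    for i, t_o in enumerate(t_os, start=1):
        score_cols[f"t_ortho{i}"] = t_o
    scores = pd.DataFrame(score_cols, index=frame.index)
    log.info("opls_fit n=%d p=%d n_ortho=%d R2Y=%.3f Q2=%.3f", n, arr.shape[1],
             len(w_os), r2y, q2)
    return OplsModel(
        w=w, p=p_load, c=c, w_ortho=w_os, p_ortho=p_os, scores=scores,
        y_mean=y_mean, classes=classes, r2y=r2y, q2=q2,
        n_ortho=len(w_os), folds=folds,
    )


def select_n_ortho(
    x, y, max_ortho: int = 5, folds: int = 7, seed: int = 0, min_gain: float = 0.01
) -> OplsModel:
    """Add orthogonal components while Q2 improves by more than ``min_gain``."""
    best = opls_fit(x, y, n_ortho=0, folds=folds, seed=seed)
    for n_o in range(1, max_ortho + 1):
        cand = opls_fit(x, y, n_ortho=n_o, folds=folds, seed=seed)
        if cand.q2 > best.q2 + min_gain:
            best = cand
        else:
            break
    return best


def permutation_q2(
    x, y, n_ortho: int = 1, folds: int = 7, seed: int = 0, n_permutations: int = 20
) -> np.ndarray:
    """Q2 under random label permutation (the standard validity check)."""
    rng = np.random.default_rng(seed)
    y = pd.Series(y)
    out = []
    for i in range(n_permutations):
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        out.append(opls_fit(x, perm, n_ortho=n_ortho, folds=folds, seed=seed + i + 1).q2)
    return np.array(out)


# ---------------------------------------------------------------- Hotelling


@dataclass
class HotellingEllipse:
    cov: np.ndarray
    t2_critical: float
    semi_axes: tuple[float, float]
    center: np.ndarray
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        t2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.cov), d)
        return t2 <= self.t2_critical


def hotelling_ellipse(scores: np.ndarray | pd.DataFrame, level: float = 0.95) -> HotellingEllipse:
    """95% (by default) Hotelling T² ellipse for a 2-D score cloud."""
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be n × 2")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("degenerate score covariance")
    f_crit = stats.f.ppf(level, 2, n - 2)
    t2_crit = 2.0 * (n - 1) / (n - 2) * f_crit
    eigvals = np.linalg.eigvalsh(cov)
    semi = tuple(float(np.sqrt(ev * t2_crit)) for ev in eigvals[::-1])
    return HotellingEllipse(cov, float(t2_crit), semi, center, level)
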