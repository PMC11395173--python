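"""PLS1 regression (NIPALS) of storage day on sensory attribute scores, with
leave-one-out component selection and VIP attribute importance.

Sensory attributes of a demerit protocol are strongly collinear (they all
track one latent freshness factor), which is why partial least squares, not
ordinary regression, is the standard chemometrics tool for asking which
attributes carry the storage-time signal. The VIP (variable importance in
projection) score summarizes each predictor's contribution across the
retained latent components; predictors with VIP > 1 are conventionally
flagged as important.

Algorithm: the NIPALS PLS1 recursion. Per component a:

    w_a = X'y / ||X'y||          (unit-norm weight)
    t_a = X w_a                  (score)
    p_a = X't_a / (t_a't_a)      (X loading)
    q_a = y't_a / (t_a't_a)      (y loading)
    X <- X - t_a p_a' ,  y <- y - t_a q_a     (deflation)

X is centered (and by default autoscaled to unit variance, the usual choice
for mixed-range sensory attributes); y is centered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("qimshelf")

_EPS = 1e-12


class PlsError(ValueError):
    pass


@dataclass(frozen=True)
class PlsModel:
    n_components: int
    weights: np.ndarray  # (p, A), unit-norm columns
    scores: np.ndarray  # (n, A), mutually orthogonal columns
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    explained_y_ss: np.ndarray  # SSY_a = q_a^2 * (t_a' t_a), per component

    @property
    def n_predictors(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class VipScores:
    vip: dict[str, float]
    threshold: float = 1.0

    def selected(self) -> list[str]:
        """Predictors flagged important (VIP strictly above the threshold)."""
        return [k for k, v in self.vip.items() if v > self.threshold]


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scale: bool = True,
) -> PlsModel:
    """Fit PLS1 by NIPALS.

    Stops early (with a logged warning) if X deflates to zero variance
    before the requested number of components is extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise PlsError("X must be a 2-D matrix")
    n, p = X.shape
    if n < 2 or p < 1 or len(y) != n:
        raise PlsError("need n >= 2 rows of X matching y")
    a_max = min(n - 1, p)
    if not 1 <= n_components <= a_max:
        raise PlsError(f"n_components must be in 1..{a_max}, got {n_components}")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(x_scale < _EPS, 1.0, x_scale)
    y_mean = float(y.mean())
    Xc = (X - x_mean) / x_scale
    yc = y - y_mean

    W, T, P, q, ssy = [], [], [], [], []
    for _ in range(n_components):
        xy = Xc.T @ yc
        norm = float(np.linalg.norm(xy))
        if norm < _EPS:
            logger.warning(
                "X deflated to zero covariance with y after %d component(s); "
                "stopping early", len(W)
            )
            break
        w = xy / norm
        t = Xc @ w
        tt = float(t @ t)
        if tt < _EPS:
            logger.warning("degenerate score after %d component(s); stopping early", len(W))
            break
        pa = Xc.T @ t / tt
        qa = float(yc @ t / tt)
        Xc = Xc - np.outer(t, pa)
        yc = yc - t * qa
        W.append(w)
        T.append(t)
        P.append(pa)
        q.append(qa)
        ssy.append(qa**2 * tt)
    if not W:
        raise PlsError("no informative component: X has no covariance with y")
    return PlsModel(
        n_components=len(W),
        weights=np.column_stack(W),
        scores=np.column_stack(T),
        x_loadings=np.column_stack(P),
        y_loadings=np.asarray(q),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        explained_y_ss=np.asarray(ssy),
    )


def predict_pls(model: PlsModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the response for new attribute rows.

    Scores for new data are recovered sequentially with the stored weights
    and X loadings (the same deflation the fit used)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_predictors:
        raise PlsError(
            f"X_new has {X_new.shape[1]} columns; model expects {model.n_predictors}"
        )
    Xc = (X_new - model.x_mean) / model.x_scale
    yhat = np.full(len(Xc), model.y_mean)
    for a in range(model.n_components):
        t = Xc @ model.weights[:, a]
        yhat += t * model.y_loadings[a]
        Xc = Xc - np.outer(t, model.x_loadings[:, a])
    return yhat


def vip_scores(
    model: PlsModel, parameter_names: list[str] | None = None, threshold: float = 1.0
) -> VipScores:
    """VIP per predictor:

        VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a )

    with unit-norm weight columns; the scores satisfy sum_j VIP_j^2 = p.
    """
    p = model.n_predictors
    ssy = model.explained_y_ss
    w2 = model.weights**2  # columns already unit norm
    vip = np.sqrt(p * (w2 @ ssy) / ssy.sum())
    names = parameter_names or [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise PlsError("parameter_names length does not match predictors")
    return VipScores(vip={k: float(v) for k, v in zip(names, vip)}, threshold=threshold)


def loo_cv(X: np.ndarray, y: np.ndarray, a_max: int, scale: bool = True) -> dict:
    """Leave-one-out cross-validation over component counts 1..a_max.

    Returns per-A RMSECV and the argmin component count (ties go to the
    smaller model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise PlsError("leave-one-out needs n >= 3")
    limit = min(n - 2, p)  # each fold drops one row
    if not 1 <= a_max <= limit:
        raise PlsError(f"a_max must be in 1..{limit}, got {a_max}")
    press = np.zeros(a_max)
    for i in range(n):
        keep = np.arange(n) != i
        model = fit_pls1(X[keep], y[keep], a_max, scale=scale)
        # reuse one full-size fit per fold; truncate to each A
        xc = (X[i] - model.x_mean) / model.x_scale
        yhat = model.y_mean
        for a in range(a_max):
            if a < model.n_components:
                t = float(xc @ model.weights[:, a])
                yhat += t * model.y_loadings[a]
                xc = xc - t * model.x_loadings[:, a]
            press[a] += (yhat - y[i]) ** 2
    rmsecv = np.sqrt(press / n)
    return {"per_A_rmsecv": rmsecv.tolist(), "chosen_A": int(np.argmin(rmsecv)) + 1}
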