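"""Single-response partial least-squares regression (PLS1) with
eigenvalue-threshold component selection and five-fold cross-validation.

PLSR extracts successive latent components that maximise covariance
between the (z-scored) predictors and the response, coupling data
reduction with regression.  Model quality is summarised by R-squared on
the full fit, predictive relevance Q-squared (``1 - PRESS / TSS`` with
PRESS accumulated over held-out folds) and the RMSE between responses and
fitted values.  Components are retained while their training-score
variance ("eigenvalue" on standardised predictors) is at least 1,
Kaiser-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PLSRError(ValueError):
    pass


@dataclass
class PLSRModel:
    """Fitted PLS1 model.

    ``weights`` (p x A) are the unit-norm predictor weights defining each
    component; ``x_loadings``/``y_loadings`` the deflation loadings;
    ``score_vars`` the per-component training score variances (ddof=1).
    The loading table reported for interpretation scales each weight
    column by ``y_loading * sd(score)`` — the predictor's contribution to
    the fitted response through that component — so magnitudes are
    comparable across components (documented convention; only signs and
    ranks are comparable across implementations).
    """

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    score_vars: np.ndarray
    coef: np.ndarray
    n_components: int
    feature_names: list[str] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return self.y_mean + Z @ self.coef

    @property
    def loading_table(self) -> pd.DataFrame:
        cols = [f"PC{a + 1}" for a in range(self.n_components)]
        names = self.feature_names or [f"x{i}" for i in range(self.weights.shape[0])]
        scale = self.y_loadings * np.sqrt(self.score_vars)
        return pd.DataFrame(self.weights * scale[None, :], index=names, columns=cols)


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = []
    yv = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != yv.shape[0]:
        raise PLSRError("X and y have different numbers of rows")
    return Xv, yv, names


def fit_plsr(X, y, n_components: int) -> PLSRModel:
    """Fit PLS1 by iterative deflation (NIPALS) on z-scored predictors."""
    Xv, yv, names = _as_xy(X, y)
    n, p = Xv.shape
    if n < n_components + 1:
        raise PLSRError("need more rows than components")
    rank = np.linalg.matrix_rank(Xv - Xv.mean(axis=0))
    if n_components > rank:
        raise PLSRError(f"n_components={n_components} exceeds predictor rank {rank}")
    x_mean = Xv.mean(axis=0)
    x_std = Xv.std(axis=0, ddof=1)
    if np.any(x_std == 0):
        raise PLSRError("constant predictor column")
    Z = (Xv - x_mean) / x_std
    y_mean = float(yv.mean())
    f = yv - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    score_vars = np.zeros(n_components)
    E = Z.copy()
    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:
            w = np.zeros(p)
            w[a % p] = 1.0
        else:
            w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt == 0:
            raise PLSRError("degenerate component (zero score variance)")
        P[:, a] = E.T @ t / tt
        q[a] = float(f @ t) / tt
        E = E - np.outer(t, P[:, a])
        f = f - q[a] * t
        W[:, a] = w
        score_vars[a] = tt / (len(t) - 1)

    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(x_mean=x_mean, x_std=x_std, y_mean=y_mean, weights=W,
                     x_loadings=P, y_loadings=q, score_vars=score_vars,
                     coef=coef, n_components=n_components, feature_names=names)


def select_n_components(X, y, threshold: float = 1.0) -> int:
    """Number of successive components whose training score variance on the
    standardised predictors is at least ``threshold`` (minimum 1)."""
    Xv, yv, _ = _as_xy(X, y)
    max_a = int(np.linalg.matrix_rank(Xv - Xv.mean(axis=0)))
    model = fit_plsr(Xv, yv, max(max_a, 1))
    n = 0
    for v in model.score_vars:
        if v >= threshold:
            n += 1
        else:
            break
    return max(n, 1)


@dataclass
class PLSRFitReport:
    r2: float
    q2: float
    rmse: float
    n_components: int
    partial_r2: np.ndarray
    loading_table: pd.DataFrame
    fold_seed: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "q2": self.q2, "rmse": self.rmse,
                "n_components": self.n_components,
                "partial_r2": [float(v) for v in self.partial_r2],
                "fold_seed": self.fold_seed}


def make_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of ``range(n)`` into near-equal folds."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def crossvalidate_plsr(X, y, n_components: int | None = None, folds: int = 5,
                       seed: int = 0, tss_per_fold: bool = False) -> PLSRFitReport:
    """Fit on all data and estimate predictive relevance over random folds.

    R-squared, RMSE and the per-component incremental (partial) R-squared
    come from the full fit; Q-squared is ``1 - PRESS / TSS`` with PRESS
    summed over the held-out folds.  TSS defaults to deviations about the
    whole-sample mean (per-training-fold mean behind ``tss_per_fold``).
    """
    Xv, yv, names = _as_xy(X, y)
    n = len(yv)
    if n < 10:
        raise PLSRError("need at least 10 observations for cross-validation")
    if n_components is None:
        n_components = select_n_components(Xv, yv)

    Xdf = pd.DataFrame(Xv, columns=names) if names else Xv
    model = fit_plsr(Xdf, yv, n_components)
    yhat = model.predict(Xv)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0:
        raise PLSRError("zero total variance in response")
    r2 = 1.0 - float(np.sum((yv - yhat) ** 2)) / tss
    rmse = float(np.sqrt(np.mean((yv - yhat) ** 2)))

    cum = []
    for a in range(1, n_components + 1):
        ya = fit_plsr(Xv, yv, a).predict(Xv)
        cum.append(1.0 - float(np.sum((yv - ya) ** 2)) / tss)
    partial = np.diff([0.0] + cum)

    press = 0.0
    tss_cv = 0.0
    for test_idx in make_folds(n, folds, seed):
        if len(test_idx) < 2:
            raise PLSRError("fold with fewer than 2 items")
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        a_fold = min(n_components,
                     int(np.linalg.matrix_rank(Xv[train_mask] - Xv[train_mask].mean(axis=0))))
        fold_model = fit_plsr(Xv[train_mask], yv[train_mask], a_fold)
        resid = yv[test_idx] - fold_model.predict(Xv[test_idx])
        press += float(np.sum(resid**2))
        base = yv[train_mask].mean() if tss_per_fold else yv.mean()
        tss_cv += float(np.sum((yv[test_idx] - base) ** 2))
    q2 = 1.0 - press / tss_cv

    return PLSRFitReport(r2=r2, q2=q2, rmse=rmse, n_components=n_components,
                         partial_r2=partial, loading_table=model.loading_table,
                         fold_seed=seed)
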