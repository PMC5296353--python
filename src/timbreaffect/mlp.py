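"""A 17-3-1 multilayer perceptron trained from scratch with full-batch
backpropagation, the five-fold (27 + 2 extras) cross-validation paradigm,
and Milne-style signed feature contributions.

The network maps range-normalised descriptors in [0, 1] to a single
emotion output (mean ratings mapped to [0, 1] via ``(rating - 1) / 8``).
Hidden and output units use logistic sigmoids; weights and biases are
initialised uniformly in +/-0.05.  Per-pattern gradient-descent deltas are
accumulated over an epoch and the summed delta applied once per epoch, so
the update is invariant to presentation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MLPError(ValueError):
    pass


@dataclass
class MLPConfig:
    n_inputs: int = 17
    n_hidden: int = 3
    learning_rate: float = 0.2
    epochs: int = 700
    init_scale: float = 0.05
    target_mse: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise MLPError("need at least one hidden unit")
        if self.learning_rate < 0:
            raise MLPError("learning rate must be nonnegative")


@dataclass
class MLPModel:
    """Trained network: W1 (inputs x hidden) + b1, w2 (hidden) + b2."""

    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    mse_trace: np.ndarray
    config: MLPConfig
    feature_names: list[str] = field(default_factory=list)

    @property
    def final_mse(self) -> float:
        return float(self.mse_trace[-1])

    @property
    def converged(self) -> bool:
        return self.final_mse < self.config.target_mse

    def to_dict(self) -> dict:
        return {"W1": self.W1.tolist(), "b1": self.b1.tolist(),
                "w2": self.w2.tolist(), "b2": self.b2,
                "final_mse": self.final_mse,
                "feature_names": self.feature_names}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def predict(model: MLPModel, X) -> np.ndarray:
    """Deterministic forward pass; outputs in (0, 1)."""
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[None, :]
    if Xv.shape[1] != model.W1.shape[0]:
        raise MLPError(f"expected {model.W1.shape[0]} inputs, got {Xv.shape[1]}")
    H = _sigmoid(Xv @ model.W1 + model.b1)
    return _sigmoid(H @ model.w2 + model.b2)


def train(X_train, y_train, config: MLPConfig) -> MLPModel:
    """Full-batch gradient descent on summed squared error.

    The per-pattern loss is ``(t - o)^2 / 2`` (its gradient drives the
    deltas); the recorded MSE trace is the mean of ``(t - o)^2``, so the
    convergence contract "MSE below target" refers to that mean.  Raises
    if training diverges (MSE exceeding 10x its initial value).
    """
    names = list(X_train.columns) if isinstance(X_train, pd.DataFrame) else []
    Xv = np.asarray(X_train, dtype=float)
    yv = np.asarray(y_train, dtype=float).ravel()
    n, p = Xv.shape
    if p != config.n_inputs:
        raise MLPError(f"config expects {config.n_inputs} inputs, X has {p}")
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    W1 = rng.uniform(-s, s, size=(p, config.n_hidden))
    b1 = rng.uniform(-s, s, size=config.n_hidden)
    w2 = rng.uniform(-s, s, size=config.n_hidden)
    b2 = float(rng.uniform(-s, s))

    lr = config.learning_rate
    trace = np.empty(config.epochs)
    initial_mse = None
    for epoch in range(config.epochs):
        H = _sigmoid(Xv @ W1 + b1)
        o = _sigmoid(H @ w2 + b2)
        err = o - yv
        mse = float(np.mean(err**2))
        trace[epoch] = mse
        if initial_mse is None:
            initial_mse = mse
        elif mse > 10.0 * initial_mse:
            raise MLPError("training diverged; reduce the learning rate")
        # summed per-pattern deltas (batch update, order-invariant)
        d_o = err * o * (1.0 - o)
        d_h = np.outer(d_o, w2) * H * (1.0 - H)
        w2 -= lr * (H.T @ d_o)
        b2 -= lr * float(np.sum(d_o))
        W1 -= lr * (Xv.T @ d_h)
        b1 -= lr * d_h.sum(axis=0)
    return MLPModel(W1=W1, b1=b1, w2=w2, b2=b2, mse_trace=trace,
                    config=config, feature_names=names)


# ---------------------------------------------------------------------------
# Fold plan: 5 x 27 + 2 extras tested with every fold
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    folds: list[list]        # disjoint id lists (the CV partition)
    extras: list             # ids appended to every test set
    seed: int

    def test_ids(self, k: int) -> list:
        return list(self.folds[k]) + list(self.extras)

    def train_ids(self, k: int) -> list:
        return [i for j, fold in enumerate(self.folds) if j != k for i in fold]


def make_fold_plan(stimulus_ids, seed: int = 0, folds: int = 5) -> FoldPlan:
    """Seeded partition of ``n = 5k + 2`` ids into 5 folds of k, with the 2
    leftover ids joining every test set."""
    ids = list(stimulus_ids)
    n = len(ids)
    if n % folds != 2:
        raise MLPError(f"need n = {folds}k + 2 stimulus ids, got n = {n}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    extras = perm[:2]
    rest = perm[2:]
    size = len(rest) // folds
    fold_lists = [rest[k * size:(k + 1) * size] for k in range(folds)]
    return FoldPlan(folds=fold_lists, extras=extras, seed=seed)


@dataclass
class MLPCVReport:
    fold_rmse: list[float]
    mean_rmse: float
    fold_models: list[MLPModel]
    plan: FoldPlan

    def to_dict(self) -> dict:
        return {"fold_rmse": self.fold_rmse, "mean_rmse": self.mean_rmse,
                "fold_seed": self.plan.seed}


def crossvalidate_mlp(X: pd.DataFrame, y: pd.Series, plan: FoldPlan,
                      config: MLPConfig) -> MLPCVReport:
    """Train one network per fold (on the other four folds) and report the
    test RMSE on that fold's 27 stimuli plus the 2 extras.

    Each fold's network gets its own deterministic init seed derived from
    the config seed, so the whole report is reproducible bit-for-bit.
    """
    rmses = []
    models = []
    children = np.random.SeedSequence(config.seed).spawn(len(plan.folds))
    for k in range(len(plan.folds)):
        fold_seed = int(children[k].generate_state(1)[0] % (2**31 - 1))
        cfg = MLPConfig(n_inputs=config.n_inputs, n_hidden=config.n_hidden,
                        learning_rate=config.learning_rate, epochs=config.epochs,
                        init_scale=config.init_scale, target_mse=config.target_mse,
                        seed=fold_seed)
        tr, te = plan.train_ids(k), plan.test_ids(k)
        model = train(X.loc[tr], y.loc[tr], cfg)
        pred = predict(model, X.loc[te])
        rmses.append(float(np.sqrt(np.mean((y.loc[te].to_numpy() - pred) ** 2))))
        models.append(model)
    return MLPCVReport(fold_rmse=rmses, mean_rmse=float(np.mean(rmses)),
                       fold_models=models, plan=plan)


# ---------------------------------------------------------------------------
# Milne-style signed feature contributions
# ---------------------------------------------------------------------------


def milne_contributions(model: MLPModel, global_norm: bool = False) -> pd.Series:
    """Signed percentage contribution of each input to the output.

    Input i contributes ``sum_j (W1[i, j] / sum_i' |W1[i', j]|) * w2[j]``
    (per-hidden-unit absolute-sum normalisation; a global normalisation
    over all input->hidden weights is available behind ``global_norm``).
    The result is expressed as a signed percentage of the total absolute
    contribution, so magnitudes sum to 100.  Hidden units with an all-zero
    incoming column are skipped.
    """
    W1, w2 = model.W1, model.w2
    p, h = W1.shape
    contrib = np.zeros(p)
    if global_norm:
        total = np.sum(np.abs(W1))
        if total > 0:
            contrib = (W1 / total) @ w2
    else:
        for j in range(h):
            col_sum = float(np.sum(np.abs(W1[:, j])))
            if col_sum == 0:
                continue
            contrib += (W1[:, j] / col_sum) * w2[j]
    denom = float(np.sum(np.abs(contrib)))
    pct = contrib * 100.0 / denom if denom > 0 else contrib
    names = model.feature_names or [f"x{i}" for i in range(p)]
    return pd.Series(pct, index=names, name="contribution_pct")


def average_contributions(models, renormalize: bool = False) -> pd.Series:
    """Mean of the per-fold-model contribution percentages.

    With ``renormalize`` the averaged profile is rescaled so its absolute
    values again sum to 100%.
    """
    table = pd.concat([milne_contributions(m) for m in models], axis=1)
    mean = table.mean(axis=1)
    if renormalize:
        total = mean.abs().sum()
        if total > 0:
            mean = mean * 100.0 / total
    mean.name = "contribution_pct"
    return mean
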