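"""Base predictors: ordinary least squares, ridge, and a feed-forward net.

The linear models work on centered features with an unpenalized intercept:
OLS takes the minimum-norm solution on rank-deficient systems, ridge
minimizes ||y - Xb||^2 + lam ||b||^2 in closed form.  The network is a
NumPy multilayer perceptron (ReLU hidden layers, linear output) trained by
minibatch Adam on mean-squared error.  Training stops when the epoch-level
loss history is convex in its recent window (consecutive decrements
shrinking over the last 3 epochs) AND the relative decrease between the
last two epochs is below 5%, or at the 50-epoch cap, whichever comes
first.  Hyperparameters (learning rate, batch size, depth, width) are
drawn from log-uniform / discrete-uniform distributions and ranked by
3-fold cross-validated Pearson accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold

from .metrics import accuracy

MAX_EPOCHS = 50
STOP_REL_DECREASE = 0.05
_SD_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# linear models

@dataclass
class LinearModel:
    """y ~ intercept + X @ coef; lam records the L2 penalty used (0 = OLS)."""

    intercept: float
    coef: np.ndarray
    lam: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.coef.size:
            raise ValueError(
                f"feature count {X.shape[1] if X.ndim == 2 else X.shape} does not "
                f"match model ({self.coef.size})"
            )
        return self.intercept + X @ self.coef

    def to_json(self) -> str:
        return json.dumps({"kind": "linear", "intercept": self.intercept,
                           "coef": self.coef.tolist(), "lam": self.lam})

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(d["intercept"], np.asarray(d["coef"], dtype=float), d["lam"])


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("X must be a nonempty 2-D matrix")
    if X.shape[0] != y.size:
        raise ValueError(f"{X.shape[0]} rows but {y.size} responses")
    return X, y


def fit_ols(X: np.ndarray, y: np.ndarray) -> LinearModel:
    """Least squares with intercept; minimum-norm on rank deficiency."""
    X, y = _check_xy(X, y)
    xm, ym = X.mean(axis=0), y.mean()
    beta, *_ = np.linalg.lstsq(X - xm, y - ym, rcond=None)
    return LinearModel(intercept=float(ym - xm @ beta), coef=beta, lam=0.0)


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> LinearModel:
    """Closed-form ridge on centered features; intercept unpenalized."""
    if lam < 0:
        raise ValueError("penalty lam must be nonnegative")
    if lam == 0:
        return fit_ols(X, y)
    X, y = _check_xy(X, y)
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    m = X.shape[1]
    beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(m), Xc.T @ yc)
    return LinearModel(intercept=float(ym - xm @ beta), coef=beta, lam=float(lam))


RIDGE_LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


def choose_ridge_lambda(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[float, ...] = RIDGE_LAMBDA_GRID,
    k: int = 3,
    seed: int = 0,
) -> float:
    """Pick lam from a log grid by k-fold CV Pearson accuracy (ties: first)."""
    X, y = _check_xy(X, y)
    n = X.shape[0]
    k = min(k, n)
    if k < 2:
        return float(grid[0])
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    best_lam, best_score = float(grid[0]), -np.inf
    for lam in grid:
        scores = []
        for tr, va in kf.split(X):
            if len(va) < 2:
                continue
            model = fit_ridge(X[tr], y[tr], lam)
            r = accuracy(y[va], model.predict(X[va]))
            if np.isfinite(r):
                scores.append(r)
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score:
            best_score, best_lam = score, float(lam)
    return best_lam


# ---------------------------------------------------------------------------
# feed-forward network

@dataclass
class NetworkHyperparams:
    """Tunable network settings, with the search-space bounds enforced."""

    learning_rate: float
    batch_size: int
    n_layers: int
    layer_width: int

    def __post_init__(self) -> None:
        if not 1e-4 <= self.learning_rate <= 100.0:
            raise ValueError("learning_rate outside [1e-4, 100]")
        if self.batch_size not in (4, 8, 16, 32, 64, 128):
            raise ValueError("batch_size must be a power of two in {4,...,128}")
        if not 3 <= self.n_layers <= 8:
            raise ValueError("n_layers outside [3, 8]")
        if not 3 <= self.layer_width <= 100:
            raise ValueError("layer_width outside [3, 100]")


@dataclass
class NetworkModel:
    """ReLU multilayer perceptron with input standardization baked in."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_sd: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for W, Wn, b in zip(self.weights[:-1], self.weights[1:], self.biases[:-1]):
            if W.shape[1] != Wn.shape[0] or W.shape[1] != b.size:
                raise ValueError("adjacent layer shapes inconsistent")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.weights[0].shape[0]:
            raise ValueError("feature count does not match network input layer")
        a = (X - self.x_mean) / self.x_sd
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return (a @ self.weights[-1] + self.biases[-1]).ravel()

    def to_json(self) -> str:
        return json.dumps({
            "kind": "network",
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "loss_history": self.loss_history,
        })

    @classmethod
    def from_json(cls, text: str) -> "NetworkModel":
        d = json.loads(text)
        return cls(
            [np.asarray(W, dtype=float) for W in d["weights"]],
            [np.asarray(b, dtype=float) for b in d["biases"]],
            np.asarray(d["x_mean"], dtype=float),
            np.asarray(d["x_sd"], dtype=float),
            list(d["loss_history"]),
        )


def should_stop(loss_history: list[float]) -> bool:
    """Loss-curve stopping rule.

    Fires when at least 3 epoch losses exist, the last two decrements are
    both positive and shrinking (d_prev > d_last > 0, i.e. the curve is
    decreasing at a slowing rate), and the last relative decrease is below
    5%.
    """
    if len(loss_history) < 3:
        return False
    l3, l2, l1 = loss_history[-3], loss_history[-2], loss_history[-1]
    d_prev, d_last = l3 - l2, l2 - l1
    if not (d_prev > d_last > 0):
        return False
    return d_last / l2 < STOP_REL_DECREASE if l2 > 0 else True


class DivergenceError(RuntimeError):
    """Non-finite training loss; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


def fit_network(
    X: np.ndarray,
    y: np.ndarray,
    hp: NetworkHyperparams,
    seed: int = 0,
    max_epochs: int = MAX_EPOCHS,
) -> NetworkModel:
    """Train the MLP by minibatch Adam on MSE; record per-epoch losses."""
    X, y = _check_xy(X, y)
    rng = np.random.default_rng([int(seed), 7])
    n, m = X.shape
    x_mean = X.mean(axis=0)
    x_sd = np.maximum(X.std(axis=0), _SD_FLOOR)
    Xs = (X - x_mean) / x_sd

    widths = [m] + [hp.layer_width] * hp.n_layers + [1]
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    t = 0

    batch = min(hp.batch_size, n)
    loss_history: list[float] = []
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            xb, yb = Xs[idx], y[idx]
            # forward pass, caching activations
            acts = [xb]
            for W, b in zip(weights[:-1], biases[:-1]):
                acts.append(np.maximum(acts[-1] @ W + b, 0.0))
            out = (acts[-1] @ weights[-1] + biases[-1]).ravel()
            # backprop of MSE
            delta = (2.0 / len(idx)) * (out - yb)[:, None]
            grads_W, grads_b = [None] * len(weights), [None] * len(biases)
            for layer in range(len(weights) - 1, -1, -1):
                grads_W[layer] = acts[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (acts[layer] > 0)
            t += 1
            lr_t = hp.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for i in range(len(weights)):
                mW[i] = beta1 * mW[i] + (1 - beta1) * grads_W[i]
                vW[i] = beta2 * vW[i] + (1 - beta2) * grads_W[i] ** 2
                weights[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                mb[i] = beta1 * mb[i] + (1 - beta1) * grads_b[i]
                vb[i] = beta2 * vb[i] + (1 - beta2) * grads_b[i] ** 2
                biases[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + eps)
        # full-data epoch loss
        a = Xs
        for W, b in zip(weights[:-1], biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        pred = (a @ weights[-1] + biases[-1]).ravel()
        loss = float(np.mean((pred - y) ** 2))
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        loss_history.append(loss)
        if should_stop(loss_history):
            break
    return NetworkModel(weights, biases, x_mean, x_sd, loss_history)


def sample_hyperparams(n_draws: int, seed: int = 0) -> list[NetworkHyperparams]:
    """Random-search draws from the stated distributions.

    learning rate log10-uniform on [1e-4, 100]; batch size log2-uniform on
    {4,...,128}; layers uniform on [3,8]; width uniform on [3,100].
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng([int(seed), 11])
    draws = []
    for _ in range(n_draws):
        draws.append(NetworkHyperparams(
            learning_rate=float(10.0 ** rng.uniform(-4.0, 2.0)),
            batch_size=int(2 ** rng.integers(2, 8)),
            n_layers=int(rng.integers(3, 9)),
            layer_width=int(rng.integers(3, 101)),
        ))
    return draws


def tune_network(
    X: np.ndarray,
    y: np.ndarray,
    n_draws: int = 300,
    k: int = 3,
    seed: int = 0,
    max_epochs: int = MAX_EPOCHS,
    log: list | None = None,
) -> NetworkHyperparams:
    """Pick hyperparameters by mean k-fold CV accuracy (ties: first draw).

    Divergent draws score -inf and are skipped.  ``log`` (if given)
    collects (draw index, hp, mean accuracy) triples.
    """
    X, y = _check_xy(X, y)
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} rows < k = {k} folds")
    draws = sample_hyperparams(n_draws, seed)
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    splits = list(kf.split(X))
    best_hp, best_score = draws[0], -np.inf
    for d, hp in enumerate(draws):
        scores = []
        try:
            for fold, (tr, va) in enumerate(splits):
                model = fit_network(X[tr], y[tr], hp,
                                    seed=_mix(seed, d, fold), max_epochs=max_epochs)
                r = accuracy(y[va], model.predict(X[va]))
                if np.isfinite(r):
                    scores.append(r)
        except DivergenceError:
            scores = []
        score = float(np.mean(scores)) if scores else -np.inf
        if log is not None:
            log.append((d, hp, score))
        if score > best_score:
            best_score, best_hp = score, hp
    return best_hp


def _mix(*parts: int) -> int:
    """Deterministic sub-seed below 2^31 from integer parts."""
    h = 0
    for p in parts:
        h = (h * 1000003 + int(p) + 1) % (2**31 - 1)
    return h


def predict(model, X: np.ndarray) -> np.ndarray:
    """Forward evaluation for any fitted base model."""
    return model.predict(np.asarray(X, dtype=float))


def save_model(model, path: str | Path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path: str | Path):
    text = Path(path).read_text()
    kind = json.loads(text)["kind"]
    return {"linear": LinearModel, "network": NetworkModel}[kind].from_json(text)
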