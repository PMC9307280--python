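"""Fully connected neural-network surrogate of the 1D-0D simulation.

Architecture: input layer, ``N_layer`` hidden layers of ``N_node`` nodes
each with batch normalization between the linear transformation and the
ReLU activation, and a linear output layer.  Training minimizes the mean
squared error of the (standardized) outputs with Adam and mini-batches;
validation R^2 is monitored every epoch, trailing-100-epoch means are
compared every 100 epochs and training stops after three successive
non-improving evaluations, restoring the weights of the best epoch.

Inputs are scaled affinely so their declared bounds map to [-1, 1];
outputs are standardized with the training-set mean and SD.  Everything is
plain numpy, so predictions are simple matrix-vector products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class Hyperparameters:
    n_hidden_layers: int = 7
    nodes_per_layer: int = 200
    batch_size: int = 3000
    learning_rate: float = 10.0 ** -2.5

    def validate(self):
        if min(self.n_hidden_layers, self.nodes_per_layer,
               self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class ScalingSpec:
    """Affine input scaling to [-1, 1] plus output standardization."""
    x_lower: np.ndarray
    x_upper: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    def validate(self):
        if np.any(self.x_upper <= self.x_lower):
            raise ValueError("input upper bounds must exceed lower bounds")
        if np.any(self.y_std <= 0):
            raise ValueError("zero-variance output column")

    def apply_x(self, X):
        return 2.0 * (X - self.x_lower) / (self.x_upper - self.x_lower) - 1.0

    def apply_y(self, Y):
        return (Y - self.y_mean) / self.y_std

    def invert_y(self, Yp):
        return Yp * self.y_std + self.y_mean


def fit_scaling(X: np.ndarray, Y: np.ndarray,
                x_lower=None, x_upper=None) -> ScalingSpec:
    """Build a ScalingSpec from training data.  Input bounds default to the
    declared manifest bounds when given, otherwise the empirical min/max.
    Validation/test data must be scaled with these training statistics."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    lo = np.asarray(x_lower, float) if x_lower is not None else X.min(axis=0)
    hi = np.asarray(x_upper, float) if x_upper is not None else X.max(axis=0)
    same = hi <= lo
    hi = np.where(same, lo + 1.0, hi)
    spec = ScalingSpec(lo, hi, Y.mean(axis=0), Y.std(axis=0))
    spec.validate()
    return spec


class SurrogateModel:
    """Weights, biases and batch-normalization state of the network."""

    def __init__(self, d_in: int, d_out: int, hp: Hyperparameters, seed: int = 0):
        hp.validate()
        if d_in < 1 or d_out < 1:
            raise ValueError("dimensions must be positive")
        self.hp = hp
        self.d_in = d_in
        self.d_out = d_out
        rng = np.random.default_rng(seed)
        dims = [d_in] + [hp.nodes_per_layer] * hp.n_hidden_layers + [d_out]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / dims[i]),
                             size=(dims[i + 1], dims[i]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        nh = hp.n_hidden_layers
        self.gamma = [np.ones(hp.nodes_per_layer) for _ in range(nh)]
        self.delta = [np.zeros(hp.nodes_per_layer) for _ in range(nh)]
        self.run_mean = [np.zeros(hp.nodes_per_layer) for _ in range(nh)]
        self.run_var = [np.ones(hp.nodes_per_layer) for _ in range(nh)]
        self.scaling: ScalingSpec | None = None
        self.training_meta: dict = {}

    # -- forward ----------------------------------------------------
    def _forward(self, X, training=False):
        """Returns the scaled-space output; caches intermediates when
        training for backprop."""
        cache = [] if training else None
        h = X
        nh = self.hp.n_hidden_layers
        for l in range(nh):
            z = h @ self.W[l].T + self.b[l]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.run_mean[l] = (_BN_MOMENTUM * self.run_mean[l]
                                    + (1 - _BN_MOMENTUM) * mu)
                self.run_var[l] = (_BN_MOMENTUM * self.run_var[l]
                                   + (1 - _BN_MOMENTUM) * var)
            else:
                mu = self.run_mean[l]
                var = self.run_var[l]
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * inv
            a = self.gamma[l] * zhat + self.delta[l]
            out = np.maximum(a, 0.0)
            if training:
                cache.append((h, zhat, inv, a, out))
            h = out
        y = h @ self.W[nh].T + self.b[nh]
        if training:
            cache.append(h)
        return (y, cache) if training else y

    def _backward(self, X, dY, cache):
        """Gradients of the loss w.r.t. all trainable arrays."""
        nh = self.hp.n_hidden_layers
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        gG = [None] * nh
        gD = [None] * nh
        h_last = cache[-1]
        gW[nh] = dY.T @ h_last
        gb[nh] = dY.sum(axis=0)
        dh = dY @ self.W[nh]
        for l in range(nh - 1, -1, -1):
            h_in, zhat, inv, a, out = cache[l]
            da = dh * (a > 0)
            gG[l] = (da * zhat).sum(axis=0)
            gD[l] = da.sum(axis=0)
            n = da.shape[0]
            dzhat = da * self.gamma[l]
            dz = (inv / n) * (n * dzhat - dzhat.sum(axis=0)
                              - zhat * (dzhat * zhat).sum(axis=0))
            gW[l] = dz.T @ h_in
            gb[l] = dz.sum(axis=0)
            dh = dz @ self.W[l]
        return gW, gb, gG, gD

    # -- public API -------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Inverse-scaled predictions for one row or a batch of rows."""
        if self.scaling is None:
            raise RuntimeError("model has no fitted scaling; train it first")
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.d_in:
            raise ValueError(f"expected {self.d_in} inputs, got {X.shape[1]}")
        yp = self._forward(self.scaling.apply_x(X))
        return self.scaling.invert_y(yp)

    def parameters(self):
        return (self.W, self.b, self.gamma, self.delta)

    def snapshot(self):
        return ([w.copy() for w in self.W], [b.copy() for b in self.b],
                [g.copy() for g in self.gamma], [d.copy() for d in self.delta],
                [m.copy() for m in self.run_mean],
                [v.copy() for v in self.run_var])

    def restore(self, snap):
        self.W, self.b, self.gamma, self.delta, self.run_mean, self.run_var = (
            [a.copy() for a in grp] for grp in snap)

    def save(self, path) -> None:
        d = {
            "d_in": self.d_in, "d_out": self.d_out, "hp": asdict(self.hp),
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
            "gamma": [g.tolist() for g in self.gamma],
            "delta": [g.tolist() for g in self.delta],
            "run_mean": [m.tolist() for m in self.run_mean],
            "run_var": [v.tolist() for v in self.run_var],
            "scaling": None if self.scaling is None else {
                "x_lower": self.scaling.x_lower.tolist(),
                "x_upper": self.scaling.x_upper.tolist(),
                "y_mean": self.scaling.y_mean.tolist(),
                "y_std": self.scaling.y_std.tolist()},
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        d = json.loads(Path(path).read_text())
        m = cls(d["d_in"], d["d_out"], Hyperparameters(**d["hp"]))
        m.W = [np.array(w) for w in d["W"]]
        m.b = [np.array(b) for b in d["b"]]
        m.gamma = [np.array(g) for g in d["gamma"]]
        m.delta = [np.array(g) for g in d["delta"]]
        m.run_mean = [np.array(g) for g in d["run_mean"]]
        m.run_var = [np.array(g) for g in d["run_var"]]
        if d["scaling"] is not None:
            s = d["scaling"]
            m.scaling = ScalingSpec(np.array(s["x_lower"]),
                                    np.array(s["x_upper"]),
                                    np.array(s["y_mean"]),
                                    np.array(s["y_std"]))
        m.training_meta = d["training_meta"]
        return m


def build_model(hp: Hyperparameters, d_in: int, d_out: int,
                seed: int = 0) -> SurrogateModel:
    return SurrogateModel(d_in, d_out, hp, seed)


def count_parameters(model: SurrogateModel) -> int:
    """Number of trainable weights and biases of the linear layers,
    sum over layers of (N_node^l * N_node^{l-1} + N_node^l).  Batch-norm
    scale/shift parameters are excluded from this count."""
    return int(sum(w.size + b.size for w, b in zip(model.W, model.b)))


def mse_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error pooled over samples and outputs."""
    y_true = np.atleast_2d(y_true)
    y_pred = np.atleast_2d(y_pred)
    return float(np.mean(np.sum((y_true - y_pred) ** 2, axis=1))
                 / y_true.shape[1])


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pooled coefficient of determination over all output components:
    1 - sum ||y - yhat||^2 / sum ||y - ybar||^2."""
    y_true = np.atleast_2d(y_true)
    y_pred = np.atleast_2d(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    ss_res = np.sum((y_true - y_pred) ** 2)
    ss_tot = np.sum((y_true - y_true.mean(axis=0)) ** 2)
    return float(1.0 - ss_res / ss_tot)


def mae_per_output(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    return np.mean(np.abs(np.atleast_2d(y_pred) - np.atleast_2d(y_true)),
                   axis=0)


def evaluate_metrics(y_pred: np.ndarray, y_true: np.ndarray,
                     groups: dict | None = None) -> dict:
    """Loss, pooled R^2 and per-output MAE; optional per-group R^2 for
    named output subsets (e.g. flow vs pressure columns)."""
    if np.asarray(y_true).size == 0:
        raise ValueError("empty input")
    out = {"mse_loss": mse_loss(y_true, y_pred),
           "r2": r2_score(y_true, y_pred),
           "mae": mae_per_output(y_true, y_pred)}
    for name, idx in (groups or {}).items():
        out[f"r2_{name}"] = r2_score(np.atleast_2d(y_true)[:, idx],
                                     np.atleast_2d(y_pred)[:, idx])
    return out


@dataclass
class TrainingReport:
    val_r2_history: list = field(default_factory=list)
    loss_history: list = field(default_factory=list)
    best_epoch: int = 0
    stopping_epoch: int = 0
    best_val_r2: float = -np.inf
    test_metrics: dict = field(default_factory=dict)


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def update(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(model: SurrogateModel, train_X, train_Y, val_X, val_Y,
          seed: int = 0, max_epochs: int = 5000,
          eval_every: int = 100, patience: int = 3,
          x_lower=None, x_upper=None):
    """Mini-batch Adam optimization of the MSE loss with the trailing-window
    early-stopping rule; returns (model, TrainingReport) with the weights
    of the best validation-R^2 epoch restored."""
    train_X = np.asarray(train_X, float)
    train_Y = np.asarray(train_Y, float)
    scaling = fit_scaling(train_X, train_Y, x_lower, x_upper)
    model.scaling = scaling
    Xs = scaling.apply_x(train_X)
    Ys = scaling.apply_y(train_Y)
    Xv = scaling.apply_x(np.asarray(val_X, float))
    Yv = scaling.apply_y(np.asarray(val_Y, float))

    rng = np.random.default_rng(seed)
    flat = lambda: [p for grp in model.parameters() for p in grp]
    opt = _Adam(flat(), model.hp.learning_rate)
    n = Xs.shape[0]
    bs = min(model.hp.batch_size, n)
    report = TrainingReport()
    best_snap = model.snapshot()
    best_window = -np.inf
    bad_evals = 0
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            if len(idx) < 2:      # batch statistics need >= 2 rows
                continue
            xb, yb = Xs[idx], Ys[idx]
            yp, cache = model._forward(xb, training=True)
            diff = yp - yb
            ep_loss += float(np.sum(diff ** 2))
            dY = 2.0 * diff / (len(idx) * model.d_out)
            grads = model._backward(xb, dY, cache)
            if not all(np.all(np.isfinite(g)) for grp in grads for g in grp):
                raise RuntimeError("training diverged: non-finite gradients")
            opt.update(flat(), [g for grp in grads for g in grp])
        report.loss_history.append(ep_loss / (n * model.d_out))
        r2v = r2_score(Yv, model._forward(Xv))
        report.val_r2_history.append(r2v)
        if r2v > report.best_val_r2:
            report.best_val_r2 = r2v
            report.best_epoch = epoch
            best_snap = model.snapshot()
        if epoch % eval_every == 0:
            window = float(np.mean(report.val_r2_history[-eval_every:]))
            if window > best_window:
                best_window = window
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= patience:
                    break
    report.stopping_epoch = epoch
    model.restore(best_snap)
    return model, report


def grid_search(grids: dict, train_data, val_data, test_data,
                seed: int = 0, **train_kwargs):
    """Train one model per hyperparameter combination and select the best
    by pooled test R^2.  ``grids`` maps Hyperparameters field names to value
    lists; ``*_data`` are (X, Y) pairs.  Returns (best model, results table)."""
    from itertools import product
    keys = list(grids)
    if not keys or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be non-empty")
    rows = []
    best = None
    best_r2 = -np.inf
    (Xtr, Ytr), (Xv, Yv), (Xte, Yte) = train_data, val_data, test_data
    for combo in product(*(grids[k] for k in keys)):
        hp = Hyperparameters(**dict(zip(keys, combo)))
        try:
            model = build_model(hp, Xtr.shape[1], Ytr.shape[1], seed)
            model, rep = train(model, Xtr, Ytr, Xv, Yv, seed=seed,
                               **train_kwargs)
            r2_test = r2_score(Yte, model.predict(Xte))
        except RuntimeError as exc:
            rows.append(dict(zip(keys, combo), r2_test=np.nan,
                             error=str(exc)))
            continue
        rows.append(dict(zip(keys, combo), r2_test=r2_test,
                         best_epoch=rep.best_epoch,
                         stopping_epoch=rep.stopping_epoch, error=""))
        if r2_test > best_r2:
            best_r2 = r2_test
            best = model
    return best, pd.DataFrame(rows)
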