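"""Sequence-to-descriptor CNN surrogate.

A compact 1-D convolutional network maps the 272 x 21 one-hot Fv encoding to
the ten region scores of one spatial property; three such models (SAP_pos,
SCM_neg, SCM_pos) together produce the full 30-descriptor set. The
architecture is  [conv(ReLU) -> batch-norm -> dropout] x n  -> max-pool ->
flatten -> dense(ReLU) -> linear(10),  trained with Adam on mean absolute
error, with the weights checkpointed at the epoch of minimum validation MAE.

The network, its optimiser, and the tuners (random search, successive-halving
hyperband, Gaussian-process Bayesian optimisation) are implemented directly
on numpy so the whole stack is dependency-light and bit-reproducible for a
fixed seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np

from .sequences import FvSequencePair, one_hot_encode, preprocess
from .structure import DESCRIPTOR_PROPERTIES, REGIONS, canonical_descriptor_names

# Hyperparameter grid (the tuning search space).
FILTER_CHOICES = tuple(range(16, 129, 16))
KERNEL_CHOICES = (3, 4, 5)
DROPOUT_CHOICES = tuple(round(0.1 * i, 1) for i in range(6))
DENSE_CHOICES = tuple(range(32, 129, 16))
LR_CHOICES = (1e-2, 5e-3, 1e-3, 1e-4)

INPUT_SHAPE = (272, 21)
N_OUTPUTS = 10


@dataclass
class SurrogateConfig:
    n_conv_layers: int = 3
    filters: int = 32
    kernel_size: int = 3
    dropout: float = 0.2
    dense_units: int = 64
    learning_rate: float = 1e-3
    n_outputs: int = N_OUTPUTS
    pool_size: int = 2
    pool_type: str = "max"      # "max" (default) or "avg"
    loss: str = "mae"           # "mae" (default) or "mse"
    seed: int = 0

    def validate(self) -> None:
        if self.n_conv_layers < 1:
            raise ValueError("need at least one conv layer")
        if self.filters not in FILTER_CHOICES:
            raise ValueError(f"filters {self.filters} outside grid {FILTER_CHOICES}")
        if self.kernel_size not in KERNEL_CHOICES:
            raise ValueError(f"kernel size {self.kernel_size} outside grid")
        if not any(abs(self.dropout - c) < 1e-9 for c in DROPOUT_CHOICES):
            raise ValueError(f"dropout {self.dropout} outside grid")
        if self.dense_units not in DENSE_CHOICES:
            raise ValueError(f"dense units {self.dense_units} outside grid")
        if self.learning_rate not in LR_CHOICES:
            raise ValueError(f"learning rate {self.learning_rate} outside grid")
        if self.pool_type not in ("max", "avg"):
            raise ValueError("pool_type must be 'max' or 'avg'")
        if self.loss not in ("mae", "mse"):
            raise ValueError("loss must be 'mae' or 'mse'")


@dataclass
class TrainingRun:
    split: tuple[float, float, float] = (0.65, 0.25, 0.10)
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    # Epoch at which batch-norm layers freeze to their running statistics
    # (a fixed per-channel affine map; scale/shift keep learning). One-hot
    # sequence activations have tiny post-ReLU channel variances, and
    # normalising by them puts the downstream layers in a badly conditioned
    # regime that generalises poorly at small sample sizes; freezing at
    # epoch 0 (the default) keeps the layers at their identity
    # initialisation, which restores stable generalisation while retaining
    # the architecture's trainable scale/shift. None runs conventional
    # batch statistics throughout.
    bn_freeze_epoch: int | None = 0

    def validate(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if self.bn_freeze_epoch is not None and self.bn_freeze_epoch < 0:
            raise ValueError("bn_freeze_epoch must be >= 0 or None")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(_Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        scale = math.sqrt(2.0 / (kernel * c_in))
        self.params["W"] = rng.normal(0, scale, (kernel * c_in, c_out)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, train, rng):
        # x: (B, L, C) -> valid convolution -> (B, L-k+1, F)
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, L', C, k)
        cols = win.transpose(0, 1, 3, 2).reshape(x.shape[0], -1, k * x.shape[2])
        self._cols, self._in_shape = np.ascontiguousarray(cols), x.shape
        return self._cols @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        B, Lp, F = grad.shape
        k = self.kernel
        cols2 = self._cols.reshape(-1, self._cols.shape[2])
        self.grads["W"] = cols2.T @ grad.reshape(-1, F)
        self.grads["b"] = grad.sum(axis=(0, 1))
        dcols = (grad @ self.params["W"].T).reshape(B, Lp, k, self._in_shape[2])
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        for off in range(k):
            dx[:, off:off + Lp, :] += dcols[:, :, off, :]
        return dx


class ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm(_Layer):
    """Per-channel normalisation over the batch and position axes.

    ``frozen`` switches the layer to its running statistics (making it a
    fixed per-channel affine map whose scale/shift are still trained); see
    :class:`TrainingRun.bn_freeze_epoch`.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.frozen = False
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, train, rng):
        axes = tuple(range(x.ndim - 1))
        if train and not self.frozen:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._batch_stats = train and not self.frozen
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        self._axes = axes
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        axes = self._axes
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * self.params["gamma"]
        if not self._batch_stats:  # fixed normalisation: plain affine chain
            return g * self._inv
        n = math.prod(grad.shape[i] for i in range(grad.ndim - 1))
        dx = (g - g.mean(axis=axes)
              - self._xhat * (g * self._xhat).sum(axis=axes) / n) * self._inv
        return dx


class Dropout(_Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MaxPool1D(_Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train, rng):
        B, L, C = x.shape
        Lp = L // self.size
        self._in_shape = x.shape
        blocks = x[:, :Lp * self.size, :].reshape(B, Lp, self.size, C)
        self._argmax = blocks.argmax(axis=2)
        return blocks.max(axis=2)

    def backward(self, grad):
        B, Lp, C = grad.shape
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        blocks = np.zeros((B, Lp, self.size, C), dtype=grad.dtype)
        b, l, c = np.ix_(np.arange(B), np.arange(Lp), np.arange(C))
        blocks[b, l, self._argmax, c] = grad
        dx[:, :Lp * self.size, :] = blocks.reshape(B, Lp * self.size, C)
        return dx


class AvgPool1D(_Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train, rng):
        B, L, C = x.shape
        Lp = L // self.size
        self._in_shape = x.shape
        return x[:, :Lp * self.size, :].reshape(B, Lp, self.size, C).mean(axis=2)

    def backward(self, grad):
        B, Lp, C = grad.shape
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :Lp * self.size, :] = np.repeat(grad / self.size, self.size, axis=1)
        return dx


class Flatten(_Layer):
    def forward(self, x, train, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0, scale, (n_in, n_out)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class SurrogateModel:
    """The CNN surrogate for one spatial property (10 region outputs)."""

    def __init__(self, config: SurrogateConfig, property_name: str = ""):
        config.validate()
        self.config = config
        self.property_name = property_name
        rng = np.random.default_rng(config.seed)
        L, C = INPUT_SHAPE
        layers: list[_Layer] = []
        c_in = C
        for _ in range(config.n_conv_layers):
            layers += [
                Conv1D(c_in, config.filters, config.kernel_size, rng),
                ReLU(),
                BatchNorm(config.filters),
                Dropout(config.dropout),
            ]
            L = L - config.kernel_size + 1
            c_in = config.filters
        pool_cls = MaxPool1D if config.pool_type == "max" else AvgPool1D
        layers.append(pool_cls(config.pool_size))
        L //= config.pool_size
        layers.append(Flatten())
        layers.append(Dense(L * c_in, config.dense_units, rng))
        layers.append(ReLU())
        layers.append(Dense(config.dense_units, config.n_outputs, rng))
        self.layers = layers

    # -- plumbing ----------------------------------------------------------
    def describe(self) -> list[str]:
        return [type(layer).__name__ for layer in self.layers]

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            for name in sorted(layer.params):
                out.append(layer.params[name].copy())
            if isinstance(layer, BatchNorm):
                out += [layer.running_mean.copy(), layer.running_var.copy()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for name in sorted(layer.params):
                layer.params[name] = next(it).copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        rng = np.random.default_rng(0)  # unused in inference mode
        outs = [self.forward(X[i:i + batch_size].astype(np.float32), False, rng)
                for i in range(0, len(X), batch_size)]
        return np.concatenate(outs, axis=0) if outs else np.zeros((0, self.config.n_outputs))


class _Adam:
    def __init__(self, model: SurrogateModel, lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-7):
        self.model, self.lr, self.b1, self.b2, self.eps = model, lr, b1, b2, eps
        self.t = 0
        self.state = {}
        for li, layer in enumerate(model.layers):
            for name, p in layer.params.items():
                self.state[(li, name)] = (np.zeros_like(p), np.zeros_like(p))

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.model.layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                m, v = self.state[(li, name)]
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                self.state[(li, name)] = (m, v)
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                layer.params[name] = (p - self.lr * mhat /
                                      (np.sqrt(vhat) + self.eps)).astype(np.float32)


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def build_model(config: SurrogateConfig, property_name: str = "") -> SurrogateModel:
    """Instantiate the CNN for a validated hyperparameter configuration."""
    return SurrogateModel(config, property_name)


def split_dataset(
    X: np.ndarray, y: np.ndarray, run: TrainingRun
) -> tuple[np.ndarray, ...]:
    """Seeded, unstratified train/validation/test split."""
    run.validate()
    n = len(X)
    order = np.random.default_rng(run.seed).permutation(n)
    n_train = int(round(run.split[0] * n))
    n_val = int(round(run.split[1] * n))
    tr, va, te = (order[:n_train], order[n_train:n_train + n_val],
                  order[n_train + n_val:])
    return X[tr], y[tr], X[va], y[va], X[te], y[te]


def _loss_and_grad(pred: np.ndarray, y: np.ndarray, kind: str):
    diff = pred - y
    if kind == "mae":
        return float(np.abs(diff).mean()), np.sign(diff) / diff.size
    return float((diff ** 2).mean()), 2.0 * diff / diff.size


def train(
    model: SurrogateModel,
    X: np.ndarray,
    y: np.ndarray,
    run: TrainingRun | None = None,
) -> dict:
    """Train with Adam; restore the epoch of minimum validation MAE.

    Returns the history: per-epoch train loss and validation MAE, the best
    epoch, and the split sizes. The model is left holding the checkpointed
    (not final) weights. A non-finite loss aborts with a diagnostic.
    """
    run = run or TrainingRun()
    run.validate()
    if len(X) < 10:
        raise ValueError("dataset too small: need at least 10 samples")
    if not np.isfinite(y).all():
        raise ValueError("labels must be finite")

    Xtr, ytr, Xva, yva, Xte, yte = split_dataset(X, y, run)
    rng = np.random.default_rng(run.seed + 1)
    optimiser = _Adam(model, model.config.learning_rate)
    history = {"epoch": [], "train_loss": [], "val_mae": []}
    best = (math.inf, -1, None)

    for epoch in range(run.epochs):
        if run.bn_freeze_epoch is not None and epoch == run.bn_freeze_epoch:
            for layer in model.layers:
                if isinstance(layer, BatchNorm):
                    layer.frozen = True
        order = rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(Xtr), run.batch_size):
            idx = order[start:start + run.batch_size]
            xb = Xtr[idx].astype(np.float32)
            pred = model.forward(xb, True, rng)
            loss, grad = _loss_and_grad(pred, ytr[idx], model.config.loss)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or check the labels"
                )
            model.backward(grad.astype(np.float32))
            optimiser.step()
            losses.append(loss)
        val_mae = float(np.abs(model.predict(Xva) - yva).mean())
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_mae"].append(val_mae)
        if val_mae < best[0]:
            best = (val_mae, epoch, model.get_weights())

    model.set_weights(best[2])
    history["best_epoch"] = best[1]
    history["best_val_mae"] = best[0]
    history["split_sizes"] = (len(Xtr), len(Xva), len(Xte))
    history["test_indices"] = None  # test partition is re-derivable from seed
    return history


@dataclass(frozen=True)
class EvalReport:
    mae: np.ndarray            # per output
    baseline_mae: np.ndarray   # constant mean predictor, per output
    pearson: np.ndarray        # per output; NaN if actuals constant

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.pearson))


def evaluate(model: SurrogateModel, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Per-output MAE, baseline MAE (mean predictor) and Pearson r."""
    pred = model.predict(X)
    mae = np.abs(pred - y).mean(axis=0)
    baseline = np.abs(y - y.mean(axis=0)).mean(axis=0)
    pearson = np.empty(y.shape[1])
    for k in range(y.shape[1]):
        sy, sp = y[:, k].std(), pred[:, k].std()
        if sy == 0 or sp == 0:
            pearson[k] = np.nan
        else:
            pearson[k] = float(np.corrcoef(y[:, k], pred[:, k])[0, 1])
    return EvalReport(mae=mae, baseline_mae=baseline, pearson=pearson)


# ---------------------------------------------------------------------------
# Descriptor prediction from sequence
# ---------------------------------------------------------------------------

def predict_descriptors(models: dict[str, SurrogateModel], pairs, numberer=None):
    """30 named descriptors per antibody from the three property models.

    Sequences failing the preprocessing filters get a row carrying the
    failure reasons instead of descriptor values.
    """
    import pandas as pd

    missing = set(DESCRIPTOR_PROPERTIES) - set(models)
    if missing:
        raise KeyError(f"missing surrogate models for {sorted(missing)}")
    names = canonical_descriptor_names()
    rows = []
    processed = preprocess(list(pairs), numberer)
    ok = [(pair, one_hot_encode(aligned))
          for pair, report, aligned in processed if report.passed]
    encoded = np.stack([e.matrix for _, e in ok]) if ok else None
    preds = {
        prop: models[prop].predict(encoded) if encoded is not None else None
        for prop in DESCRIPTOR_PROPERTIES
    }
    ok_index = {pair.name: i for i, (pair, _) in enumerate(ok)}
    for pair, report, aligned in processed:
        row = {"Name": pair.name}
        if report.passed:
            i = ok_index[pair.name]
            for prop in DESCRIPTOR_PROPERTIES:
                for j, region in enumerate(REGIONS):
                    row[f"{prop}_{region}"] = float(preds[prop][i, j])
            row["Failure_Reason"] = ""
        else:
            for name in names:
                row[name] = np.nan
            row["Failure_Reason"] = ";".join(sorted(report.reasons))
        rows.append(row)
    return pd.DataFrame(rows, columns=["Name", *names, "Failure_Reason"])


# ---------------------------------------------------------------------------
# Persistence (JSON architecture + HDF5 weights)
# ---------------------------------------------------------------------------

def save_model(model: SurrogateModel, directory: str | Path, name: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    desc = {
        "config": asdict(model.config),
        "property": model.property_name,
        "architecture": model.describe(),
        "n_parameters": model.n_parameters(),
    }
    (directory / f"{name}.json").write_text(json.dumps(desc, indent=2))
    with h5py.File(directory / f"{name}.h5", "w") as fh:
        for i, w in enumerate(model.get_weights()):
            fh.create_dataset(f"w{i:03d}", data=w)


def load_model(directory: str | Path, name: str) -> SurrogateModel:
    directory = Path(directory)
    desc = json.loads((directory / f"{name}.json").read_text())
    model = SurrogateModel(SurrogateConfig(**desc["config"]), desc["property"])
    with h5py.File(directory / f"{name}.h5", "r") as fh:
        weights = [fh[k][()] for k in sorted(fh.keys())]
    model.set_weights(weights)
    return model


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------

def _sample_config(rng: np.random.Generator, seed: int) -> SurrogateConfig:
    return SurrogateConfig(
        filters=int(rng.choice(FILTER_CHOICES)),
        kernel_size=int(rng.choice(KERNEL_CHOICES)),
        dropout=float(rng.choice(DROPOUT_CHOICES)),
        dense_units=int(rng.choice(DENSE_CHOICES)),
        learning_rate=float(rng.choice(LR_CHOICES)),
        seed=seed,
    )


def _trial(config: SurrogateConfig, X, y, run: TrainingRun) -> float:
    model = build_model(config)
    history = train(model, X, y, run)
    return history["best_val_mae"]


def _encode_config(c: SurrogateConfig) -> np.ndarray:
    return np.array([c.filters / 128, c.kernel_size / 5, c.dropout,
                     c.dense_units / 128, -math.log10(c.learning_rate) / 4])


def tune(
    X: np.ndarray,
    y: np.ndarray,
    strategy: str = "random",
    budget: int = 8,
    epochs_per_trial: int = 5,
    seed: int = 0,
    candidates: list[SurrogateConfig] | None = None,
) -> tuple[SurrogateConfig, list[dict]]:
    """Search the hyperparameter grid; returns (best config, trial log).

    ``random`` draws ``budget`` grid points; ``hyperband`` runs successive
    halving over training epochs; ``bayesian`` fits a Gaussian process to
    completed trials and picks candidates by expected improvement. An
    explicit candidate list bypasses sampling (useful for controlled
    comparisons).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if strategy not in ("random", "hyperband", "bayesian"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    trials: list[dict] = []

    def run_trial(config: SurrogateConfig, epochs: int) -> float:
        score = _trial(config, X, y, TrainingRun(epochs=epochs, seed=seed))
        trials.append({"config": asdict(config), "epochs": epochs,
                       "val_mae": score})
        return score

    def draw(k: int) -> list[SurrogateConfig]:
        if candidates is not None:
            return list(candidates)[:k]
        return [_sample_config(rng, seed) for _ in range(k)]

    if strategy == "random":
        configs = draw(budget)
        scores = [run_trial(c, epochs_per_trial) for c in configs]
    elif strategy == "hyperband":
        configs = draw(budget)
        epochs = max(1, epochs_per_trial // 2)
        scores = [run_trial(c, epochs) for c in configs]
        while len(configs) > 1:
            order = np.argsort(scores, kind="stable")[:max(1, len(configs) // 2)]
            configs = [configs[i] for i in order]
            epochs *= 2
            scores = [run_trial(c, epochs) for c in configs]
    else:  # bayesian
        from sklearn.gaussian_process import GaussianProcessRegressor

        pool = draw(max(budget * 4, 8))
        n_init = min(max(2, budget // 2), budget, len(pool))
        configs, scores = [], []
        for c in pool[:n_init]:
            configs.append(c)
            scores.append(run_trial(c, epochs_per_trial))
        remaining = pool[n_init:]
        while len(configs) < budget and remaining:
            gp = GaussianProcessRegressor(normalize_y=True).fit(
                np.stack([_encode_config(c) for c in configs]), scores)
            enc = np.stack([_encode_config(c) for c in remaining])
            mu, sd = gp.predict(enc, return_std=True)
            best = min(scores)
            z = (best - mu) / np.maximum(sd, 1e-9)
            from scipy.stats import norm
            ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            pick = int(np.argmax(ei))
            c = remaining.pop(pick)
            configs.append(c)
            scores.append(run_trial(c, epochs_per_trial))

    best_idx = int(np.argmin(scores))
    return configs[best_idx], trials
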