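"""Feed-forward classifier: one hidden block, early stopping, full diagnostics.

A deliberately small network — input layer sized to the fused feature
vector, one hidden layer of 20 tanh units, five output neurons (one per
tissue class).  Two objectives are supported: mean squared error between
one-hot targets and sigmoid outputs, and cross-entropy with softmax
outputs (the default).  Training is deterministic full-batch gradient
descent with a bold-driver adaptive step, stopping when the validation
loss fails to improve for ``max_fail`` consecutive epochs (default 6),
when the gradient norm falls below a threshold, or at the epoch budget.
The weights returned are those of the best-validation epoch, and the full
per-epoch history (losses, gradient norm, validation failures) is kept
for the error-histogram / regression diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from histofusion.types import FeatureMatrix

LOSSES = ("mse", "cross_entropy")


def mse_loss(actual: np.ndarray, expected: np.ndarray) -> float:
    """Mean squared error (1/m) sum (x_i - y_i)^2 over two equal-length vectors."""
    a = np.asarray(actual, dtype=np.float64).ravel()
    e = np.asarray(expected, dtype=np.float64).ravel()
    if a.shape != e.shape:
        raise ValueError("length mismatch")
    if a.size < 1:
        raise ValueError("vectors must be non-empty")
    return float(np.mean((a - e) ** 2))


def cross_entropy_loss(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy of predicted probabilities vs one-hot targets."""
    p = np.clip(np.asarray(probs, dtype=np.float64), eps, 1.0)
    y = np.asarray(onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("shape mismatch")
    return float(-np.sum(y * np.log(p)) / p.shape[0])


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


@dataclass
class MLPModel:
    """One-hidden-layer network weights plus the configuration that shaped them."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    loss: str = "cross_entropy"
    seed: int = 0

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def hidden_units(self) -> int:
        return self.W1.shape[1]

    @property
    def output_units(self) -> int:
        return self.W2.shape[1]

    def copy(self) -> "MLPModel":
        return MLPModel(self.W1.copy(), self.b1.copy(), self.W2.copy(),
                        self.b2.copy(), self.loss, self.seed)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    validation_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    gradient_norm: list[float] = field(default_factory=list)
    validation_failures: list[int] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def ann_init(input_dim: int, hidden_units: int = 20, output_units: int = 5,
             seed: int = 0, loss: str = "cross_entropy") -> MLPModel:
    """Seeded uniform +/- 1/sqrt(fan_in) initialization."""
    if loss not in LOSSES:
        raise ValueError(f"loss must be one of {LOSSES}")
    rng = np.random.default_rng(seed)
    lim1 = 1.0 / np.sqrt(input_dim)
    lim2 = 1.0 / np.sqrt(hidden_units)
    return MLPModel(
        W1=rng.uniform(-lim1, lim1, size=(input_dim, hidden_units)),
        b1=np.zeros(hidden_units),
        W2=rng.uniform(-lim2, lim2, size=(hidden_units, output_units)),
        b2=np.zeros(output_units),
        loss=loss,
        seed=seed,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: MLPModel, X: np.ndarray):
    H = np.tanh(X @ model.W1 + model.b1)
    Z = H @ model.W2 + model.b2
    if model.loss == "cross_entropy":
        O = _softmax(Z)
    else:
        O = 1.0 / (1.0 + np.exp(-Z))
    return H, O


def _loss_value(model: MLPModel, O: np.ndarray, Y: np.ndarray) -> float:
    if model.loss == "cross_entropy":
        return cross_entropy_loss(O, Y)
    return mse_loss(O, Y)


def _gradients(model: MLPModel, X: np.ndarray, Y: np.ndarray):
    """Analytic full-batch gradients of the configured loss."""
    n = X.shape[0]
    H, O = _forward(model, X)
    if model.loss == "cross_entropy":
        dZ = (O - Y) / n
    else:
        dZ = 2.0 * (O - Y) * O * (1.0 - O) / (n * Y.shape[1])
    gW2 = H.T @ dZ
    gb2 = dZ.sum(axis=0)
    dH = (dZ @ model.W2.T) * (1.0 - H ** 2)
    gW1 = X.T @ dH
    gb1 = dH.sum(axis=0)
    loss = _loss_value(model, O, Y)
    return loss, (gW1, gb1, gW2, gb2)


def _grad_norm(grads) -> float:
    return float(np.sqrt(sum(float((g ** 2).sum()) for g in grads)))


def ann_train(model: MLPModel, train: FeatureMatrix, validation: FeatureMatrix,
              test: FeatureMatrix | None = None, max_fail: int = 6,
              max_epochs: int = 500, learning_rate: float = 0.5,
              grad_threshold: float = 1e-6) -> tuple[MLPModel, TrainingHistory]:
    """Full-batch gradient training with validation-failure early stopping.

    The bold-driver step rule grows the learning rate by 5% after an epoch
    that lowers the training loss and halves it (reverting the step) after
    one that raises it, keeping training deterministic without a tuned
    schedule.  Stops after ``max_fail`` consecutive epochs without a new
    best validation loss, when the gradient norm drops below
    ``grad_threshold``, or at ``max_epochs``; the returned model carries
    the best-validation-epoch weights.
    """
    if validation.n_samples == 0:
        raise ValueError("validation set must be non-empty")
    n_classes = model.output_units
    Xtr, Ytr = train.values, one_hot(train.labels, n_classes)
    Xva, Yva = validation.values, one_hot(validation.labels, n_classes)
    Xte = Yte = None
    if test is not None:
        Xte, Yte = test.values, one_hot(test.labels, n_classes)

    history = TrainingHistory()
    model = model.copy()
    if max_epochs == 0:
        history.stop_reason = "zero epoch budget"
        return model, history

    best = model.copy()
    best_val = np.inf
    fails = 0
    lr = learning_rate
    prev_train_loss = np.inf

    for epoch in range(max_epochs):
        train_loss, grads = _gradients(model, Xtr, Ytr)
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        gnorm = _grad_norm(grads)

        _, Ova = _forward(model, Xva)
        val_loss = _loss_value(model, Ova, Yva)
        if Xte is not None:
            _, Ote = _forward(model, Xte)
            history.test_loss.append(_loss_value(model, Ote, Yte))
        history.train_loss.append(train_loss)
        history.validation_loss.append(val_loss)
        history.gradient_norm.append(gnorm)

        if val_loss < best_val:
            best_val = val_loss
            best = model.copy()
            history.best_epoch = epoch
            fails = 0
        else:
            fails += 1
        history.validation_failures.append(fails)

        if fails >= max_fail:
            history.stop_reason = f"validation failed {max_fail} consecutive epochs"
            break
        if gnorm < grad_threshold:
            history.stop_reason = "gradient below threshold"
            break

        # bold-driver step
        if train_loss > prev_train_loss:
            lr *= 0.5
        else:
            lr *= 1.05
        prev_train_loss = train_loss
        gW1, gb1, gW2, gb2 = grads
        model.W1 -= lr * gW1
        model.b1 -= lr * gb1
        model.W2 -= lr * gW2
        model.b2 -= lr * gb2
    else:
        history.stop_reason = "max epochs reached"

    best.loss = model.loss
    return best, history


def ann_predict(model: MLPModel, X: FeatureMatrix | np.ndarray):
    """Per-sample score matrix (n x 5) and argmax class indices.

    Softmax-normalized scores in cross-entropy mode; raw logistic outputs
    in MSE mode.
    """
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)
    if V.shape[1] != model.input_dim:
        raise ValueError("feature dimension does not match the model")
    _, O = _forward(model, V)
    return O, O.argmax(axis=1)


def error_histogram(targets, outputs, n_bins: int = 20):
    """Histogram of (target - output) errors over ``n_bins`` equal bins.

    ``targets``/``outputs`` may be arrays (a single split) or dicts keyed
    by split name; the bin edges span the observed error range pooled over
    splits, and counts are reported per split.  Returns (edges, counts).
    """
    if not isinstance(targets, dict):
        targets = {"all": targets}
        outputs = {"all": outputs}
    errors = {k: (np.asarray(targets[k], dtype=np.float64)
                  - np.asarray(outputs[k], dtype=np.float64)).ravel()
              for k in targets}
    pooled = np.concatenate(list(errors.values()))
    if pooled.size == 0:
        raise ValueError("empty input")
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:  # degenerate range: a single error value
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    counts = {k: np.histogram(v, bins=edges)[0] for k, v in errors.items()}
    return edges, counts


def regression_r(targets, outputs) -> float:
    """Pearson correlation of flattened targets vs outputs, as a percentage."""
    t = np.asarray(targets, dtype=np.float64).ravel()
    o = np.asarray(outputs, dtype=np.float64).ravel()
    if t.shape != o.shape:
        raise ValueError("length mismatch")
    if t.std() == 0 or o.std() == 0:
        raise ValueError("zero-variance inputs: correlation undefined")
    r = float(np.corrcoef(t, o)[0, 1])
    return r * 100.0
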