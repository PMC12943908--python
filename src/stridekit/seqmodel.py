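"""LSTM stride-length regressor.

A single-layer LSTM (50 hidden units by default) followed by a fully
connected output layer maps a fixed-length one-dimensional stride signal
— raw, Kalman-filtered or modified-Kalman-filtered — to a scalar stride
length. Training minimises MSE with Adam, mini-batches, dropout on the
final hidden state and early stopping on the validation loss.

The network is implemented directly in numpy (forward pass,
backpropagation through time, Adam) so it is fully seeded and
deterministic on a single CPU. Variable-length stride segments are
linearly resampled to a common length before training; z-score
normalisation of inputs and targets is fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceDataset",
    "LstmConfig",
    "LstmRegressor",
    "prepare_sequences",
    "train_model",
    "predict_lengths",
]


@dataclass
class SequenceDataset:
    """Fixed-length stride signals with labels, split tags and
    train-split normalisation statistics."""

    sequences: np.ndarray  # (n, target_len)
    labels: np.ndarray  # (n,) metres
    split_assignment: np.ndarray  # (n,) in {"train","val","test"}
    x_mean: float
    x_sd: float
    y_mean: float
    y_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.sequences.ndim != 2:
            raise ValueError("sequences must be a 2-D (n, length) array")
        if len(self.labels) != len(self.sequences):
            raise ValueError("label mismatch: labels count != sequence count")

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.split_assignment == name
        return self.sequences[mask], self.labels[mask]

    @property
    def target_len(self) -> int:
        return self.sequences.shape[1]


@dataclass
class LstmConfig:
    hidden_units: int = 50
    layers: int = 1
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 500
    early_stopping_patience: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be ≥ 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.layers != 1:
            raise ValueError("only a single LSTM layer is supported")


def _resample(signal: np.ndarray, target_len: int) -> np.ndarray:
    """Linear resampling of a 1-D signal onto target_len points."""
    x = np.asarray(signal, dtype=float)
    if len(x) == target_len:
        return x.copy()
    src = np.linspace(0.0, 1.0, len(x))
    dst = np.linspace(0.0, 1.0, target_len)
    return np.interp(dst, src, x)


def prepare_sequences(
    segments,
    labels,
    target_len: int = 50,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> SequenceDataset:
    """Resample stride signals to a common length, split and normalise.

    ``segments`` may be raw arrays or objects with a ``samples``
    attribute. The train/validation/test split is a seeded permutation
    with the given fractions; normalisation statistics come exclusively
    from the training split.
    """
    sigs = [getattr(s, "samples", s) for s in segments]
    if len(sigs) == 0:
        raise ValueError("no segments given")
    labels = np.asarray(labels, dtype=float)
    if len(labels) != len(sigs):
        raise ValueError("label mismatch: labels count != segment count")
    X = np.stack([_resample(s, target_len) for s in sigs])
    n = len(X)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = max(1, int(np.floor(fractions[0] * n)))
    n_val = int(np.floor(fractions[1] * n))
    tags = np.empty(n, dtype=object)
    tags[order[:n_train]] = "train"
    tags[order[n_train:n_train + n_val]] = "val"
    tags[order[n_train + n_val:]] = "test"
    train_X = X[tags == "train"]
    train_y = labels[tags == "train"]
    x_sd = float(np.std(train_X))
    y_sd = float(np.std(train_y))
    return SequenceDataset(
        sequences=X,
        labels=labels,
        split_assignment=tags.astype(str),
        x_mean=float(np.mean(train_X)),
        x_sd=max(x_sd, 1e-12),
        y_mean=float(np.mean(train_y)),
        y_sd=max(y_sd, 1e-12),
        seed=seed,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LstmRegressor:
    """Single-layer LSTM + linear head, trained by BPTT with Adam.

    Parameters are stored as ``W`` (input→gates), ``U`` (hidden→gates),
    ``b`` (gate bias, forget gate initialised to +1), ``Wy``/``by`` (the
    output head). Gate order along the last axis is input, forget, cell,
    output.
    """

    def __init__(self, cfg: LstmConfig, input_dim: int = 1):
        self.cfg = cfg
        self.input_dim = input_dim
        H = cfg.hidden_units
        rng = np.random.default_rng(cfg.seed)
        s = 1.0 / np.sqrt(H)
        self.params = {
            "W": rng.uniform(-s, s, (input_dim, 4 * H)),
            "U": rng.uniform(-s, s, (H, 4 * H)),
            "b": np.zeros(4 * H),
            "Wy": rng.uniform(-s, s, (H, 1)),
            "by": np.zeros(1),
        }
        self.params["b"][H:2 * H] = 1.0  # forget-gate bias
        self.trained = False
        # normalisation stats copied from the dataset at fit time
        self.x_mean = 0.0
        self.x_sd = 1.0
        self.y_mean = 0.0
        self.y_sd = 1.0
        self.target_len: int | None = None

    # ---- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, cache: bool = False):
        """X: (B, T, D) normalised input. Returns yhat (B,) and caches."""
        p = self.params
        B, T, _ = X.shape
        H = self.cfg.hidden_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches = []
        for t in range(T):
            z = X[:, t, :] @ p["W"] + h @ p["U"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if cache:
                caches.append((X[:, t, :], h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        yhat = (h @ p["Wy"] + p["by"])[:, 0]
        return yhat, h, caches

    def _backward(self, X, y, h_last, caches, dropmask):
        p = self.params
        B, T, _ = X.shape
        H = self.cfg.hidden_units
        hdrop = h_last * dropmask
        yhat = (hdrop @ p["Wy"] + p["by"])[:, 0]
        dyhat = (2.0 / B) * (yhat - y)  # d(MSE)/dyhat
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wy"] = hdrop.T @ dyhat[:, None]
        grads["by"] = np.array([dyhat.sum()])
        dh = (dyhat[:, None] @ p["Wy"].T) * dropmask
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tc = caches[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["W"] += x_t.T @ dz
            grads["U"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ p["U"].T
            dc = dc * f
        loss = float(np.mean((yhat - y) ** 2))
        return loss, grads

    # ---- training ----------------------------------------------------------

    def fit(self, ds: SequenceDataset) -> dict:
        """Train on the dataset's train split, early-stopping on val MSE.

        Returns the training history: per-epoch train and validation
        losses (normalised units).
        """
        cfg = self.cfg
        self.x_mean, self.x_sd = ds.x_mean, ds.x_sd
        self.y_mean, self.y_sd = ds.y_mean, ds.y_sd
        self.target_len = ds.target_len

        Xtr, ytr = ds.split("train")
        if len(Xtr) == 0:
            raise ValueError("empty training split")
        Xval, yval = ds.split("val")
        Xtr_n = ((Xtr - self.x_mean) / self.x_sd)[:, :, None]
        ytr_n = (ytr - self.y_mean) / self.y_sd
        Xval_n = ((Xval - self.x_mean) / self.x_sd)[:, :, None]
        yval_n = (yval - self.y_mean) / self.y_sd

        history = {"train_loss": [], "val_loss": []}
        if cfg.max_epochs == 0:
            return history
        if len(Xtr) < 2:
            raise ValueError("need ≥ 2 training sequences")

        rng = np.random.default_rng(cfg.seed + 1)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = None
        patience_left = cfg.early_stopping_patience
        keep = 1.0 - cfg.dropout_rate

        for _ in range(cfg.max_epochs):
            order = rng.permutation(len(Xtr_n))
            ep_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = Xtr_n[idx], ytr_n[idx]
                _, h_last, caches = self._forward(xb, cache=True)
                if cfg.dropout_rate > 0:
                    dropmask = (
                        rng.random(h_last.shape) < keep
                    ).astype(float) / keep
                else:
                    dropmask = np.ones_like(h_last)
                loss, grads = self._backward(xb, yb, h_last, caches, dropmask)
                ep_loss += loss * len(idx)
                step += 1
                for k in self.params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    self.params[k] -= (
                        cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    )
            history["train_loss"].append(ep_loss / len(Xtr_n))
            if len(Xval_n) > 0:
                yhat_val, _, _ = self._forward(Xval_n)
                val_loss = float(np.mean((yhat_val - yval_n) ** 2))
                history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_params = {k: p.copy() for k, p in self.params.items()}
                    patience_left = cfg.early_stopping_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_params is not None:
            self.params = best_params
        self.trained = True
        return history

    def predict(self, sequences: np.ndarray) -> np.ndarray:
        """Predict stride lengths (m, clipped at 0) for resampled signals."""
        if not self.trained:
            raise RuntimeError("model is not trained")
        X = np.asarray(sequences, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if len(X) == 0:
            return np.empty(0)
        if self.target_len is not None and X.shape[1] != self.target_len:
            raise ValueError(
                f"sequence length {X.shape[1]} does not match training "
                f"configuration ({self.target_len})"
            )
        Xn = ((X - self.x_mean) / self.x_sd)[:, :, None]
        yhat, _, _ = self._forward(Xn)
        return np.maximum(yhat * self.y_sd + self.y_mean, 0.0)


def train_model(ds: SequenceDataset, cfg: LstmConfig) -> tuple[LstmRegressor, dict]:
    """Train an :class:`LstmRegressor` on the dataset; returns (model, history)."""
    model = LstmRegressor(cfg, input_dim=1)
    history = model.fit(ds)
    return model, history


def predict_lengths(model: LstmRegressor, ds: SequenceDataset, split: str = "test"):
    """Predicted lengths (m) for one split of the dataset."""
    X, _ = ds.split(split)
    return model.predict(X) if len(X) else np.empty(0)
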