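"""Binary convolutional classifier for enhancer activity.

Architecture: one-hot DNA input (L x 4) -> 1D convolution (n_filters,
kernel_size) -> ReLU -> per-filter global max pooling -> dense ReLU layer ->
single sigmoid output.  The network, its gradients and the Adam optimizer are
implemented directly on NumPy arrays; the model is small enough that this is
fast on one CPU, and having explicit backpropagation gives exact gradients
with respect to the input, which the attribution stage relies on.

A logistic-regression baseline on the flattened one-hot encoding (trained on
identical splits) quantifies how much of the signal is linearly accessible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class EncodingError(ValueError):
    pass


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode an ACGT string as an L x 4 one-hot matrix (row order A,C,G,T)."""
    idx = np.empty(len(sequence), dtype=np.int64)
    for i, ch in enumerate(sequence):
        j = _BASE_INDEX.get(ch)
        if j is None:
            raise EncodingError(f"non-ACGT character {ch!r} at position {i}")
        idx[i] = j
    out = np.zeros((len(sequence), 4), dtype=np.float32)
    out[np.arange(len(sequence)), idx] = 1.0
    return out


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for valid one-hot input."""
    return "".join(BASES[j] for j in np.asarray(matrix).argmax(axis=1))


def encode_batch(sequences: Sequence[str]) -> np.ndarray:
    """Stack one-hot encodings into an (n, L, 4) array; lengths must agree."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise EncodingError(f"sequences have mixed lengths: {sorted(lengths)}")
    return np.stack([one_hot_encode(s) for s in sequences])


@dataclass
class Hyperparams:
    """Training configuration of the convolutional classifier."""

    n_filters: int = 32
    kernel_size: int = 16
    dense_units: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def validate(self, input_length: int | None = None) -> None:
        for name in ("n_filters", "kernel_size", "dense_units", "batch_size",
                     "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if input_length is not None and self.kernel_size > input_length:
            raise ValueError(
                f"kernel_size {self.kernel_size} exceeds input length {input_length}"
            )


@dataclass
class EvalReport:
    """Held-out evaluation metrics of a trained classifier."""

    auroc: float
    auprc: float
    accuracy: float
    loss: float
    n_train: int
    n_val: int
    n_test: int

    def to_dict(self) -> dict:
        return asdict(self)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ConvNet:
    """The classifier network; parameters live in a dict of NumPy arrays."""

    def __init__(self, hp: Hyperparams, input_length: int):
        hp.validate(input_length)
        self.hp = hp
        self.input_length = input_length
        rng = np.random.default_rng(hp.seed)
        k, f, d = hp.kernel_size, hp.n_filters, hp.dense_units
        # He initialization for the ReLU layers
        self.params = {
            "Wc": (rng.standard_normal((k * 4, f)) * np.sqrt(2.0 / (k * 4))).astype(
                np.float32
            ),
            "bc": np.zeros(f, dtype=np.float32),
            "W1": (rng.standard_normal((f, d)) * np.sqrt(2.0 / f)).astype(np.float32),
            "b1": np.zeros(d, dtype=np.float32),
            "w2": (rng.standard_normal(d) * np.sqrt(1.0 / d)).astype(np.float32),
            "b2": np.zeros(1, dtype=np.float32),
        }
        self.trained = False

    # ---- forward / backward -------------------------------------------------

    def _windows(self, x: np.ndarray) -> np.ndarray:
        # (B, L, 4) -> (B, P, k*4) im2col view flattened per window
        k = self.hp.kernel_size
        w = sliding_window_view(x, (k, 4), axis=(1, 2))[:, :, 0]  # (B, P, k, 4)
        b, p = w.shape[0], w.shape[1]
        return w.reshape(b, p, k * 4)

    def forward(self, x: np.ndarray, cache: bool = False):
        """Logits for a batch (B, L, 4); optionally return the backward cache."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        win = self._windows(x)
        z = win @ self.params["Wc"] + self.params["bc"]  # (B, P, F)
        a = np.maximum(z, 0.0)
        arg = a.argmax(axis=1)  # (B, F)
        m = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]  # (B, F)
        h_pre = m @ self.params["W1"] + self.params["b1"]
        h = np.maximum(h_pre, 0.0)
        logit = h @ self.params["w2"] + self.params["b2"][0]
        if cache:
            return logit, {"x": x, "win": win, "z": z, "arg": arg, "m": m,
                           "h_pre": h_pre, "h": h}
        return logit

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.forward(x))

    def _backward_core(self, cache: dict, dlogit: np.ndarray, need_input: bool,
                       need_params: bool):
        p = self.params
        h = cache["h"]
        dh = dlogit[:, None] * p["w2"][None, :]
        dh_pre = dh * (cache["h_pre"] > 0)
        dm = dh_pre @ p["W1"].T  # (B, F)
        # route max-pool gradient to the argmax window positions
        b_sz, p_len, f = cache["z"].shape
        da = np.zeros((b_sz, p_len, f), dtype=np.float32)
        np.put_along_axis(da, cache["arg"][:, None, :], dm[:, None, :], axis=1)
        dz = da * (cache["z"] > 0)
        grads = None
        if need_params:
            grads = {
                "w2": h.T @ dlogit,
                "b2": np.array([dlogit.sum()], dtype=np.float32),
                "W1": cache["m"].T @ dh_pre,
                "b1": dh_pre.sum(axis=0),
                "Wc": np.einsum("bpi,bpf->if", cache["win"], dz),
                "bc": dz.sum(axis=(0, 1)),
            }
        dx = None
        if need_input:
            k = self.hp.kernel_size
            dwin = dz @ p["Wc"].T  # (B, P, k*4)
            dwin = dwin.reshape(b_sz, p_len, k, 4)
            dx = np.zeros_like(cache["x"])
            for j in range(k):
                dx[:, j : j + p_len, :] += dwin[:, :, j, :]
        return grads, dx

    def input_gradients(self, x: np.ndarray, on_logit: bool = True) -> np.ndarray:
        """d(output)/d(input) for each example in the batch.

        ``on_logit=True`` differentiates the pre-sigmoid logit (the default
        used for attribution, which avoids sigmoid saturation); otherwise the
        probability.
        """
        logit, cache = self.forward(x, cache=True)
        dlogit = np.ones_like(logit)
        if not on_logit:
            s = _sigmoid(logit)
            dlogit = s * (1.0 - s)
        _, dx = self._backward_core(cache, dlogit.astype(np.float32), True, False)
        return dx

    # ---- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {"hp": asdict(self.hp), "input_length": self.input_length,
                "trained": self.trained}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str) -> "ConvNet":
        import os

        path = str(path)
        if not os.path.exists(path) and os.path.exists(path + ".npz"):
            path += ".npz"
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(Hyperparams(**meta["hp"]), meta["input_length"])
            for key in model.params:
                model.params[key] = data[key]
            model.trained = meta["trained"]
        return model


def _bce_loss_and_grad(logits, y, weights):
    p = _sigmoid(logits)
    eps = 1e-7
    loss = -np.mean(weights * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    dlogit = weights * (p - y) / len(y)
    return loss, dlogit.astype(np.float32)


def _split_data(x, y, seed):
    """Stratified 70/15/15 train/validation/test split."""
    idx = np.arange(len(y))
    train, rest = train_test_split(idx, test_size=0.3, stratify=y, random_state=seed)
    val, test = train_test_split(rest, test_size=0.5, stratify=y[rest],
                                 random_state=seed)
    return train, val, test


def _class_weights(y):
    n, n_pos = len(y), y.sum()
    n_neg = n - n_pos
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w.astype(np.float32)


def evaluate(model: ConvNet, x, y) -> tuple[float, float, float, float]:
    probs = model.predict_proba(x)
    eps = 1e-7
    loss = float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
    auroc = float(roc_auc_score(y, probs))
    auprc = float(average_precision_score(y, probs))
    acc = float(np.mean((probs >= 0.5) == y))
    return auroc, auprc, acc, loss


def train(
    positives: Sequence[str],
    negatives: Sequence[str],
    hp: Hyperparams | None = None,
) -> tuple[ConvNet, EvalReport]:
    """Train the classifier on labeled sequence sets.

    Binary cross-entropy with inverse-frequency class weights, Adam, early
    stopping on validation loss with ``hp.patience``; all randomness is
    driven by ``hp.seed``.  Returns the trained model and the held-out-test
    report.
    """
    hp = hp or Hyperparams()
    if len(positives) < 10 or len(negatives) < 10:
        raise ValueError("each class needs at least 10 examples for training")
    x = np.concatenate([encode_batch(positives), encode_batch(negatives)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    hp.validate(x.shape[1])
    model = ConvNet(hp, x.shape[1])
    report = _fit(model, x, y, hp)
    return model, report


def _fit(model: ConvNet, x, y, hp: Hyperparams) -> EvalReport:
    tr, va, te = _split_data(x, y, hp.seed)
    w_all = _class_weights(y[tr])
    rng = np.random.default_rng(hp.seed + 1)

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    t_step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    stale = 0
    for _epoch in range(hp.max_epochs):
        order = rng.permutation(len(tr))
        for lo in range(0, len(order), hp.batch_size):
            sel = tr[order[lo : lo + hp.batch_size]]
            logits, cache = model.forward(x[sel], cache=True)
            _, dlogit = _bce_loss_and_grad(logits, y[sel], w_all[order[lo : lo + hp.batch_size]])
            grads, _ = model._backward_core(cache, dlogit, False, True)
            t_step += 1
            for key, g in grads.items():
                adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * g
                adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * g * g
                m_hat = adam_m[key] / (1 - beta1 ** t_step)
                v_hat = adam_v[key] / (1 - beta2 ** t_step)
                model.params[key] = (
                    model.params[key] - hp.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                ).astype(np.float32)
        val_logits = model.forward(x[va])
        val_loss, _ = _bce_loss_and_grad(val_logits, y[va], np.ones(len(va), dtype=np.float32))
        if val_loss < best_val - 1e-5:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= hp.patience:
                break
    model.params = best_params
    model.trained = True
    auroc, auprc, acc, loss = evaluate(model, x[te], y[te])
    return EvalReport(auroc, auprc, acc, loss, len(tr), len(va), len(te))


def grid_search(
    grid: Sequence[Hyperparams],
    positives: Sequence[str],
    negatives: Sequence[str],
):
    """Train every grid cell on identical splits; best = highest validation
    AUROC.  Cells whose configuration is invalid for the data (e.g. kernel
    wider than the sequences) are marked invalid and skipped.

    Returns ``(best_hp, table)`` where table is a pandas DataFrame with one
    row per cell (validation AUROC or the invalidity reason).
    """
    import pandas as pd

    if not grid:
        raise ValueError("empty hyper-parameter grid")
    x = np.concatenate([encode_batch(positives), encode_batch(negatives)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    rows, results = [], []
    for i, hp in enumerate(grid):
        row = asdict(hp)
        try:
            hp.validate(x.shape[1])
            model = ConvNet(hp, x.shape[1])
            _fit(model, x, y, hp)
            tr, va, te = _split_data(x, y, hp.seed)
            val_auroc = float(roc_auc_score(y[va], model.predict_proba(x[va])))
            row.update(valid=True, val_auroc=val_auroc)
            results.append((val_auroc, i))
        except ValueError as exc:
            row.update(valid=False, val_auroc=np.nan, error=str(exc))
        rows.append(row)
    if not results:
        raise ValueError("no valid grid cell")
    best_idx = max(results)[1]
    return grid[best_idx], pd.DataFrame(rows)


def baseline_linear(
    positives: Sequence[str],
    negatives: Sequence[str],
    seed: int = 0,
) -> EvalReport:
    """Logistic regression on the flattened one-hot encoding, same splits.

    The comparison target for the network: how far a single affine map with a
    sigmoid link gets on the same data.
    """
    if len(positives) < 10 or len(negatives) < 10:
        raise ValueError("each class needs at least 10 examples for training")
    x = np.concatenate([encode_batch(positives), encode_batch(negatives)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    flat = x.reshape(len(x), -1)
    tr, va, te = _split_data(x, y, seed)
    clf = LogisticRegression(max_iter=2000, C=1.0)
    clf.fit(flat[tr], y[tr])
    probs = clf.predict_proba(flat[te])[:, 1]
    eps = 1e-7
    loss = float(-np.mean(y[te] * np.log(probs + eps)
                          + (1 - y[te]) * np.log(1 - probs + eps)))
    return EvalReport(
        auroc=float(roc_auc_score(y[te], probs)),
        auprc=float(average_precision_score(y[te], probs)),
        accuracy=float(np.mean((probs >= 0.5) == y[te])),
        loss=loss,
        n_train=len(tr),
        n_val=len(va),
        n_test=len(te),
    )
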