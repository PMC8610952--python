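"""Convolutional risk model: 12-h urine-output window -> hourly 0-100 score.

The model consumes the last 12 hourly urine-flow values (ml/kg/h) and emits
the probability that the patient develops an AKIN stage-2/3 episode from
6 h onward; updated every hour, rescaled to a 0-100 risk score after Platt
calibration.  Architecture: stacked blocks of parallel 1-D convolutions
(kernels 3/5/7) whose concatenated feature maps are merged with the block
input through a highway gate, global average pooling and a sigmoid head.

Implemented directly in NumPy (forward + manual backprop + Adam): the
inputs are 12-value sequences and the default network has ~5k parameters,
so CPU training is a matter of seconds and the whole computation stays
deterministic under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

WINDOW_HOURS = 12
DEFAULT_ALARM_THRESHOLD = 70.0


@dataclass
class ModelConfig:
    conv_block_count: int = 2
    filters_per_block: int = 8
    kernel_sizes: Tuple[int, ...] = (3, 5, 7)
    highway_gate: bool = True
    learning_rate: float = 3e-3
    epochs: int = 40
    batch_size: int = 256
    #: "balanced" weights positives by n_neg/n_pos; or a positive float
    class_weight: object = "balanced"
    early_stopping_patience: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.conv_block_count < 1 or self.filters_per_block < 1:
            raise ValueError("block and filter counts must be positive")
        if any(k < 1 or k > WINDOW_HOURS for k in self.kernel_sizes):
            raise ValueError(f"kernel sizes must be in [1, {WINDOW_HOURS}]")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning rate, epochs and batch size must be positive")


# ---------------------------------------------------------------- layers

def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Conv1d:
    """Same-padded 1-D convolution, channels-last (B, T, C)."""

    def __init__(self, k: int, c_in: int, c_out: int, rng, bias_init: float = 0.0):
        scale = np.sqrt(2.0 / (k * c_in))
        self.W = rng.normal(0.0, scale, size=(k, c_in, c_out))
        self.b = np.full(c_out, bias_init)
        self.k, self.pad = k, (k - 1) // 2

    def forward(self, X):
        B, T, _ = X.shape
        Xp = np.pad(X, ((0, 0), (self.pad, self.k - 1 - self.pad), (0, 0)))
        self._Xp, self._T = Xp, T
        Y = self.b + sum(Xp[:, j : j + T, :] @ self.W[j] for j in range(self.k))
        return Y

    def backward(self, dY):
        Xp, T = self._Xp, self._T
        self.dW = np.stack([np.einsum("bti,bto->io", Xp[:, j : j + T, :], dY) for j in range(self.k)])
        self.db = dY.sum(axis=(0, 1))
        dXp = np.zeros_like(Xp)
        for j in range(self.k):
            dXp[:, j : j + T, :] += dY @ self.W[j].T
        return dXp[:, self.pad : self.pad + T, :]

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class _HighwayBlock:
    """Parallel convolutions + highway gate: y = g * H(x) + (1 - g) * P(x)."""

    def __init__(self, c_in: int, filters: int, kernels, rng, highway: bool):
        self.branches = [_Conv1d(k, c_in, filters, rng) for k in kernels]
        c_out = filters * len(kernels)
        self.proj = _Conv1d(1, c_in, c_out, rng)
        self.highway = highway
        if highway:
            # gate bias starts negative: the block initially passes its input
            self.gate = _Conv1d(1, c_in, c_out, rng, bias_init=-1.0)
        self.c_out = c_out

    def forward(self, X):
        Hs = [br.forward(X) for br in self.branches]
        Z = np.concatenate(Hs, axis=2)
        self._relu_mask = Z > 0
        H = Z * self._relu_mask
        P = self.proj.forward(X)
        if not self.highway:
            self._H = None
            return H + P
        G = _sigmoid(self.gate.forward(X))
        self._H, self._P, self._G = H, P, G
        return G * H + (1.0 - G) * P

    def backward(self, dY):
        if self.highway:
            H, P, G = self._H, self._P, self._G
            dH = dY * G
            dP = dY * (1.0 - G)
            dGpre = dY * (H - P) * G * (1.0 - G)
            dX = self.gate.backward(dGpre)
        else:
            dH, dP = dY, dY
            dX = 0.0
        dX = dX + self.proj.backward(dP)
        dZ = dH * self._relu_mask
        f = self.branches[0].W.shape[2]
        for i, br in enumerate(self.branches):
            dX = dX + br.backward(dZ[:, :, i * f : (i + 1) * f])
        return dX

    def layers(self):
        out = list(self.branches) + [self.proj]
        if self.highway:
            out.append(self.gate)
        return out


class CnnRiskModel:
    """The full network: blocks -> global average pool -> sigmoid head."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.blocks: List[_HighwayBlock] = []
        c_in = 1
        for _ in range(config.conv_block_count):
            blk = _HighwayBlock(c_in, config.filters_per_block, config.kernel_sizes, rng, config.highway_gate)
            self.blocks.append(blk)
            c_in = blk.c_out
        scale = np.sqrt(1.0 / c_in)
        self.w_out = rng.normal(0.0, scale, size=c_in)
        self.b_out = 0.0
        self._adam_state = None

    # ---- forward / backward -------------------------------------------
    def forward(self, X):
        """X: (B, 12) urine flows -> probabilities (B,)."""
        A = np.asarray(X, dtype=float)[:, :, None]
        for blk in self.blocks:
            A = blk.forward(A)
        self._pooled = A.mean(axis=1)  # (B, C)
        logits = self._pooled @ self.w_out + self.b_out
        self._T = A.shape[1]
        return _sigmoid(logits)

    predict_proba = forward

    def _backward(self, dlogits):
        self.dw_out = self._pooled.T @ dlogits
        self.db_out = dlogits.sum()
        dPool = dlogits[:, None] * self.w_out[None, :]
        dA = np.repeat(dPool[:, None, :], self._T, axis=1) / self._T
        for blk in reversed(self.blocks):
            dA = blk.backward(dA)

    # ---- parameters ----------------------------------------------------
    def _param_refs(self):
        refs = []
        for blk in self.blocks:
            for layer in blk.layers():
                refs.append(layer.W)
                refs.append(layer.b)
        return refs

    def _grad_refs(self):
        refs = []
        for blk in self.blocks:
            for layer in blk.layers():
                refs.append(layer.dW)
                refs.append(layer.db)
        return refs

    def get_weights(self):
        flat = [p.copy() for p in self._param_refs()]
        flat.append(self.w_out.copy())
        flat.append(np.array(self.b_out))
        return flat

    def set_weights(self, flat):
        refs = self._param_refs()
        for p, v in zip(refs, flat[: len(refs)]):
            p[...] = v
        self.w_out[...] = flat[-2]
        self.b_out = float(flat[-1])

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self._param_refs()) + self.w_out.size + 1

    # ---- training ------------------------------------------------------
    def _adam_step(self, grads, lr, t):
        if self._adam_state is None:
            self._adam_state = [(np.zeros_like(g), np.zeros_like(g)) for g in grads]
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self._param_refs() + [self.w_out]
        for i, (p, g) in enumerate(zip(params, grads[:-1])):
            m, v = self._adam_state[i]
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
        if len(self._adam_state) < len(grads):
            self._adam_state.append((np.zeros(()), np.zeros(())))
        m, v = self._adam_state[len(grads) - 1]
        g = grads[-1]
        m[...] = b1 * m + (1 - b1) * g
        v[...] = b2 * v + (1 - b2) * g * g
        self.b_out = float(self.b_out - lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps))

    def train_step(self, X, y, w, lr, t):
        """One weighted-BCE gradient step; returns the batch loss."""
        p = self.forward(X)
        eps = 1e-12
        loss = -np.mean(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dlogits = w * (p - y) / len(y)
        self._backward(dlogits)
        grads = self._grad_refs() + [self.dw_out, np.asarray(self.db_out)]
        self._adam_step(grads, lr, t)
        return float(loss)


def _class_weights(y, scheme):
    w = np.ones(len(y))
    if scheme == "balanced":
        n_pos = max(1, int(y.sum()))
        w[y == 1] = (len(y) - n_pos) / n_pos
    elif isinstance(scheme, (int, float)):
        w[y == 1] = float(scheme)
    return w


def train_model(model: CnnRiskModel, X_train, y_train, X_val, y_val,
                config: Optional[ModelConfig] = None) -> Dict[str, list]:
    """Minibatch Adam with early stopping on validation AUC.

    Returns the training history (per-epoch loss and validation AUC);
    the model is left holding the best-validation weights.  Deterministic
    given ``config.seed``.
    """
    cfg = config or model.config
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    w_all = _class_weights(y_train, cfg.class_weight)
    rng = np.random.default_rng(cfg.seed + 1)
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)

    history = {"loss": [], "val_auc": []}
    best_auc, best_weights, since_best, step = -np.inf, None, 0, 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(y_train))
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            step += 1
            losses.append(model.train_step(X_train[idx], y_train[idx], w_all[idx], cfg.learning_rate, step))
        val_p = _predict_in_batches(model, X_val)
        val_auc = roc_auc_score(y_val, val_p) if len(np.unique(y_val)) > 1 else 0.5
        history["loss"].append(float(np.mean(losses)))
        history["val_auc"].append(float(val_auc))
        if val_auc > best_auc + 1e-6:
            best_auc, best_weights, since_best = val_auc, model.get_weights(), 0
        elif val_auc >= best_auc - 1e-9:
            # tie on validation AUC: keep the later (more confident) weights
            best_weights = model.get_weights()
            since_best += 1
        else:
            since_best += 1
        if since_best >= cfg.early_stopping_patience:
            break
    if best_weights is not None:
        model.set_weights(best_weights)
    return history


def _predict_in_batches(model, X, batch: int = 4096):
    out = [model.predict_proba(X[s : s + batch]) for s in range(0, len(X), batch)]
    return np.concatenate(out) if out else np.array([])


# ---------------------------------------------------------------- samples

@dataclass
class WindowSamples:
    """Flat window-sample arrays; patient ids kept so splits stay disjoint."""

    X: np.ndarray  # (N, 12)
    y: np.ndarray  # (N,)
    patient_ids: np.ndarray
    window_end_hours: np.ndarray


def make_window_samples(series_list, labels: Dict[str, str]) -> WindowSamples:
    """One 12-h window per hour t >= 12 of each stay (case series arrive
    already truncated, so every case window is a positive)."""
    X, y, ids, hours = [], [], [], []
    for s in series_list:
        lab = 1 if labels.get(s.patient_id, "control") == "case" else 0
        uo = s.uo_mlkg_h
        for t in range(WINDOW_HOURS, len(uo) + 1):
            X.append(uo[t - WINDOW_HOURS : t])
            y.append(lab)
            ids.append(s.patient_id)
            hours.append(t)
    if X:
        return WindowSamples(np.asarray(X, dtype=float), np.asarray(y), np.asarray(ids), np.asarray(hours))
    return WindowSamples(np.empty((0, WINDOW_HOURS)), np.empty(0, dtype=int),
                         np.empty(0, dtype=object), np.empty(0, dtype=int))


# ------------------------------------------------------------- calibration

class PlattCalibrator:
    """Monotone logistic recalibration p -> sigmoid(a * logit(p) + b).

    Rank-preserving whenever a > 0 (always the case on informative
    calibration data), so ROC and AUC are unchanged by construction.
    """

    def __init__(self):
        self.a, self.b = 1.0, 0.0

    @staticmethod
    def _logit(p):
        p = np.clip(np.asarray(p, dtype=float), 1e-7, 1 - 1e-7)
        return np.log(p / (1 - p))

    def fit(self, raw_p, y) -> "PlattCalibrator":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("calibration data must contain both classes")
        from sklearn.linear_model import LogisticRegression

        z = self._logit(raw_p)[:, None]
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        lr.fit(z, y)
        a, b = float(lr.coef_[0][0]), float(lr.intercept_[0])
        if a <= 0:  # degenerate (anti-informative) fit: keep ranks, warn via identity
            a, b = 1.0, 0.0
        self.a, self.b = a, b
        return self

    def transform(self, raw_p) -> np.ndarray:
        return _sigmoid(self.a * self._logit(raw_p) + self.b)


def calibrate(model: CnnRiskModel, X_cal, y_cal) -> PlattCalibrator:
    return PlattCalibrator().fit(_predict_in_batches(model, np.asarray(X_cal, dtype=float)), y_cal)


def expected_calibration_error(p, y, n_bins: int = 10) -> float:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.linspace(0, 1, n_bins + 1)
    ece = 0.0
    for lo, hi in zip(edges, edges[1:]):
        mask = (p >= lo) & (p < hi) if hi < 1 else (p >= lo) & (p <= hi)
        if mask.any():
            ece += mask.mean() * abs(p[mask].mean() - y[mask].mean())
    return float(ece)


# --------------------------------------------------------------- scoring

def predict_risk(model: CnnRiskModel, calibrator: Optional[PlattCalibrator], series,
                 alarm_threshold: float = DEFAULT_ALARM_THRESHOLD) -> pd.DataFrame:
    """Hourly 0-100 risk scores for one stay (one row per hour t >= 12).

    A score at hour t is the calibrated probability (x100) of stage-2/3
    onset at or after t + 6, computed from hours [t-12, t).
    """
    uo = np.asarray(series.uo_mlkg_h if hasattr(series, "uo_mlkg_h") else series, dtype=float)
    if len(uo) < WINDOW_HOURS:
        raise ValueError(f"series of {len(uo)} h is shorter than the {WINDOW_HOURS}-h input window")
    ends = np.arange(WINDOW_HOURS, len(uo) + 1)
    X = np.stack([uo[t - WINDOW_HOURS : t] for t in ends])
    p = _predict_in_batches(model, X)
    if calibrator is not None:
        p = calibrator.transform(p)
    score = np.clip(100.0 * p, 0.0, 100.0)
    return pd.DataFrame(
        {
            "patient_id": getattr(series, "patient_id", ""),
            "hour": ends,
            "score": score,
            "alarm": score > alarm_threshold,
        }
    )


# ------------------------------------------------------------ persistence

def save_model(model: CnnRiskModel, path) -> None:
    """Weights + config as JSON (the network is small enough for text)."""
    payload = {
        "config": {**model.config.__dict__, "kernel_sizes": list(model.config.kernel_sizes)},
        "weights": [w.tolist() for w in model.get_weights()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> CnnRiskModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg_d = payload["config"]
    cfg_d["kernel_sizes"] = tuple(cfg_d["kernel_sizes"])
    model = CnnRiskModel(ModelConfig(**cfg_d))
    model.set_weights([np.asarray(w) for w in payload["weights"]])
    return model
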