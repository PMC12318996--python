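"""Squeeze-and-excitation LSTM classifier for concentration-class spectra.

A reflectance spectrum of C bands is treated as a C-channel signal.  The
SE block computes a per-channel squeeze (global average pool — for
length-1 channels this is the band value itself), excites it through a
bottleneck two-layer network, and rescales each band by the resulting
logistic gate in (0, 1):

    z = GAP(x),   s = sigmoid(W2 relu(W1 z + b1) + b2),   x' = s * x

The reweighted spectrum is then fed band-by-band (low to high wavelength,
one band value per time step) through a stack of LSTM layers, each cell
computing the classical gate equations

    f_t = sigmoid(W_fx x_t + W_fh h_{t-1} + b_f)
    i_t = sigmoid(W_ix x_t + W_ih h_{t-1} + b_i)
    o_t = sigmoid(W_ox x_t + W_oh h_{t-1} + b_o)
    g_t = tanh   (W_gx x_t + W_gh h_{t-1} + b_g)
    c_t = f_t * c_{t-1} + i_t * g_t
    h_t = o_t * tanh(c_t)

and the final hidden state goes through a fully connected softmax head
over the three concentration classes (0 / 10 / 100 mg/L).  Training
minimises mean cross-entropy with a choice of SGD, Adam or RMSprop, all
implemented here with seeded initialisation so identical configs
reproduce identical fits.  Setting ``use_se=False`` gives the plain-LSTM
baseline with an otherwise identical protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ingest import LabeledSpectra

__all__ = [
    "SEBlockParams",
    "LSTMCellParams",
    "SELSTMConfig",
    "SplitSpec",
    "EvalReport",
    "SELSTMModel",
    "TrainingDiverged",
    "se_block_forward",
    "lstm_cell_step",
    "selstm_forward",
    "train_selstm",
    "evaluate",
    "grid_search_architecture",
    "sweep_optimizer_lr",
    "stratified_split",
]

OPTIMIZERS = ("sgd", "adam", "rmsprop")
LEARNING_RATES = (0.001, 0.005, 0.01, 0.05, 0.1)
LAYER_GRID = (1, 2, 3)
UNIT_GRID = (16, 32, 64, 128)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")


# ---------------------------------------------------------------------------
# SE block
# ---------------------------------------------------------------------------


@dataclass
class SEBlockParams:
    """Bottleneck excitation network: C -> C/r -> C with logistic output gate."""

    reduce_weights: np.ndarray  # C x (C/r)
    reduce_bias: np.ndarray  # (C/r,)
    expand_weights: np.ndarray  # (C/r) x C
    expand_bias: np.ndarray  # (C,)
    reduction_ratio: int

    def __post_init__(self) -> None:
        C, Cr = self.reduce_weights.shape
        if C % self.reduction_ratio != 0 or Cr != C // self.reduction_ratio:
            raise ValueError(
                f"reduction ratio {self.reduction_ratio} incompatible with C={C}, "
                f"bottleneck {Cr}"
            )


def se_block_forward(params: SEBlockParams, x: np.ndarray) -> np.ndarray:
    """Channel-attention reweighting: out = sigmoid(excite(squeeze(x))) * x.

    ``x`` is a single C-vector or a (batch, C) matrix.  With all weights
    and biases zero the gate is sigmoid(0) = 0.5 everywhere, so the output
    is exactly half the input.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    C = params.reduce_weights.shape[0]
    if X.shape[1] != C:
        raise ValueError(f"input has {X.shape[1]} channels, SE block expects {C}")
    z = X  # GAP over length-1 channels is the identity
    hidden = np.maximum(z @ params.reduce_weights + params.reduce_bias, 0.0)
    s = _sigmoid(hidden @ params.expand_weights + params.expand_bias)
    out = s * X
    return out[0] if single else out


# ---------------------------------------------------------------------------
# LSTM cell (reference form, one step)
# ---------------------------------------------------------------------------


@dataclass
class LSTMCellParams:
    """One LSTM cell's weights in the explicit per-gate form."""

    W_fx: np.ndarray
    W_ix: np.ndarray
    W_ox: np.ndarray
    W_gx: np.ndarray
    W_fh: np.ndarray
    W_ih: np.ndarray
    W_oh: np.ndarray
    W_gh: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_g: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_fh.shape[0]


def lstm_cell_step(
    params: LSTMCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM time step, exactly the gate equations in the module docstring.

    Accepts 1-D (single sample) or 2-D (batch, dim) arrays.  Non-finite
    inputs are rejected.
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=np.float64))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=np.float64))
    c_prev = np.atleast_1d(np.asarray(c_prev, dtype=np.float64))
    for name, a in (("x_t", x_t), ("h_prev", h_prev), ("c_prev", c_prev)):
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite values in {name}")
    f = _sigmoid(x_t @ params.W_fx + h_prev @ params.W_fh + params.b_f)
    i = _sigmoid(x_t @ params.W_ix + h_prev @ params.W_ih + params.b_i)
    o = _sigmoid(x_t @ params.W_ox + h_prev @ params.W_oh + params.b_o)
    g = np.tanh(x_t @ params.W_gx + h_prev @ params.W_gh + params.b_g)
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


# ---------------------------------------------------------------------------
# model configuration and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SELSTMConfig:
    """Architecture + training protocol of the (SE-)LSTM classifier."""

    n_bands: int = 256
    n_layers: int = 2
    units: int = 32
    reduction_ratio: int = 16
    n_classes: int = 3
    use_se: bool = True
    optimizer: str = "adam"
    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 32
    standardize: bool = True  # per-band z-scoring fitted on the calibration set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}, got {self.optimizer!r}")
        if self.use_se and self.n_bands % self.reduction_ratio != 0:
            raise ValueError(
                f"reduction ratio {self.reduction_ratio} must divide n_bands {self.n_bands}"
            )


# internal gate layout of the stacked parameter matrices: the three logistic
# gates first (contiguous sigmoid block), the tanh candidate last
_I, _F, _O, _G = 0, 1, 2, 3


def _gate_slices(H: int):
    return [slice(k * H, (k + 1) * H) for k in range(4)]


# ---------------------------------------------------------------------------
# recurrent loop kernels (numba-accelerated when available)
# ---------------------------------------------------------------------------


def _fwd_loop(xproj, Wh, Hseq, gates, TC, Cprev, Hprev, want_cache):
    """Run the cell recursion over all T steps; writes Hseq (+ caches)."""
    T, n, H4 = xproj.shape
    H = H4 // 4
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    for t in range(T):
        pre = xproj[t] + np.dot(h, Wh)
        for b in range(n):
            for k in range(H):
                i = 1.0 / (1.0 + np.exp(-pre[b, k]))
                f = 1.0 / (1.0 + np.exp(-pre[b, H + k]))
                o = 1.0 / (1.0 + np.exp(-pre[b, 2 * H + k]))
                g = np.tanh(pre[b, 3 * H + k])
                if want_cache:
                    Hprev[t, b, k] = h[b, k]
                    Cprev[t, b, k] = c[b, k]
                    gates[t, b, k] = i
                    gates[t, b, H + k] = f
                    gates[t, b, 2 * H + k] = o
                    gates[t, b, 3 * H + k] = g
                cc = f * c[b, k] + i * g
                tc = np.tanh(cc)
                c[b, k] = cc
                h[b, k] = o * tc
                if want_cache:
                    TC[t, b, k] = tc
        Hseq[t] = h


def _bwd_loop(dH_ext, gates, TC, Cprev, WhT, da):
    """Backward pass through time for one layer; fills da (T, n, 4H)."""
    T, n, H = dH_ext.shape
    dh_rec = np.zeros((n, H))
    dc = np.zeros((n, H))
    for t in range(T - 1, -1, -1):
        for b in range(n):
            for k in range(H):
                dh = dH_ext[t, b, k] + dh_rec[b, k]
                i = gates[t, b, k]
                f = gates[t, b, H + k]
                o = gates[t, b, 2 * H + k]
                g = gates[t, b, 3 * H + k]
                tc = TC[t, b, k]
                do = dh * tc
                dck = dc[b, k] + dh * o * (1.0 - tc * tc)
                da[t, b, k] = dck * g * i * (1.0 - i)
                da[t, b, H + k] = dck * Cprev[t, b, k] * f * (1.0 - f)
                da[t, b, 2 * H + k] = do * o * (1.0 - o)
                da[t, b, 3 * H + k] = dck * i * (1.0 - g * g)
                dc[b, k] = dck * f
        dh_rec = np.dot(da[t], WhT)


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    _fwd_loop = _njit(cache=True, fastmath=False)(_fwd_loop)
    _bwd_loop = _njit(cache=True, fastmath=False)(_bwd_loop)
except ImportError:  # plain-python fallback keeps results identical, just slower
    pass


def _init_params(config: SELSTMConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}

    def glorot(shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape)

    C, H = config.n_bands, config.units
    if config.use_se:
        Cr = C // config.reduction_ratio
        params["se_W1"] = glorot((C, Cr))
        params["se_b1"] = np.zeros(Cr)
        params["se_W2"] = glorot((Cr, C))
        params["se_b2"] = np.zeros(C)
    in_size = 1
    for layer in range(config.n_layers):
        params[f"l{layer}_Wx"] = glorot((in_size, 4 * H))
        params[f"l{layer}_Wh"] = glorot((H, 4 * H))
        b = np.zeros(4 * H)
        b[_gate_slices(H)[_F]] = 1.0  # open forget gates at init
        params[f"l{layer}_b"] = b
        in_size = H
    params["head_W"] = glorot((H, config.n_classes))
    params["head_b"] = np.zeros(config.n_classes)
    return params


@dataclass
class SELSTMModel:
    """Trained (SE-)LSTM classifier: config + parameter arrays.

    ``input_center``/``input_scale`` hold the per-band standardisation
    fitted on the calibration split (None when standardisation is off);
    they are applied inside every forward pass so callers always feed raw
    reflectance.
    """

    config: SELSTMConfig
    params: dict[str, np.ndarray]
    input_center: np.ndarray | None = None
    input_scale: np.ndarray | None = None

    def se_params(self) -> SEBlockParams | None:
        if not self.config.use_se:
            return None
        return SEBlockParams(
            reduce_weights=self.params["se_W1"],
            reduce_bias=self.params["se_b1"],
            expand_weights=self.params["se_W2"],
            expand_bias=self.params["se_b2"],
            reduction_ratio=self.config.reduction_ratio,
        )

    def cell_params(self, layer: int) -> LSTMCellParams:
        """Layer weights in the explicit per-gate form (for the cell-step oracle)."""
        H = self.config.units
        sl = _gate_slices(H)
        Wx, Wh, b = (self.params[f"l{layer}_{k}"] for k in ("Wx", "Wh", "b"))
        return LSTMCellParams(
            W_fx=Wx[:, sl[_F]], W_ix=Wx[:, sl[_I]], W_ox=Wx[:, sl[_O]], W_gx=Wx[:, sl[_G]],
            W_fh=Wh[:, sl[_F]], W_ih=Wh[:, sl[_I]], W_oh=Wh[:, sl[_O]], W_gh=Wh[:, sl[_G]],
            b_f=b[sl[_F]], b_i=b[sl[_I]], b_o=b[sl[_O]], b_g=b[sl[_G]],
        )

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return selstm_forward(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def save_model(model: SELSTMModel, path: str) -> None:
    """Checkpoint: parameter arrays as NPZ plus a JSON sidecar with the config."""
    import json
    from dataclasses import asdict

    arrays = dict(model.params)
    if model.input_center is not None:
        arrays["_input_center"] = model.input_center
        arrays["_input_scale"] = model.input_scale
    np.savez(path, **arrays)
    with open(str(path) + ".json", "w") as fh:
        json.dump(asdict(model.config), fh, indent=2)


def load_model(path: str) -> SELSTMModel:
    import json

    with open(str(path) + ".json") as fh:
        config = SELSTMConfig(**json.load(fh))
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as npz:
        params = {k: npz[k] for k in npz.files}
    center = params.pop("_input_center", None)
    scale = params.pop("_input_scale", None)
    return SELSTMModel(config=config, params=params, input_center=center, input_scale=scale)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    model: SELSTMModel, X: np.ndarray, want_cache: bool = False
) -> tuple[np.ndarray, dict | None]:
    cfg, P = model.config, model.params
    X = np.atleast_2d(np.ascontiguousarray(X, dtype=np.float64))
    if X.shape[1] != cfg.n_bands:
        raise ValueError(f"input has {X.shape[1]} bands, model expects {cfg.n_bands}")
    if model.input_center is not None:
        X = (X - model.input_center) / model.input_scale
    n, H = X.shape[0], cfg.units
    cache: dict = {"X": X} if want_cache else None

    if cfg.use_se:
        hidden = np.maximum(X @ P["se_W1"] + P["se_b1"], 0.0)
        s = _sigmoid(hidden @ P["se_W2"] + P["se_b2"])
        Xw = s * X
        if want_cache:
            cache.update(se_hidden=hidden, se_s=s)
    else:
        Xw = X

    seq = np.ascontiguousarray(Xw.T)[:, :, None]  # (T, n, 1): one band per time step
    dummy = np.empty((1, 1, 1))
    for layer in range(cfg.n_layers):
        Wx, Wh, b = P[f"l{layer}_Wx"], P[f"l{layer}_Wh"], P[f"l{layer}_b"]
        T = seq.shape[0]
        xproj = (seq.reshape(T * n, -1) @ Wx).reshape(T, n, 4 * H) + b
        H_seq = np.empty((T, n, H))
        if want_cache:
            gates = np.empty((T, n, 4 * H))
            TC = np.empty((T, n, H))
            Cprev = np.empty((T, n, H))
            Hprev = np.empty((T, n, H))
        else:
            gates = TC = Cprev = Hprev = dummy
        _fwd_loop(xproj, Wh, H_seq, gates, TC, Cprev, Hprev, want_cache)
        if want_cache:
            cache[f"l{layer}"] = dict(input=seq, gates=gates, TC=TC, Cprev=Cprev, Hprev=Hprev)
        seq = H_seq
    h_last = seq[-1]
    logits = h_last @ P["head_W"] + P["head_b"]
    probs = _softmax(logits)
    if want_cache:
        cache["h_last"] = h_last
    return probs, cache


def selstm_forward(model: SELSTMModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of spectra; rows sum to 1."""
    probs, _ = _forward(model, X, want_cache=False)
    return probs


def _backward(model: SELSTMModel, cache: dict, probs: np.ndarray, y: np.ndarray) -> dict:
    """Gradients of mean cross-entropy w.r.t. every parameter array."""
    cfg, P = model.config, model.params
    n = probs.shape[0]
    H = cfg.units
    sl = _gate_slices(H)

    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    grads = {
        "head_W": cache["h_last"].T @ dlogits,
        "head_b": dlogits.sum(axis=0),
    }
    dh_top = dlogits @ P["head_W"].T  # grad w.r.t. last hidden state of top layer

    dSeq_next = None  # (T, n, H) grad w.r.t. this layer's output sequence
    for layer in range(cfg.n_layers - 1, -1, -1):
        lc = cache[f"l{layer}"]
        gates, TC, Cprev, Hprev = lc["gates"], lc["TC"], lc["Cprev"], lc["Hprev"]
        T = gates.shape[0]
        Wx, Wh = P[f"l{layer}_Wx"], P[f"l{layer}_Wh"]
        da = np.empty((T, n, 4 * H))
        if layer == cfg.n_layers - 1:
            dH_ext = np.zeros((T, n, H))
            dH_ext[-1] = dh_top
        else:
            dH_ext = dSeq_next
        _bwd_loop(dH_ext, gates, TC, Cprev, np.ascontiguousarray(Wh.T), da)
        in_seq = lc["input"]
        in_flat = in_seq.reshape(T * n, -1)
        da_flat = da.reshape(T * n, 4 * H)
        grads[f"l{layer}_Wx"] = in_flat.T @ da_flat
        grads[f"l{layer}_Wh"] = Hprev.reshape(T * n, H).T @ da_flat
        grads[f"l{layer}_b"] = da_flat.sum(axis=0)
        dSeq_next = (da_flat @ Wx.T).reshape(T, n, -1)

    dXw = dSeq_next[:, :, 0].T  # (n, C): grad w.r.t. the (reweighted) spectrum
    if cfg.use_se:
        X, s, hidden = cache["X"], cache["se_s"], cache["se_hidden"]
        ds = dXw * X
        du = ds * s * (1.0 - s)
        grads["se_W2"] = hidden.T @ du
        grads["se_b2"] = du.sum(axis=0)
        dhid = du @ P["se_W2"].T
        dpre = dhid * (hidden > 0)
        grads["se_W1"] = X.T @ dpre
        grads["se_b1"] = dpre.sum(axis=0)
        # x feeds both the gate input and the elementwise product
        # (dX itself is not needed further; inputs are data)
    return grads


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class _Optimizer:
    def __init__(self, kind: str, lr: float, params: dict[str, np.ndarray]):
        self.kind, self.lr, self.t = kind, lr, 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr = self.lr
        if self.kind == "sgd":
            for k in params:
                params[k] -= lr * grads[k]
        elif self.kind == "rmsprop":
            rho, eps = 0.9, 1e-8
            for k in params:
                self.v[k] = rho * self.v[k] + (1 - rho) * grads[k] ** 2
                params[k] -= lr * grads[k] / (np.sqrt(self.v[k]) + eps)
        elif self.kind == "adam":
            b1, b2, eps = 0.9, 0.999, 1e-8
            bc1 = 1 - b1**self.t
            bc2 = 1 - b2**self.t
            for k in params:
                self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
                self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
                params[k] -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + eps)
        else:  # pragma: no cover - guarded by SELSTMConfig
            raise ValueError(self.kind)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Calibration/prediction accuracy (%), mean cross-entropy, and overfit gap."""

    accuracy_calibration: float
    accuracy_prediction: float
    loss_calibration: float
    loss_prediction: float
    overfit_coefficient: float  # percentage points, calibration - prediction

    def summary(self) -> str:
        return (
            f"calibration: {self.accuracy_calibration:6.2f}%  "
            f"loss {self.loss_calibration:.4f}\n"
            f"prediction:  {self.accuracy_prediction:6.2f}%  "
            f"loss {self.loss_prediction:.4f}\n"
            f"overfitting coefficient: {self.overfit_coefficient:.2f} points"
        )

    def to_dict(self) -> dict:
        return {
            "accuracy_calibration": self.accuracy_calibration,
            "accuracy_prediction": self.accuracy_prediction,
            "loss_calibration": self.loss_calibration,
            "loss_prediction": self.loss_prediction,
            "overfit_coefficient": self.overfit_coefficient,
        }


def _check_labels(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty label set")
    if np.any((y < 0) | (y >= n_classes)):
        bad = y[(y < 0) | (y >= n_classes)][0]
        raise ValueError(f"label {bad} outside 0..{n_classes - 1}")
    return y.astype(np.int64)

def _accuracy_and_loss(model, X, y) -> tuple[float, float]:
    probs = model.predict_proba(X)
    y = _check_labels(y, probs.shape[1])
    acc = 100.0 * float(np.mean(np.argmax(probs, axis=1) == y))
    loss = float(np.mean(-np.log(np.clip(probs[np.arange(y.size), y], 1e-300, None))))
    return acc, loss


def evaluate(model, calibration: tuple, prediction: tuple) -> EvalReport:
    """Accuracy/loss on both sets; overfit = calibration minus prediction accuracy.

    ``model`` is anything with ``predict_proba(X) -> (n, n_classes)``;
    the sets are (X, y) pairs with integer class codes.
    """
    acc_c, loss_c = _accuracy_and_loss(model, *calibration)
    acc_p, loss_p = _accuracy_and_loss(model, *prediction)
    return EvalReport(
        accuracy_calibration=acc_c,
        accuracy_prediction=acc_p,
        loss_calibration=loss_c,
        loss_prediction=loss_p,
        overfit_coefficient=acc_c - acc_p,
    )


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Stratified calibration/prediction split (chemometrics naming)."""

    calibration_frac: float = 0.7
    seed: int = 0


def stratified_split(y: np.ndarray, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Per-class proportional index split, deterministic in the spec's seed."""
    y = np.asarray(y)
    rng = np.random.default_rng(spec.seed)
    cal, pred = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        n_cal = int(round(spec.calibration_frac * idx.size))
        cal.extend(idx[:n_cal])
        pred.extend(idx[n_cal:])
    return np.sort(np.array(cal, dtype=np.int64)), np.sort(np.array(pred, dtype=np.int64))


def train_selstm(
    config: SELSTMConfig,
    data: LabeledSpectra | tuple[np.ndarray, np.ndarray],
    split: SplitSpec = SplitSpec(),
) -> tuple[SELSTMModel, EvalReport, list[float]]:
    """Train an (SE-)LSTM on labelled spectra and report both splits.

    ``data`` is a LabeledSpectra (class codes derived from concentration
    levels) or an (X, y) pair.  Returns the model, the EvalReport on the
    calibration and prediction sets, and the per-epoch training loss
    curve.  Identical config + data reproduce identical results; a
    non-finite loss aborts with the epoch index.
    """
    if isinstance(data, LabeledSpectra):
        X, y = data.X, data.class_codes()
    else:
        X, y = data
        X = np.asarray(X, dtype=np.float64)
    y = _check_labels(y, config.n_classes)
    if config.n_bands != X.shape[1]:
        config = replace(config, n_bands=X.shape[1])
    cal_idx, pred_idx = stratified_split(y, split)
    if np.unique(y[cal_idx]).size < 2:
        raise ValueError("calibration split contains fewer than 2 classes")
    Xc, yc = X[cal_idx], y[cal_idx]
    Xp, yp = X[pred_idx], y[pred_idx]

    rng = np.random.default_rng(config.seed)
    model = SELSTMModel(config=config, params=_init_params(config, rng))
    if config.standardize:
        model.input_center = Xc.mean(axis=0)
        scale = Xc.std(axis=0)
        scale[scale == 0] = 1.0
        model.input_scale = scale
    opt = _Optimizer(config.optimizer, config.learning_rate, model.params)
    losses: list[float] = []
    n = Xc.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs, cache = _forward(model, Xc[idx], want_cache=True)
            p_true = np.clip(probs[np.arange(idx.size), yc[idx]], 1e-300, None)
            batch_loss = float(np.mean(-np.log(p_true)))
            epoch_loss += batch_loss * idx.size
            grads = _backward(model, cache, probs, yc[idx])
            opt.step(model.params, grads)
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise TrainingDiverged(epoch)
        losses.append(epoch_loss)
    report = evaluate(model, (Xc, yc), (Xp, yp))
    return model, report, losses


def _run_cell(config: SELSTMConfig, data, split: SplitSpec) -> dict:
    try:
        model, report, _ = train_selstm(config, data, split)
        row = report.to_dict()
        row["n_parameters"] = model.n_parameters()
        row["status"] = "ok"
    except Exception as exc:  # recorded per cell, not fatal
        row = {
            "accuracy_calibration": np.nan,
            "accuracy_prediction": np.nan,
            "loss_calibration": np.nan,
            "loss_prediction": np.nan,
            "overfit_coefficient": np.nan,
            "n_parameters": np.nan,
            "status": f"failed: {exc}",
        }
    return row


def grid_search_architecture(
    data,
    layer_grid: Sequence[int] = LAYER_GRID,
    unit_grid: Sequence[int] = UNIT_GRID,
    base_config: SELSTMConfig = SELSTMConfig(),
    split: SplitSpec = SplitSpec(),
) -> pd.DataFrame:
    """One seeded run per (layers, units) cell, ranked by prediction accuracy.

    Ties rank the smaller model first.  Failed cells keep their row with a
    status message instead of aborting the sweep.
    """
    if not layer_grid or not unit_grid:
        raise ValueError("empty architecture grid")
    rows = []
    for n_layers in layer_grid:
        for units in unit_grid:
            cfg = replace(base_config, n_layers=n_layers, units=units)
            row = _run_cell(cfg, data, split)
            row.update(n_layers=n_layers, units=units)
            rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["accuracy_prediction", "n_parameters"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def sweep_optimizer_lr(
    data,
    optimizers: Sequence[str] = OPTIMIZERS,
    learning_rates: Sequence[float] = LEARNING_RATES,
    base_config: SELSTMConfig = SELSTMConfig(),
    split: SplitSpec = SplitSpec(),
) -> pd.DataFrame:
    """Optimizer x learning-rate sweep (3 x 5 by default), ranked as the grid."""
    if not optimizers or not learning_rates:
        raise ValueError("empty optimizer/learning-rate sweep")
    rows = []
    for optname in optimizers:
        for lr in learning_rates:
            cfg = replace(base_config, optimizer=optname, learning_rate=lr)
            row = _run_cell(cfg, data, split)
            row.update(optimizer=optname, learning_rate=lr)
            rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["accuracy_prediction", "loss_prediction"],
        ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
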