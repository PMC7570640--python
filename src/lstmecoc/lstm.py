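"""Single-cell LSTM trained by backpropagation-through-time (BPTT).

The network is one LSTM cell with ``H`` hidden units (default 256) followed
by a fully-connected layer with three neurons and a softmax cross-entropy
loss.  Each input sequence is 60 time steps; the per-step input is the
flattened 63-channel x 100-sample block (6300 values).  The standard
Graves-style cell is used: for step t with previous hidden state h and cell
state c,

    f_t = sigmoid(W_f x_t + R_f h_{t-1} + b_f)        (forget gate)
    i_t = sigmoid(W_i x_t + R_i h_{t-1} + b_i)        (input gate)
    s_t = tanh   (W_s x_t + R_s h_{t-1} + b_s)        (cell candidate)
    o_t = sigmoid(W_o x_t + R_o h_{t-1} + b_o)        (output gate)
    c_t = f_t * c_{t-1} + i_t * s_t
    h_t = o_t * tanh(c_t)

Gradients are computed analytically by unrolling the recurrence over all
steps.  After training, the final hidden state h_60 is the feature vector
handed to the ECOC-SVM classifier.

Gate parameters are stored stacked as ``Wx`` [4H x D], ``Wh`` [4H x H] and
``b`` [4H] in gate order (f, i, s, o), which lets the whole input
projection for a batch be computed as a single matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .recording import CLASSES, STEP_INPUT_DIM, StepSequence, class_index

GATES = ("f", "i", "s", "o")
N_CLASSES = len(CLASSES)


@dataclass
class LSTMParams:
    """Gate weights/biases plus the fully-connected classification head."""

    Wx: np.ndarray  # [4H, D] input weights, gate order f, i, s, o
    Wh: np.ndarray  # [4H, H] recurrent weights
    b: np.ndarray   # [4H]    gate biases
    Wfc: np.ndarray  # [n_classes, H] head weights
    bfc: np.ndarray  # [n_classes]   head bias

    def __post_init__(self) -> None:
        H = self.Wh.shape[1]
        if self.Wx.shape[0] != 4 * H or self.Wh.shape != (4 * H, H):
            raise ValueError("inconsistent gate parameter shapes")
        if self.b.shape != (4 * H,):
            raise ValueError("bias shape mismatch")
        if self.Wfc.shape[1] != H:
            raise ValueError("head weight shape mismatch")
        for arr in (self.Wx, self.Wh, self.b, self.Wfc, self.bfc):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")

    @property
    def hidden_units(self) -> int:
        return self.Wh.shape[1]

    @property
    def input_dim(self) -> int:
        return self.Wx.shape[1]

    def gate(self, name: str, which: str = "Wx") -> np.ndarray:
        """Per-gate view of a stacked parameter (``which`` in Wx/Wh/b)."""
        H = self.hidden_units
        k = GATES.index(name)
        return getattr(self, which)[k * H:(k + 1) * H]

    def astype(self, dtype) -> "LSTMParams":
        return LSTMParams(*(getattr(self, f).astype(dtype)
                            for f in ("Wx", "Wh", "b", "Wfc", "bfc")))

    def copy(self) -> "LSTMParams":
        return LSTMParams(*(getattr(self, f).copy()
                            for f in ("Wx", "Wh", "b", "Wfc", "bfc")))


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults: the fixed published setting)."""

    learning_rate: float = 0.001
    mini_batch: int = 4
    l2: float = 0.0005
    optimizer: str = "adam"  # "adam" or "sgd_momentum"
    epochs: int = 30
    grad_clip: float | None = 1.0
    seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mini_batch < 1:
            raise ValueError("mini_batch must be >= 1")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd_momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FeatureVector:
    """Final-step hidden-state activations of one sequence."""

    values: np.ndarray
    id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).ravel()
        if self.label is not None:
            class_index(self.label)


def init_params(H: int, seed: int, input_dim: int = STEP_INPUT_DIM,
                n_classes: int = N_CLASSES) -> LSTMParams:
    """Deterministic initialization.

    Input weights are Glorot-uniform, recurrent weights orthogonal (per
    gate), biases zero except the forget-gate bias, which starts at 1 so
    the cell initially retains its state.
    """
    if H < 1:
        raise ValueError(f"hidden units must be >= 1, got {H}")
    rng = np.random.default_rng(seed)
    limit = np.sqrt(6.0 / (input_dim + H))
    Wx = rng.uniform(-limit, limit, (4 * H, input_dim))
    blocks = []
    for _ in GATES:
        q, r = np.linalg.qr(rng.standard_normal((H, H)))
        q *= np.sign(np.diag(r))  # fix QR sign ambiguity for determinism
        blocks.append(q)
    Wh = np.vstack(blocks)
    b = np.zeros(4 * H)
    b[:H] = 1.0  # forget gate
    limit_fc = np.sqrt(6.0 / (H + n_classes))
    Wfc = rng.uniform(-limit_fc, limit_fc, (n_classes, H))
    bfc = np.zeros(n_classes)
    return LSTMParams(Wx, Wh, b, Wfc, bfc)


def _forward_batch(X: np.ndarray, params: LSTMParams):
    """Unrolled forward pass for a batch.

    Parameters
    ----------
    X : ndarray, shape (B, T, D)

    Returns
    -------
    scores : ndarray (B, n_classes)
    cache : dict of per-step quantities needed by the backward pass
    """
    B, T, D = X.shape
    if D != params.input_dim:
        raise ValueError(
            f"sequence step dimension {D} != model input dimension {params.input_dim}"
        )
    H = params.hidden_units
    dtype = params.Wx.dtype
    # one big GEMM for the input projection of every step
    Zx = X.reshape(B * T, D) @ params.Wx.T
    Zx = Zx.reshape(B, T, 4 * H)
    h = np.zeros((B, H), dtype=dtype)
    c = np.zeros((B, H), dtype=dtype)
    gates = np.empty((B, T, 4 * H), dtype=dtype)
    cs = np.empty((B, T, H), dtype=dtype)
    hs = np.empty((B, T, H), dtype=dtype)
    for t in range(T):
        z = Zx[:, t] + h @ params.Wh.T + params.b
        f = expit(z[:, :H])
        i = expit(z[:, H:2 * H])
        s = np.tanh(z[:, 2 * H:3 * H])
        o = expit(z[:, 3 * H:])
        c = f * c + i * s
        h = o * np.tanh(c)
        gates[:, t, :H] = f
        gates[:, t, H:2 * H] = i
        gates[:, t, 2 * H:3 * H] = s
        gates[:, t, 3 * H:] = o
        cs[:, t] = c
        hs[:, t] = h
    scores = h @ params.Wfc.T + params.bfc
    cache = {"X": X, "gates": gates, "cs": cs, "hs": hs}
    return scores, cache


def lstm_forward(seq: StepSequence, params: LSTMParams):
    """Forward pass of one sequence.

    Returns ``(hidden_states [T x H], class_scores [n_classes])``.
    """
    X = seq.flattened_steps()[None].astype(params.Wx.dtype)
    scores, cache = _forward_batch(X, params)
    return cache["hs"][0], scores[0]


def _backward_batch(dscores: np.ndarray, params: LSTMParams, cache: dict):
    """BPTT gradients of the stacked parameters given d(loss)/d(scores)."""
    X, gates, cs, hs = cache["X"], cache["gates"], cache["cs"], cache["hs"]
    B, T, D = X.shape
    H = params.hidden_units
    dtype = params.Wx.dtype
    hT = hs[:, -1]
    grads = {
        "Wfc": dscores.T @ hT,
        "bfc": dscores.sum(axis=0),
    }
    dh = dscores @ params.Wfc
    dc = np.zeros((B, H), dtype=dtype)
    dZ = np.empty((B, T, 4 * H), dtype=dtype)
    for t in range(T - 1, -1, -1):
        f = gates[:, t, :H]
        i = gates[:, t, H:2 * H]
        s = gates[:, t, 2 * H:3 * H]
        o = gates[:, t, 3 * H:]
        c = cs[:, t]
        c_prev = cs[:, t - 1] if t > 0 else np.zeros_like(c)
        tanh_c = np.tanh(c)
        dc = dc + dh * o * (1.0 - tanh_c**2)
        dz = dZ[:, t]
        dz[:, :H] = dc * c_prev * f * (1.0 - f)
        dz[:, H:2 * H] = dc * s * i * (1.0 - i)
        dz[:, 2 * H:3 * H] = dc * i * (1.0 - s**2)
        dz[:, 3 * H:] = dh * tanh_c * o * (1.0 - o)
        dh = dz @ params.Wh
        dc = dc * f
    dZ_flat = dZ.reshape(B * T, 4 * H)
    grads["Wx"] = dZ_flat.T @ X.reshape(B * T, D)
    h_prev = np.concatenate(
        [np.zeros((B, 1, H), dtype=dtype), hs[:, :-1]], axis=1
    )
    grads["Wh"] = dZ_flat.T @ h_prev.reshape(B * T, H)
    grads["b"] = dZ_flat.sum(axis=0)
    return grads


def _softmax_xent(scores: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. scores (batch)."""
    lse = logsumexp(scores, axis=1)
    losses = lse - scores[np.arange(len(labels)), labels]
    probs = np.exp(scores - lse[:, None])
    dscores = probs
    dscores[np.arange(len(labels)), labels] -= 1.0
    dscores /= len(labels)
    return float(np.mean(losses)), dscores


def l2_penalty(params: LSTMParams, l2: float) -> float:
    """``l2 * 0.5 * sum(weights^2)`` over all weight matrices (not biases)."""
    if l2 == 0:
        return 0.0
    return float(l2 * 0.5 * (
        np.sum(params.Wx.astype(np.float64) ** 2)
        + np.sum(params.Wh.astype(np.float64) ** 2)
        + np.sum(params.Wfc.astype(np.float64) ** 2)
    ))


def compute_loss(class_scores: np.ndarray, label: int | str,
                 params: LSTMParams | None = None, l2: float = 0.0) -> float:
    """Softmax cross-entropy of one score vector, plus the L2 penalty."""
    idx = class_index(label) if isinstance(label, str) else int(label)
    scores = np.asarray(class_scores, dtype=np.float64)[None]
    loss, _ = _softmax_xent(scores, np.array([idx]))
    if l2 > 0:
        if params is None:
            raise ValueError("params required when l2 > 0")
        loss += l2_penalty(params, l2)
    return loss


def batch_loss_and_grads(X: np.ndarray, labels: np.ndarray,
                         params: LSTMParams, l2: float = 0.0):
    """Loss and analytic gradients for a batch (used by training and by the
    finite-difference gradient check)."""
    scores, cache = _forward_batch(X, params)
    loss, dscores = _softmax_xent(scores.astype(np.float64), labels)
    grads = _backward_batch(dscores.astype(params.Wx.dtype), params, cache)
    if l2 > 0:
        loss += l2_penalty(params, l2)
        for name in ("Wx", "Wh", "Wfc"):
            grads[name] = grads[name] + l2 * getattr(params, name)
    return loss, grads


def _clip_gradients(grads: dict, max_norm: float) -> dict:
    total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                        for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        grads = {k: g * scale for k, g in grads.items()}
    return grads


class _Adam:
    """ADAM optimizer state (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: LSTMParams, grads: dict) -> None:
        self.t += 1
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g**2
            mhat = self.m[name] / (1 - self.beta1**self.t)
            vhat = self.v[name] / (1 - self.beta2**self.t)
            p = getattr(params, name)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class _SGDMomentum:
    """SGD with classical momentum (0.9)."""

    def __init__(self, lr: float, momentum: float = 0.9):
        self.lr, self.momentum = lr, momentum
        self.v: dict = {}

    def step(self, params: LSTMParams, grads: dict) -> None:
        for name, g in grads.items():
            if name not in self.v:
                self.v[name] = np.zeros_like(g)
            self.v[name] = self.momentum * self.v[name] - self.lr * g
            p = getattr(params, name)
            p += self.v[name].astype(p.dtype)


def stack_sequences(dataset: list[StepSequence], dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
    """Stack sequences into ``X [N, T, D]`` and integer labels ``y [N]``."""
    if not dataset:
        raise ValueError("empty dataset")
    X = np.stack([s.flattened_steps() for s in dataset]).astype(dtype)
    labels = []
    for s in dataset:
        if s.label is None:
            raise ValueError(f"sequence {s.id!r} has no label")
        labels.append(class_index(s.label))
    return X, np.asarray(labels)


def train_lstm(dataset: list[StepSequence], config: TrainConfig,
               H: int = 256, init_seed: int | None = None):
    """Train on labelled step sequences; returns ``(params, loss_trace)``.

    Runs ``config.epochs`` passes over shuffled mini-batches; gradients by
    BPTT over all steps; updates by ADAM or SGD-with-momentum.  The loss
    trace holds the mean training loss (including L2 penalty) per epoch.
    Deterministic given ``config.seed``.
    """
    config.validate()
    X, y = stack_sequences(dataset, dtype=config.dtype)
    if len(np.unique(y)) < N_CLASSES:
        raise ValueError("training data must contain every class")
    rng = np.random.default_rng(config.seed)
    params = init_params(
        H, config.seed if init_seed is None else init_seed,
        input_dim=X.shape[2],
    ).astype(config.dtype)
    if config.optimizer == "adam":
        opt = _Adam(config.learning_rate)
    else:
        opt = _SGDMomentum(config.learning_rate)
    n = len(dataset)
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.mini_batch):
            idx = order[start:start + config.mini_batch]
            loss, grads = batch_loss_and_grads(X[idx], y[idx], params, config.l2)
            if config.grad_clip is not None:
                grads = _clip_gradients(grads, config.grad_clip)
            opt.step(params, grads)
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)))
    return params, trace


def extract_features(model: LSTMParams, seq: StepSequence,
                     pooling: str = "last") -> FeatureVector:
    """Hidden-state feature vector of one sequence (length H).

    ``pooling="last"`` (default) returns the final-step hidden state h_T;
    ``pooling="mean"`` averages the hidden states over all steps.
    """
    hidden, _ = lstm_forward(seq, model)
    if pooling == "last":
        values = hidden[-1]
    elif pooling == "mean":
        values = hidden.mean(axis=0)
    else:
        raise ValueError(f"pooling must be 'last' or 'mean', got {pooling!r}")
    return FeatureVector(values=values.astype(np.float64),
                         id=seq.id, label=seq.label)


def extract_feature_matrix(model: LSTMParams,
                           dataset: list[StepSequence]) -> np.ndarray:
    """Features for many sequences at once, shape (N, H)."""
    X = np.stack([s.flattened_steps() for s in dataset]).astype(model.Wx.dtype)
    _, cache = _forward_batch(X, model)
    return cache["hs"][:, -1].astype(np.float64)


def save_params(params: LSTMParams, path, config: TrainConfig | None = None) -> None:
    """Checkpoint: one array archive with a JSON metadata header."""
    import json

    meta = {"H": params.hidden_units, "input_dim": params.input_dim}
    if config is not None:
        meta["train_config"] = {k: v for k, v in vars(config).items()}
    np.savez_compressed(path, Wx=params.Wx, Wh=params.Wh, b=params.b,
                        Wfc=params.Wfc, bfc=params.bfc,
                        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_params(path) -> tuple[LSTMParams, dict]:
    """Load a checkpoint; returns ``(params, metadata)``."""
    import json

    with np.load(path, allow_pickle=False) as z:
        params = LSTMParams(z["Wx"], z["Wh"], z["b"], z["Wfc"], z["bfc"])
        meta = json.loads(bytes(z["meta"]).decode())
    return params, meta


def predict_softmax(model: LSTMParams, dataset: list[StepSequence]) -> np.ndarray:
    """Class predictions from the LSTM's own softmax head (ablation arm)."""
    X = np.stack([s.flattened_steps() for s in dataset]).astype(model.Wx.dtype)
    scores, _ = _forward_batch(X, model)
    return np.argmax(scores, axis=1)
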