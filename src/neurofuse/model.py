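"""Autoencoder pretraining and MLP classification, in NumPy.

The classifier is a feed-forward network with ReLU hidden layers and a
single sigmoid output giving the probability of the positive (case) class.
An autoencoder (ReLU encoder, linear decoder) is first trained to
reconstruct the scaled ROI features; its encoder can either initialise the
classifier's first layer (fine-tuned end-to-end, the single-modality route)
or act as a frozen feature extractor whose latents from several modalities
are concatenated before a fresh MLP (the multimodal latent-fusion route).

Training minimises binary cross-entropy (classifier) or mean squared
reconstruction error (autoencoder) with Adam at batch size 1, and stops
early when a held-out validation split stops improving, restoring the best
epoch's weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError, InvalidArgumentError
from .features import FeatureTable

__all__ = [
    "TrainConfig",
    "AutoencoderModel",
    "ClassifierModel",
    "train_autoencoder",
    "encode",
    "fuse_latents",
    "train_classifier",
    "predict_proba",
    "binary_cross_entropy",
]

_PROB_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults follow the small-cohort regime: Adam at learning rate 1e-3,
    mini-batch size 1, at most 500 epochs with patience-5 early stopping on
    a 10% validation split of the training data.  ``hidden_sizes`` are the
    classifier's hidden widths; with an encoder initialisation the first
    hidden width is the encoder's latent dimension instead.
    """

    learning_rate: float = 1e-3
    batch_size: int = 1
    max_epochs: int = 500
    patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0
    ae_epochs: int = 200
    hidden_sizes: tuple[int, ...] = (62, 32, 16)

    def __post_init__(self):
        if self.patience < 1:
            raise InvalidArgumentError("patience must be >= 1")
        if not 0 < self.validation_fraction < 0.5:
            raise InvalidArgumentError("validation_fraction must be in (0, 0.5)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise InvalidArgumentError("batch_size and max_epochs must be >= 1")


@dataclass
class AutoencoderModel:
    """Encoder/decoder weights of a one-hidden-layer autoencoder."""

    encoder_w: np.ndarray  # (R_in, d_latent)
    encoder_b: np.ndarray
    decoder_w: np.ndarray  # (d_latent, R_in)
    decoder_b: np.ndarray
    d_latent: int
    activation: str = "relu"
    log: list[dict] = field(default_factory=list, repr=False)

    def __post_init__(self):
        r_in, d = self.encoder_w.shape
        if d != self.d_latent or self.decoder_w.shape != (d, r_in):
            raise InvalidArgumentError("inconsistent encoder/decoder shapes")
        if self.d_latent >= r_in:
            raise InvalidArgumentError("d_latent must be smaller than input width")

    @property
    def n_inputs(self) -> int:
        return self.encoder_w.shape[0]


@dataclass
class ClassifierModel:
    """Feed-forward classifier: ReLU hidden layers, sigmoid output."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    layer_sizes: list[int]
    log: list[dict] = field(default_factory=list, repr=False)

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    def save_json(self, path) -> None:
        payload = {
            "layer_sizes": self.layer_sizes,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [np.asarray(w) for w in payload["weights"]],
            [np.asarray(b) for b in payload["biases"]],
            payload["layer_sizes"],
        )


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binary_cross_entropy(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clipping against ln 0."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    p = np.clip(np.asarray(y_prob, dtype=float).ravel(), _PROB_EPS, 1 - _PROB_EPS)
    return float(-np.mean(y_true * np.log(p) + (1 - y_true) * np.log(1 - p)))


class _Net:
    """Minimal dense network with Adam; used for both AE and classifier."""

    def __init__(self, sizes, out_activation, rng, frozen_layers=()):
        self.sizes = list(sizes)
        self.out_activation = out_activation
        self.frozen = set(frozen_layers)
        self.w, self.b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.w.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(w) for w in self.w] + [
            np.zeros_like(b) for b in self.b
        ]
        self._adam_v = [np.zeros_like(m) for m in self._adam_m]
        self._adam_t = 0

    def forward(self, x, keep=False):
        acts = [np.atleast_2d(np.asarray(x, dtype=float))]
        h = acts[0]
        last = len(self.w) - 1
        for i, (w, b) in enumerate(zip(self.w, self.b)):
            z = h @ w + b
            if i < last:
                h = _relu(z)
            elif self.out_activation == "sigmoid":
                h = _sigmoid(z)
            else:
                h = z
            acts.append(h)
        if keep:
            self._acts = acts
        return acts[-1]

    def backward(self, dz):
        """Gradients from the output pre-activation error ``dz`` (B, out)."""
        acts = self._acts
        grads_w, grads_b = [None] * len(self.w), [None] * len(self.b)
        delta = dz
        for i in reversed(range(len(self.w))):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.w[i].T) * (acts[i] > 0)
        return grads_w, grads_b

    def adam_step(self, grads_w, grads_b, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        params = self.w + self.b
        grads = grads_w + grads_b
        n_w = len(self.w)
        for i, (p, g) in enumerate(zip(params, grads)):
            layer = i if i < n_w else i - n_w
            if layer in self.frozen:
                continue
            m = self._adam_m[i] = 0.9 * self._adam_m[i] + (1 - beta1) * g
            v = self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g**2
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def snapshot(self):
        return [w.copy() for w in self.w], [b.copy() for b in self.b]

    def restore(self, snap):
        ws, bs = snap
        self.w = [w.copy() for w in ws]
        self.b = [b.copy() for b in bs]


def _loss_and_dz(net, x, y, kind):
    p = net.forward(x, keep=True)
    if kind == "bce":
        pc = np.clip(p, _PROB_EPS, 1 - _PROB_EPS)
        loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
        dz = (p - y) / x.shape[0]  # sigmoid + BCE shortcut
    else:  # mse
        diff = p - y
        loss = float(np.mean(diff**2))
        dz = 2.0 * diff / diff.size
    return loss, dz


def _eval_loss(net, x, y, kind):
    p = net.forward(x)
    if kind == "bce":
        return binary_cross_entropy(y, p)
    return float(np.mean((p - y) ** 2))


def _fit(net, x_tr, y_tr, x_val, y_val, cfg, max_epochs, loss_kind, rng):
    """Batch-wise Adam training with patience-based early stopping.

    The best validation loss and its weights are tracked each epoch; once
    ``patience`` epochs pass without improvement, training stops and the
    best weights are restored.  Returns the per-epoch log.
    """
    best_loss = _eval_loss(net, x_val, y_val, loss_kind)
    best_snap = net.snapshot()
    stale = 0
    log = [
        {
            "epoch": 0,
            "train_loss": _eval_loss(net, x_tr, y_tr, loss_kind),
            "val_loss": best_loss,
        }
    ]
    n = x_tr.shape[0]
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, dz = _loss_and_dz(net, x_tr[idx], y_tr[idx], loss_kind)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            gw, gb = net.backward(dz)
            net.adam_step(gw, gb, cfg.learning_rate)
        train_loss = _eval_loss(net, x_tr, y_tr, loss_kind)
        val_loss = _eval_loss(net, x_val, y_val, loss_kind)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise DivergenceError(epoch)
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss = val_loss
            best_snap = net.snapshot()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    net.restore(best_snap)
    return log


def _validation_split(y, fraction, rng, stratified):
    """Indices of (train, validation) rows; >= 1 validation row per stratum."""
    n = len(y)
    if stratified:
        val_idx = []
        for cls in np.unique(y):
            members = np.flatnonzero(y == cls)
            n_val = max(1, int(round(fraction * len(members))))
            if n_val >= len(members):
                raise InvalidArgumentError(
                    "too few samples in a class for a validation split"
                )
            val_idx.append(rng.permutation(members)[:n_val])
        val_idx = np.concatenate(val_idx)
    else:
        n_val = max(1, int(round(fraction * n)))
        if n_val >= n:
            raise InvalidArgumentError("too few samples for a validation split")
        val_idx = rng.permutation(n)[:n_val]
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    return np.flatnonzero(~val_mask), np.flatnonzero(val_mask)


def _as_matrix(t) -> np.ndarray:
    return t.matrix if isinstance(t, FeatureTable) else np.atleast_2d(np.asarray(t, float))


def train_autoencoder(
    train: FeatureTable | np.ndarray, d_latent: int, cfg: TrainConfig = TrainConfig()
) -> AutoencoderModel:
    """Fit a one-hidden-layer autoencoder on (scaled) training features.

    The encoder is a ReLU layer of width ``d_latent``; the decoder is
    linear.  Training minimises mean squared reconstruction error with Adam
    and patience-based early stopping on an unstratified validation split.
    """
    x = _as_matrix(train)
    r_in = x.shape[1]
    if d_latent >= r_in:
        raise InvalidArgumentError(
            f"d_latent={d_latent} must be smaller than input width {r_in}"
        )
    rng = np.random.default_rng(cfg.seed)
    tr_idx, val_idx = _validation_split(
        np.zeros(x.shape[0]), cfg.validation_fraction, rng, stratified=False
    )
    net = _Net([r_in, d_latent, r_in], out_activation="linear", rng=rng)
    log = _fit(
        net, x[tr_idx], x[tr_idx], x[val_idx], x[val_idx], cfg, cfg.ae_epochs, "mse", rng
    )
    return AutoencoderModel(
        net.w[0], net.b[0], net.w[1], net.b[1], d_latent=d_latent, log=log
    )


def encode(ae: AutoencoderModel, t: FeatureTable | np.ndarray) -> np.ndarray:
    """Latent representation ReLU(X We + be) of a feature table."""
    x = _as_matrix(t)
    if x.shape[1] != ae.n_inputs:
        raise InvalidArgumentError(
            f"feature width {x.shape[1]} != encoder input {ae.n_inputs}"
        )
    return _relu(x @ ae.encoder_w + ae.encoder_b)


def fuse_latents(latents: list[np.ndarray]) -> np.ndarray:
    """Column-wise concatenation of per-modality latent matrices."""
    if not latents:
        raise InvalidArgumentError("no latents to fuse")
    rows = {np.atleast_2d(m).shape[0] for m in latents}
    if len(rows) != 1:
        raise InvalidArgumentError(f"row counts differ across latents: {rows}")
    return np.hstack([np.atleast_2d(np.asarray(m, float)) for m in latents])


def train_classifier(
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    encoder_init: AutoencoderModel | None = None,
    freeze_encoder: bool = False,
) -> ClassifierModel:
    """Train the MLP classifier, optionally seeded by an encoder.

    With ``encoder_init`` the first hidden layer is the encoder (width =
    d_latent) and is fine-tuned with the rest unless ``freeze_encoder``.
    Without it the hidden widths come from ``cfg.hidden_sizes``.  A
    stratified validation split of the training rows drives patience-based
    early stopping on validation cross-entropy.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != len(y):
        raise InvalidArgumentError("X rows must match y length")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
        raise InvalidArgumentError("y must contain both binary classes")

    rng = np.random.default_rng(cfg.seed)
    if encoder_init is not None:
        if encoder_init.n_inputs != x.shape[1]:
            raise InvalidArgumentError(
                "encoder input width does not match the feature width"
            )
        hidden = (encoder_init.d_latent,) + tuple(cfg.hidden_sizes[1:])
    else:
        hidden = tuple(cfg.hidden_sizes)
    sizes = [x.shape[1], *hidden, 1]
    frozen = (0,) if (encoder_init is not None and freeze_encoder) else ()
    net = _Net(sizes, out_activation="sigmoid", rng=rng, frozen_layers=frozen)
    if encoder_init is not None:
        net.w[0] = encoder_init.encoder_w.copy()
        net.b[0] = encoder_init.encoder_b.copy()

    tr_idx, val_idx = _validation_split(y, cfg.validation_fraction, rng, stratified=True)
    y_col = y[:, None]
    log = _fit(
        net,
        x[tr_idx],
        y_col[tr_idx],
        x[val_idx],
        y_col[val_idx],
        cfg,
        cfg.max_epochs,
        "bce",
        rng,
    )
    return ClassifierModel(net.w, net.b, sizes, log=log)


def predict_proba(m: ClassifierModel, x: np.ndarray) -> np.ndarray:
    """Forward pass returning the positive-class probability per row."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != m.n_inputs:
        raise InvalidArgumentError(
            f"feature width {x.shape[1]} != model input {m.n_inputs}"
        )
    net = _Net.__new__(_Net)
    net.sizes = m.layer_sizes
    net.out_activation = "sigmoid"
    net.frozen = set()
    net.w, net.b = m.weights, m.biases
    return net.forward(x).ravel()
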