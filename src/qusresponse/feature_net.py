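"""Convolutional feature network for QUS parametric images.

A residual (ResNet-style) or residual-attention (RAN-style) backbone maps a
4-channel parametric image to a 256-d feature vector (global average
pooling followed by a linear projection).  For plane-level pretraining a
fully connected head (256 -> 100 -> 2 with dropout) is appended and the
network is trained with class-weighted cross-entropy, Adam, stochastic
flip/shift augmentation and early stopping on validation loss.  The
penultimate 256-d representation is the per-plane feature consumed by the
patient-level predictor.

Labels are encoded 0 = responder, 1 = non-responder; the non-responder
class (the clinical minority) carries the cost weight C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nnet
from .parametric_mapping import NetworkInput

__all__ = [
    "RESPONDER_LABEL",
    "NON_RESPONDER_LABEL",
    "BackboneConfig",
    "TrainConfig",
    "FeatureVector",
    "ResidualBlock",
    "AttentionModule",
    "FeatureNet",
    "augment_batch",
    "train_feature_net",
    "extract_features",
    "encode_label",
]

RESPONDER_LABEL = 0
NON_RESPONDER_LABEL = 1

_LABEL_MAP = {
    "responder": RESPONDER_LABEL,
    "non-responder": NON_RESPONDER_LABEL,
    RESPONDER_LABEL: RESPONDER_LABEL,
    NON_RESPONDER_LABEL: NON_RESPONDER_LABEL,
}


def encode_label(label) -> int:
    try:
        return _LABEL_MAP[label]
    except KeyError:
        raise ValueError(f"unknown response label: {label!r}") from None


@dataclass(frozen=True)
class BackboneConfig:
    architecture: str = "ran"  # "resnet" | "ran"
    depth_preset: str = "small"  # "small" | "full"
    in_channels: int = 4
    feature_dim: int = 256
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.architecture not in ("resnet", "ran"):
            raise ValueError("architecture must be 'resnet' or 'ran'")
        if self.depth_preset not in ("small", "full"):
            raise ValueError("depth_preset must be 'small' or 'full'")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 8
    dropout: float = 0.5
    class_weight_c: float = 5.0  # non-responder : responder cost ratio
    max_epochs: int = 100
    early_stopping_patience: int = 10
    hflip: bool = True
    shift_max_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_weight_c < 1:
            raise ValueError("class weight C must be >= 1")
        if not (0.0 <= self.shift_max_fraction < 1.0):
            raise ValueError("shift fraction must be in [0, 1)")


@dataclass
class FeatureVector:
    values: np.ndarray  # length 256
    plane_id: str = ""
    patient_id: str = ""


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class ResidualBlock(nnet.Layer):
    """Residual unit y = F(x) + shortcut(x) with F = conv-relu-conv.

    The shortcut is the identity when shape is preserved, else a strided
    1x1 convolution.  With all convolution weights zero and an identity
    shortcut the block is exactly the identity map (the skip-connection
    contract), and gradients always reach the input through the skip.
    """

    def __init__(self, c_in: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.conv1 = nnet.Conv2D(c_in, c_out, 3, stride=stride, rng=rng)
        self.relu1 = nnet.ReLU()
        self.conv2 = nnet.Conv2D(c_out, c_out, 3, stride=1, rng=rng)
        self.identity_shortcut = c_in == c_out and stride == 1
        self.shortcut = (
            None if self.identity_shortcut
            else nnet.Conv2D(c_in, c_out, 1, stride=stride, pad=0, rng=rng)
        )

    def params(self):
        p = self.conv1.params() + self.conv2.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def forward(self, x, train=False):
        f = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, train), train), train)
        s = x if self.identity_shortcut else self.shortcut.forward(x, train)
        if f.shape != s.shape:
            raise ValueError("residual and shortcut branch shapes differ")
        return f + s

    def backward(self, grad):
        dx_f = self.conv1.backward(self.relu1.backward(self.conv2.backward(grad)))
        dx_s = grad if self.identity_shortcut else self.shortcut.backward(grad)
        return dx_f + dx_s


class AttentionModule(nnet.Layer):
    """Attention-residual module: y = (1 + M(x)) * T(x).

    The trunk T is a residual block; the mask branch M is a small
    bottom-up/top-down encoder-decoder (average-pool, conv, upsample,
    conv) terminated by a sigmoid, so M lies strictly in (0, 1) and the
    module can only re-weight, never destroy, the trunk information.
    ``mask_override`` forces M to a constant (testing hook).
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.trunk = ResidualBlock(channels, channels, 1, rng=rng)
        self.mask_branch = nnet.Sequential([
            nnet.AvgPool2D(2),
            nnet.Conv2D(channels, channels, 3, rng=rng),
            nnet.ReLU(),
            nnet.UpsampleNearest(2),
            nnet.Conv2D(channels, channels, 1, pad=0, rng=rng),
            nnet.Sigmoid(),
        ])
        self.mask_override: float | None = None

    def params(self):
        return self.trunk.params() + self.mask_branch.params()

    def forward(self, x, train=False):
        t = self.trunk.forward(x, train)
        if self.mask_override is not None:
            m = np.full_like(t, self.mask_override)
            self._override = True
        else:
            m = self.mask_branch.forward(x, train)
            self._override = False
        if m.shape != t.shape:
            raise ValueError("mask and trunk branch shapes differ")
        self._t, self._m = t, m
        return (1.0 + m) * t

    def mask(self, x: np.ndarray) -> np.ndarray:
        """Soft attention mask M(x), elementwise in (0, 1)."""
        return self.mask_branch.forward(x, train=False)

    def backward(self, grad):
        dt = grad * (1.0 + self._m)
        dx = self.trunk.backward(dt)
        if not self._override:
            dm = grad * self._t
            dx = dx + self.mask_branch.backward(dm)
        return dx


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class FeatureNet:
    """Backbone + 256-d projection + plane-level classification head."""

    def __init__(self, config: BackboneConfig | None = None,
                 rng: np.random.Generator | None = None,
                 dropout: float = 0.5):
        cfg = config or BackboneConfig()
        rng = rng or np.random.default_rng()
        self.config = cfg
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        attn = cfg.architecture == "ran"
        if cfg.depth_preset == "small":
            widths, blocks = (8, 16, 32), (1, 1, 1)
        else:
            widths, blocks = (16, 32, 64, 128), (3, 4, 6, 3)
        layers: list[nnet.Layer] = [
            nnet.Conv2D(cfg.in_channels, widths[0], 3, stride=2, rng=rng),
            nnet.ReLU(),
        ]
        c_prev = widths[0]
        for stage, (c, nb) in enumerate(zip(widths, blocks)):
            for b in range(nb):
                stride = 2 if (b == 0 and stage > 0) else 1
                layers.append(ResidualBlock(c_prev, c, stride, rng=rng))
                c_prev = c
            if attn:
                layers.append(AttentionModule(c, rng=rng))
        layers.append(nnet.GlobalAvgPool())
        self.backbone = nnet.Sequential(layers)
        self.proj = nnet.Dense(c_prev, cfg.feature_dim, rng=rng)
        self.head = nnet.Sequential([
            nnet.Dropout(dropout, rng=self._dropout_rng),
            nnet.Dense(cfg.feature_dim, 100, rng=rng),
            nnet.ReLU(),
            nnet.Dropout(dropout, rng=self._dropout_rng),
            nnet.Dense(100, cfg.n_classes, rng=rng),
        ])

    def params(self):
        return self.backbone.params() + self.proj.params() + self.head.params()

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """256-d penultimate representation for a batch (N, 4, S, S)."""
        return self.proj.forward(self.backbone.forward(x, train=train), train=train)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.features(x, train=train), train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.backbone.backward(self.proj.backward(self.head.backward(dlogits)))

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def augment_batch(
    x: np.ndarray,
    rng: np.random.Generator,
    hflip: bool = True,
    shift_max_fraction: float = 0.3,
) -> np.ndarray:
    """Stochastic horizontal flip and 2-D shift with zero fill, per sample."""
    out = x.copy()
    n, _, h, w = x.shape
    max_dy = int(shift_max_fraction * h)
    max_dx = int(shift_max_fraction * w)
    for i in range(n):
        if hflip and rng.random() < 0.5:
            out[i] = out[i, :, :, ::-1]
        dy = int(rng.integers(-max_dy, max_dy + 1)) if max_dy else 0
        dx = int(rng.integers(-max_dx, max_dx + 1)) if max_dx else 0
        if dy or dx:
            shifted = np.zeros_like(out[i])
            ys = slice(max(dy, 0), h + min(dy, 0))
            yt = slice(max(-dy, 0), h + min(-dy, 0))
            xs = slice(max(dx, 0), w + min(dx, 0))
            xt = slice(max(-dx, 0), w + min(-dx, 0))
            shifted[:, ys, xs] = out[i][:, yt, xt]
            out[i] = shifted
    return out


def _as_xy(items, what: str, require_both: bool = False) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for inp, label in items:
        xs.append(inp.tensor if isinstance(inp, NetworkInput) else np.asarray(inp))
        ys.append(encode_label(label))
    y = np.asarray(ys)
    if require_both and len(np.unique(y)) < 2:
        raise ValueError(f"{what} set must contain both response classes")
    return np.stack(xs), y


def train_loop(
    net,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    augment: bool = False,
) -> list[dict]:
    """Shared minibatch training loop with early stopping on validation loss."""
    ss = np.random.SeedSequence(cfg.seed)
    ss_shuffle, ss_aug, ss_drop = ss.spawn(3)
    shuffle_rng = np.random.default_rng(ss_shuffle)
    aug_rng = np.random.default_rng(ss_aug)
    # re-seed the net's dropout stream for reproducible training
    for layer in _iter_layers(net):
        if isinstance(layer, nnet.Dropout):
            layer.rng = np.random.default_rng(ss_drop)
    weights = np.array([1.0, cfg.class_weight_c])
    opt = nnet.Adam(net.params(), lr=cfg.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_state = net.get_state()
    since_best = 0
    n = len(x_train)
    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            if augment:
                xb = augment_batch(xb, aug_rng, cfg.hflip, cfg.shift_max_fraction)
            opt.zero_grad()
            logits = net.forward_logits(xb, train=True)
            loss, dlogits = nnet.weighted_cross_entropy(logits, yb, weights)
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        val_logits = net.forward_logits(x_val, train=False)
        val_loss, _ = nnet.weighted_cross_entropy(val_logits, y_val, weights)
        val_acc = float(np.mean(val_logits.argmax(axis=1) == y_val))
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / n,
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        })
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = net.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stopping_patience:
                break
    net.set_state(best_state)
    return history


def _iter_layers(net):
    stack = [net.backbone, net.head] if hasattr(net, "backbone") else [net.net]
    while stack:
        item = stack.pop()
        if isinstance(item, nnet.Sequential):
            stack.extend(item.layers)
        else:
            yield item


def train_feature_net(
    train_images,
    val_images,
    backbone: BackboneConfig | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[FeatureNet, list[dict]]:
    """Train the plane-level feature network.

    ``train_images`` / ``val_images`` are sequences of
    ``(NetworkInput, label)`` where each imaging plane is an independent
    training sample carrying its tumor's response label.
    """
    cfg = cfg or TrainConfig()
    x_tr, y_tr = _as_xy(train_images, "training", require_both=True)
    x_va, y_va = _as_xy(val_images, "validation")
    init_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 17)))
    net = FeatureNet(backbone, rng=init_rng, dropout=cfg.dropout)
    history = train_loop(net, x_tr, y_tr, x_va, y_va, cfg, augment=True)
    return net, history


def extract_features(net: FeatureNet, img: NetworkInput) -> FeatureVector:
    """Deterministic (inference-mode) 256-d feature vector of one plane."""
    vec = net.features(img.tensor[None, ...], train=False)[0]
    return FeatureVector(values=vec, plane_id=img.plane_id, patient_id=img.patient_id)
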