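"""Patient-level response prediction from averaged plane features.

The 256-d feature vectors of all imaging planes of a tumor are averaged
into a single patient feature ("the tumor volume average"), which a small
fully connected network (input 256, hidden 100, softmax over 2 classes,
dropout after the first and second layers) maps to responder /
non-responder probabilities.  The feature network stays frozen while this
predictor is trained (two-stage training), with the same class-weighted
cross-entropy, Adam optimizer and early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnet
from .feature_net import (
    NON_RESPONDER_LABEL,
    RESPONDER_LABEL,
    FeatureVector,
    TrainConfig,
    encode_label,
    train_loop,
)

__all__ = [
    "PatientFeature",
    "PredictorConfig",
    "PredictionResult",
    "PredictorNet",
    "average_features",
    "train_predictor",
    "predict_patient",
]


@dataclass
class PatientFeature:
    patient_id: str
    mean_vector: np.ndarray  # length 256
    n_planes: int

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        if self.n_planes < 1:
            raise ValueError("a patient needs at least one plane")


@dataclass
class PredictorConfig:
    input_dim: int = 256
    hidden_width: int = 100
    n_classes: int = 2
    dropout: float = 0.5
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or self.hidden_width <= 0:
            raise ValueError("layer widths must be positive")


@dataclass
class PredictionResult:
    patient_id: str
    p_responder: float
    p_nonresponder: float
    predicted_label: str

    def __post_init__(self) -> None:
        total = self.p_responder + self.p_nonresponder
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("class probabilities must sum to 1")


class PredictorNet:
    """Fully connected response predictor over a 256-d patient feature."""

    def __init__(self, config: PredictorConfig | None = None,
                 rng: np.random.Generator | None = None):
        cfg = config or PredictorConfig()
        rng = rng or np.random.default_rng()
        self.config = cfg
        drop_rng = np.random.default_rng(rng.integers(2**31))
        self.net = nnet.Sequential([
            nnet.Dropout(cfg.dropout, rng=drop_rng),
            nnet.Dense(cfg.input_dim, cfg.hidden_width, rng=rng),
            nnet.ReLU(),
            nnet.Dropout(cfg.dropout, rng=drop_rng),
            nnet.Dense(cfg.hidden_width, cfg.n_classes, rng=rng),
        ])

    def params(self):
        return self.net.params()

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)

    def get_state(self):
        return [p.value.copy() for p in self.params()]

    def set_state(self, state):
        for p, v in zip(self.params(), state):
            p.value[...] = v


def average_features(plane_vectors: list[FeatureVector]) -> PatientFeature:
    """Elementwise mean of one patient's plane features (order-invariant)."""
    if not plane_vectors:
        raise ValueError("cannot average an empty list of plane features")
    ids = {v.patient_id for v in plane_vectors}
    if len(ids) > 1:
        raise ValueError(f"plane features from multiple patients: {sorted(ids)}")
    stacked = np.stack([np.asarray(v.values, dtype=float) for v in plane_vectors])
    return PatientFeature(
        patient_id=plane_vectors[0].patient_id,
        mean_vector=stacked.mean(axis=0),
        n_planes=len(plane_vectors),
    )


def _as_xy(items, require_both: bool):
    xs, ys = [], []
    for feat, label in items:
        vec = feat.mean_vector if isinstance(feat, PatientFeature) else np.asarray(feat)
        xs.append(np.asarray(vec, dtype=float))
        ys.append(encode_label(label))
    y = np.asarray(ys)
    if require_both and len(np.unique(y)) < 2:
        raise ValueError("training set must contain both response classes")
    return np.stack(xs), y


def train_predictor(
    features,
    val_features,
    config: PredictorConfig | None = None,
) -> tuple[PredictorNet, list[dict]]:
    """Train the patient-level predictor on (PatientFeature, label) pairs."""
    cfg = config or PredictorConfig()
    x_tr, y_tr = _as_xy(features, require_both=True)
    x_va, y_va = _as_xy(val_features, require_both=False)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.train.seed, 23)))
    net = PredictorNet(cfg, rng=rng)
    history = train_loop(net, x_tr, y_tr, x_va, y_va, cfg.train, augment=False)
    return net, history


def predict_patient(predictor: PredictorNet, feature: PatientFeature) -> PredictionResult:
    """Softmax response probabilities for one patient (dropout off)."""
    x = np.asarray(feature.mean_vector, dtype=float)[None, :]
    if x.shape[1] != predictor.config.input_dim:
        raise ValueError(
            f"expected feature dim {predictor.config.input_dim}, got {x.shape[1]}"
        )
    probs = nnet.softmax(predictor.forward_logits(x, train=False))[0]
    label = "non-responder" if probs[NON_RESPONDER_LABEL] >= probs[RESPONDER_LABEL] else "responder"
    # argmax decision; ties go to the positive (non-responder) class
    if probs[NON_RESPONDER_LABEL] == probs[RESPONDER_LABEL]:
        label = "non-responder"
    return PredictionResult(
        patient_id=feature.patient_id,
        p_responder=float(probs[RESPONDER_LABEL]),
        p_nonresponder=float(probs[NON_RESPONDER_LABEL]),
        predicted_label=label,
    )
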