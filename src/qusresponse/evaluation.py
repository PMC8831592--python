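"""Ground-truth labeling, splits, metrics, survival analysis and PDA maps.

Covers the evaluation side of the pipeline: the modified-response (MR)
grading rule that defines responders, stratified train/validation/test
splitting, classification metrics in the convention where the positive
class is the *non-responder* (sensitivity = correctly identified
non-responders, specificity = correctly identified responders), ROC AUC,
Kaplan–Meier curves with a log-rank test (via lifelines), and
prediction-difference-analysis (PDA) occlusion maps that attribute a
patient-level prediction to regions of each input parametric image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score

from .feature_net import NON_RESPONDER_LABEL, FeatureNet, encode_label
from .parametric_mapping import NetworkInput
from .patient_predictor import PatientFeature, PredictionResult, PredictorNet, predict_patient

__all__ = [
    "MrGradeInput",
    "SplitSpec",
    "MetricsSummary",
    "SurvivalRecord",
    "PdaMap",
    "mr_grade",
    "stratified_split",
    "compute_metrics",
    "km_curve",
    "log_rank",
    "pda_maps",
]


# ---------------------------------------------------------------------------
# Ground-truth labeling
# ---------------------------------------------------------------------------

@dataclass
class MrGradeInput:
    """Tumor sizing and cellularity findings used for response grading."""

    initial_size_cm: float
    residual_size_cm: float
    very_low_cellularity: bool = False
    no_malignant_cells: bool = False

    def __post_init__(self) -> None:
        if self.initial_size_cm < 0 or self.residual_size_cm < 0:
            raise ValueError("tumor sizes cannot be negative")


def mr_grade(inp: MrGradeInput) -> tuple[int, str]:
    """Modified-response score (1-5) and the derived response label.

    MR 1: no reduction; MR 2: < 30 % reduction; MR 3: 30-90 % reduction or
    very low residual cellularity; MR 4: > 90 % reduction with residual
    malignant cells; MR 5: no malignant cells.  Responder iff MR >= 3.
    A residual larger than the initial tumor is valid (MR 1).
    """
    if inp.no_malignant_cells:
        score = 5
    else:
        if inp.initial_size_cm <= 0:
            raise ValueError("initial size must be positive when malignant cells remain")
        r = (inp.initial_size_cm - inp.residual_size_cm) / inp.initial_size_cm
        if r > 0.90:
            score = 4
        elif inp.very_low_cellularity or r >= 0.30:
            score = 3
        elif r > 0.0:
            score = 2
        else:
            score = 1
    return score, ("responder" if score >= 3 else "non-responder")


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.30
    validation_fraction_of_train: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.validation_fraction_of_train):
            if not (0.0 < f < 1.0):
                raise ValueError("split fractions must lie in (0, 1)")


def _allocate(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` over classes ∝ counts."""
    quota = counts * total / counts.sum()
    base = np.floor(quota).astype(int)
    rest = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rest]] += 1
    return np.minimum(base, counts)


def stratified_split(labels, spec: SplitSpec | None = None):
    """Stratified train/validation/test partition of patient indices.

    ``labels`` is a sequence of response labels (or records with a
    ``label`` attribute).  Class proportions are preserved within rounding
    (largest-remainder allocation per class); the partition is disjoint,
    exhaustive and reproducible from the seed.
    Returns ``(train_idx, val_idx, test_idx)`` integer arrays.
    """
    spec = spec or SplitSpec()
    labs = np.asarray([getattr(l, "label", l) for l in labels])
    classes, counts = np.unique(labs, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("each class needs at least two members to stratify")
    rng = np.random.default_rng(spec.seed)
    n = len(labs)
    n_test = int(round(n * spec.test_fraction))
    test_per_class = _allocate(counts, n_test)
    train_idx, val_idx, test_idx = [], [], []
    pool_counts = counts - test_per_class
    n_val = int(round(pool_counts.sum() * spec.validation_fraction_of_train))
    val_per_class = _allocate(pool_counts, n_val)
    for cls, n_t, n_v in zip(classes, test_per_class, val_per_class):
        members = np.where(labs == cls)[0]
        members = rng.permutation(members)
        test_idx.extend(members[:n_t])
        val_idx.extend(members[n_t : n_t + n_v])
        train_idx.extend(members[n_t + n_v :])
    return (
        np.sort(np.asarray(train_idx, int)),
        np.sort(np.asarray(val_idx, int)),
        np.sort(np.asarray(test_idx, int)),
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsSummary:
    accuracy: float
    sensitivity: float  # non-responders predicted non-responder
    specificity: float  # responders predicted responder
    auc: float
    flags: list = field(default_factory=list)


def compute_metrics(predictions, labels) -> MetricsSummary:
    """Classification metrics with non-responder as the positive class.

    ``predictions`` may be a list of :class:`PredictionResult` or an array
    of non-responder probabilities (argmax/0.5 threshold for the label).
    A class absent from ``labels`` leaves the corresponding rate (and AUC)
    as NaN with an explanatory flag rather than a silent zero.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to score")
    if isinstance(predictions[0], PredictionResult):
        p_non = np.asarray([p.p_nonresponder for p in predictions])
        pred = np.asarray([encode_label(p.predicted_label) for p in predictions])
    else:
        p_non = np.asarray(predictions, dtype=float)
        pred = (p_non >= 0.5).astype(int)
    y = np.asarray([encode_label(getattr(l, "label", l)) for l in labels])
    if len(y) != len(p_non):
        raise ValueError("predictions and labels differ in length")

    acc = float(np.mean(pred == y))
    flags: list[str] = []
    pos = y == NON_RESPONDER_LABEL
    sens = spec = auc = np.nan
    if pos.any():
        sens = float(np.mean(pred[pos] == NON_RESPONDER_LABEL))
    else:
        flags.append("no non-responders: sensitivity undefined")
    if (~pos).any():
        spec = float(np.mean(pred[~pos] != NON_RESPONDER_LABEL))
    else:
        flags.append("no responders: specificity undefined")
    if pos.any() and (~pos).any():
        auc = float(roc_auc_score(pos.astype(int), p_non))
    else:
        flags.append("single-class labels: AUC undefined")
    return MetricsSummary(accuracy=acc, sensitivity=sens, specificity=spec,
                          auc=auc, flags=flags)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalRecord:
    patient_id: str
    time_months: float
    event: bool  # True = recurrence/death observed
    group: str = ""

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError("survival time must be positive")


def km_curve(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan–Meier product-limit estimate as a right-continuous step.

    Returns ``(times, survival)`` starting at (0, 1).
    """
    if not records:
        raise ValueError("no survival records")
    t = np.asarray([r.time_months for r in records])
    e = np.asarray([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def log_rank(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two survival groups.

    Returns ``(chi_square_statistic, p_value)`` from the asymptotic
    chi-square(1) tail.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ea = [r.event for r in group_a]
    eb = [r.event for r in group_b]
    if not (any(ea) or any(eb)):
        raise ValueError("log-rank test undefined with zero observed events")
    res = logrank_test(
        [r.time_months for r in group_a],
        [r.time_months for r in group_b],
        event_observed_A=ea,
        event_observed_B=eb,
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Prediction difference analysis
# ---------------------------------------------------------------------------

@dataclass
class PdaMap:
    """Per-channel occlusion-impact maps for one target plane."""

    channel_maps: np.ndarray  # (4, n_pos, n_pos), all >= 0
    patch_size: int
    overlap: float
    predicted_class: int
    baseline_probability: float


def pda_maps(
    feature_net: FeatureNet,
    predictor: PredictorNet,
    patient_planes: list[NetworkInput],
    target_plane: int,
    patch: int = 8,
    overlap: float = 0.5,
    batch_size: int = 64,
) -> PdaMap:
    """Occlusion attribution of the patient-level prediction to one plane.

    For every channel and every ``patch`` x ``patch`` position (stride
    ``patch * (1 - overlap)``), the patch is zeroed in that channel of the
    target plane only, the target plane's feature vector is recomputed with
    all other planes' features held fixed, and the absolute change of the
    originally predicted class probability is assigned to the patch center.
    """
    tensors = [p.tensor for p in patient_planes]
    n_ch, h, w = tensors[0].shape
    if patch > min(h, w):
        raise ValueError("occlusion patch larger than the image")
    step = max(1, int(round(patch * (1.0 - overlap))))
    if not (0 <= target_plane < len(patient_planes)):
        raise ValueError("target plane index out of range")

    feats = [feature_net.features(t[None])[0] for t in tensors]
    n_planes = len(feats)
    others_sum = np.sum(feats, axis=0) - feats[target_plane]
    base_feat = (others_sum + feats[target_plane]) / n_planes
    base = predict_patient(
        predictor, PatientFeature("pda", base_feat, n_planes)
    )
    cls = encode_label(base.predicted_label)
    p0 = base.p_nonresponder if cls == NON_RESPONDER_LABEL else base.p_responder

    ys = np.arange(0, h - patch + 1, step)
    xs = np.arange(0, w - patch + 1, step)
    maps = np.zeros((n_ch, ys.size, xs.size))
    target = tensors[target_plane]

    occluded, coords = [], []
    def _flush():
        if not occluded:
            return
        batch = np.stack(occluded)
        f = feature_net.features(batch)
        means = (others_sum[None, :] + f) / n_planes
        logits = predictor.forward_logits(means, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        for (ch, iy, ix), p in zip(coords, probs[:, cls]):
            maps[ch, iy, ix] = abs(p - p0)
        occluded.clear()
        coords.clear()

    for ch in range(n_ch):
        for iy, y0 in enumerate(ys):
            for ix, x0 in enumerate(xs):
                if not np.any(target[ch, y0 : y0 + patch, x0 : x0 + patch]):
                    continue  # zero patch: occlusion is a no-op, impact 0
                t = target.copy()
                t[ch, y0 : y0 + patch, x0 : x0 + patch] = 0.0
                occluded.append(t)
                coords.append((ch, iy, ix))
                if len(occluded) >= batch_size:
                    _flush()
    _flush()
    return PdaMap(
        channel_maps=maps, patch_size=patch, overlap=overlap,
        predicted_class=cls, baseline_probability=p0,
    )
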