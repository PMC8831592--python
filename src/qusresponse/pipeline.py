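"""End-to-end experiment driver: cohort -> maps -> features -> prediction.

Chains the pipeline stages exactly as they are applied to clinical data:
stratified patient split, parametric-map generation per plane, train-set
min-max normalization, two-stage network training (plane-level feature net,
then the patient-level predictor on averaged frozen features) and test-set
evaluation.  Used by the command-line interface and by the synthetic
end-to-end experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import MetricsSummary, SplitSpec, compute_metrics, stratified_split
from .feature_net import (
    BackboneConfig,
    FeatureNet,
    TrainConfig,
    extract_features,
    train_feature_net,
)
from .parametric_mapping import (
    NormParams,
    ParametricImage,
    SlidingGrid,
    compute_norm_params,
    generate_maps,
    preprocess_for_network,
)
from .patient_predictor import (
    PredictorConfig,
    PredictorNet,
    average_features,
    predict_patient,
    train_predictor,
)
from .qus_spectra import QusConfig
from .synthetic_rf import SyntheticCohort

__all__ = [
    "ExperimentResult",
    "cohort_parametric_images",
    "run_experiment",
    "synthetic_study",
]


@dataclass
class ExperimentResult:
    metrics: MetricsSummary
    predictions: list
    test_labels: list[str]
    feature_net: FeatureNet
    predictor: PredictorNet
    norm_params: NormParams
    split: tuple[np.ndarray, np.ndarray, np.ndarray]
    feature_history: list[dict] = field(default_factory=list)
    predictor_history: list[dict] = field(default_factory=list)


def cohort_parametric_images(
    cohort: SyntheticCohort,
    grid: SlidingGrid | None = None,
    qus_config: QusConfig | None = None,
) -> list[list[ParametricImage]]:
    """Parametric images for every plane of every patient (cohort order)."""
    return [
        [
            generate_maps(pl.frame, cohort.reference_frame, pl.contour,
                          grid=grid, config=qus_config)
            for pl in patient.planes
        ]
        for patient in cohort.patients
    ]


def run_experiment(
    cohort: SyntheticCohort,
    mode: str = "core+margin",
    backbone: BackboneConfig | None = None,
    train_cfg: TrainConfig | None = None,
    split_spec: SplitSpec | None = None,
    grid: SlidingGrid | None = None,
    qus_config: QusConfig | None = None,
    input_size: int = 64,
    images: list[list[ParametricImage]] | None = None,
    label_override: list[str] | None = None,
) -> ExperimentResult:
    """Train and evaluate the two-stage model on a cohort.

    ``images`` allows reusing precomputed parametric maps (they do not
    depend on labels or splits); ``label_override`` replaces the patient
    labels, which is how permutation-control experiments are run.
    ``input_size`` is the side of the square network input (512 in the
    clinical protocol; smaller for desk-scale experiments).
    """
    train_cfg = train_cfg or TrainConfig()
    labels = [p.label for p in cohort.patients]
    if label_override is not None:
        labels = list(label_override)
    split_spec = split_spec or SplitSpec(seed=train_cfg.seed)
    tr, va, te = stratified_split(labels, split_spec)

    if images is None:
        images = cohort_parametric_images(cohort, grid=grid, qus_config=qus_config)

    norm = compute_norm_params(
        [img for i in tr for img in images[i]], mode=mode, source="train"
    )

    def _inputs(idx):
        out = []
        for i in idx:
            pid = cohort.patients[i].patient_id
            planes = [
                preprocess_for_network(img, mode, norm, out_size=input_size,
                                       patient_id=pid)
                for img in images[i]
            ]
            out.append((planes, labels[i]))
        return out

    train_planes = [(p, lab) for planes, lab in _inputs(tr) for p in planes]
    val_planes = [(p, lab) for planes, lab in _inputs(va) for p in planes]
    net, f_hist = train_feature_net(train_planes, val_planes, backbone, train_cfg)

    def _patient_features(idx):
        feats = []
        for i in idx:
            pid = cohort.patients[i].patient_id
            vecs = [
                extract_features(net, preprocess_for_network(
                    img, mode, norm, out_size=input_size, patient_id=pid))
                for img in images[i]
            ]
            feats.append((average_features(vecs), labels[i]))
        return feats

    pred_cfg = PredictorConfig(train=train_cfg)
    predictor, p_hist = train_predictor(
        _patient_features(tr), _patient_features(va), pred_cfg
    )

    test_feats = _patient_features(te)
    predictions = [predict_patient(predictor, f) for f, _ in test_feats]
    test_labels = [lab for _, lab in test_feats]
    metrics = compute_metrics(predictions, test_labels)
    return ExperimentResult(
        metrics=metrics,
        predictions=predictions,
        test_labels=test_labels,
        feature_net=net,
        predictor=predictor,
        norm_params=norm,
        split=(tr, va, te),
        feature_history=f_hist,
        predictor_history=p_hist,
    )


def synthetic_study(
    base_seed: int = 0,
    n_patients: int = 60,
    n_seeds: int = 5,
    include_permuted: bool = False,
) -> dict:
    """Desk-scale synthetic response-prediction study.

    One cohort with strong class separation (the generator defaults) is
    simulated and its parametric maps computed once; the two-stage model is
    then trained and evaluated for ``n_seeds`` different split/training
    seeds.  With ``include_permuted=True`` the same maps additionally feed
    a negative control in which the patient labels are randomly permuted
    per seed before splitting and training — its AUC should sit near
    chance.

    Desk-scale problem sizes (documented in the methods note): 2 mm
    analysis windows at 80 % overlap, 4-7 mm tumor core radii, 64 x 64
    network inputs, small-depth backbone, 20 training epochs.

    Returns a dict with per-seed AUCs and accuracies (and, if requested,
    ``permuted_aucs``).
    """
    from .synthetic_rf import simulate_cohort

    cohort = simulate_cohort(
        n_patients,
        seed=int(base_seed) % 2**31,
        n_lines=256,
        n_samples=1536,
        core_radius_range_mm=(4.0, 7.0),
    )
    grid = SlidingGrid(overlap_fraction=0.8)
    images = cohort_parametric_images(cohort, grid=grid)
    # RF frames are no longer needed once the maps exist; free the memory
    for p in cohort.patients:
        for pl in p.planes:
            pl.frame = None
    cohort.reference_frame = None
    labels = [p.label for p in cohort.patients]

    def _run(seed: int, override):
        return run_experiment(
            cohort,
            mode="core+margin",
            backbone=BackboneConfig(architecture="ran", depth_preset="small"),
            train_cfg=TrainConfig(seed=seed, max_epochs=20,
                                  early_stopping_patience=5),
            split_spec=SplitSpec(seed=seed),
            images=images,
            input_size=64,
            label_override=override,
        )

    out = {"aucs": [], "accuracies": [], "n_patients": n_patients}
    for s in range(n_seeds):
        seed = (int(base_seed) + 1000 * (s + 1)) % 2**31
        res = _run(seed, None)
        out["aucs"].append(res.metrics.auc)
        out["accuracies"].append(res.metrics.accuracy)
    if include_permuted:
        out["permuted_aucs"] = []
        for s in range(n_seeds):
            seed = (int(base_seed) + 1000 * (s + 1)) % 2**31
            perm = np.random.default_rng(seed).permutation(len(labels))
            res = _run(seed, [labels[i] for i in perm])
            out["permuted_aucs"].append(res.metrics.auc)
    return out
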