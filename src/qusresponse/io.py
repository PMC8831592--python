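"""HDF5 cohort container and small text exports.

Layout: ``/patient_i/plane_j/rf`` holds the 2-D RF array with geometry,
pulse and ground-truth attributes; ``/patient_i/plane_j/contour`` the
closed core polygon in mm; patient-level attributes carry the response
label and survival record.  The reference frame lives under
``/reference/rf``.
"""

from __future__ import annotations

import csv

import h5py
import numpy as np

from .parametric_mapping import ParametricImage, RoiContour
from .synthetic_rf import (
    AcousticPulse,
    FrameGeometry,
    PatientPlane,
    PatientRecord,
    RFFrame,
    ScatteringSpec,
    SurvivalParams,
    SyntheticCohort,
)

__all__ = ["save_cohort", "load_cohort", "save_parametric_image",
           "load_parametric_image", "save_png_preview",
           "write_predictions_csv", "write_contour_csv", "read_contour_csv",
           "save_checkpoint", "load_checkpoint", "write_history_csv",
           "write_km_csv", "save_pda_npz"]


def _write_frame(grp: h5py.Group, frame: RFFrame) -> None:
    d = grp.create_dataset("rf", data=frame.samples)
    g, p = frame.geometry, frame.pulse
    d.attrs.update({
        "n_lines": g.n_lines, "n_samples": g.n_samples,
        "lateral_pitch_mm": g.lateral_pitch_mm,
        "axial_pitch_mm": g.axial_pitch_mm,
        "depth_offset_mm": g.depth_offset_mm,
        "center_frequency": p.center_frequency,
        "band_low": p.band_low, "band_high": p.band_high,
        "sampling_frequency": p.sampling_frequency,
    })
    t = frame.truth
    if isinstance(t, ScatteringSpec):
        d.attrs.update({
            "esd_true": t.esd_true, "eac_true_db": t.eac_true_db,
            "attenuation": t.attenuation, "sound_speed": t.sound_speed,
        })


def _read_frame(grp: h5py.Group) -> RFFrame:
    d = grp["rf"]
    a = d.attrs
    geometry = FrameGeometry(
        n_lines=int(a["n_lines"]), n_samples=int(a["n_samples"]),
        lateral_pitch_mm=float(a["lateral_pitch_mm"]),
        axial_pitch_mm=float(a["axial_pitch_mm"]),
        depth_offset_mm=float(a["depth_offset_mm"]),
    )
    pulse = AcousticPulse(
        center_frequency=float(a["center_frequency"]),
        band_low=float(a["band_low"]), band_high=float(a["band_high"]),
        sampling_frequency=float(a["sampling_frequency"]),
    )
    truth = None
    if "esd_true" in a:
        truth = ScatteringSpec(
            esd_true=float(a["esd_true"]), eac_true_db=float(a["eac_true_db"]),
            attenuation=float(a["attenuation"]), sound_speed=float(a["sound_speed"]),
        )
    return RFFrame(samples=d[()], geometry=geometry, pulse=pulse, truth=truth)


def save_cohort(path, cohort: SyntheticCohort) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = cohort.seed
        ref = f.create_group("reference")
        _write_frame(ref, cohort.reference_frame)
        for pat in cohort.patients:
            g = f.create_group(pat.patient_id)
            g.attrs.update({
                "label": pat.label,
                "survival_months": pat.survival_months,
                "event": pat.event,
            })
            for j, plane in enumerate(pat.planes):
                pg = g.create_group(f"plane_{j}")
                _write_frame(pg, plane.frame)
                pg.create_dataset("contour", data=plane.contour.core_polygon)


def load_cohort(path) -> SyntheticCohort:
    with h5py.File(path, "r") as f:
        ref_frame = _read_frame(f["reference"])
        patients = []
        for pid in sorted(k for k in f.keys() if k != "reference"):
            g = f[pid]
            planes = []
            for j in range(len([k for k in g.keys() if k.startswith("plane_")])):
                pg = g[f"plane_{j}"]
                planes.append(PatientPlane(
                    frame=_read_frame(pg),
                    contour=RoiContour(plane_id=f"{pid}_pl{j}",
                                       core_polygon=pg["contour"][()]),
                ))
            patients.append(PatientRecord(
                patient_id=pid, planes=planes,
                label=str(g.attrs["label"]),
                survival_months=float(g.attrs["survival_months"]),
                event=bool(g.attrs["event"]),
            ))
    return SyntheticCohort(
        patients=patients, reference_frame=ref_frame,
        class_params={}, survival_params=SurvivalParams(),
        seed=-1,
    )


def save_parametric_image(path, img: ParametricImage) -> None:
    np.savez(
        path, channels=img.channels, core_mask=img.core_mask,
        margin_mask=img.margin_mask, pixel_pitch_mm=img.pixel_pitch_mm,
        plane_id=np.bytes_(img.plane_id.encode()),
    )


def load_parametric_image(path) -> ParametricImage:
    z = np.load(path)
    return ParametricImage(
        channels=z["channels"], core_mask=z["core_mask"].astype(bool),
        margin_mask=z["margin_mask"].astype(bool),
        pixel_pitch_mm=float(z["pixel_pitch_mm"]),
        plane_id=bytes(z["plane_id"]).decode(),
    )


def write_contour_csv(path, contour: RoiContour) -> None:
    """Closed core polygon as CSV vertex list in mm (lateral, axial)."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["lateral_mm", "axial_mm"])
        for lat, ax in contour.core_polygon:
            wr.writerow([f"{lat:.6f}", f"{ax:.6f}"])


def read_contour_csv(path, plane_id: str = "") -> RoiContour:
    with open(path) as fh:
        rows = list(csv.reader(fh))[1:]
    return RoiContour(
        plane_id=plane_id,
        core_polygon=np.array([[float(a), float(b)] for a, b in rows]),
    )


def save_checkpoint(path, net) -> None:
    """Model parameters plus embedded config, as NPZ.

    Works for :class:`~qusresponse.feature_net.FeatureNet` and
    :class:`~qusresponse.patient_predictor.PredictorNet`.
    """
    import json

    from .feature_net import FeatureNet

    if isinstance(net, FeatureNet):
        cfg = {
            "kind": "feature_net",
            "architecture": net.config.architecture,
            "depth_preset": net.config.depth_preset,
        }
    else:
        c = net.config
        cfg = {
            "kind": "predictor",
            "input_dim": c.input_dim,
            "hidden_width": c.hidden_width,
            "n_classes": c.n_classes,
            "dropout": c.dropout,
        }
    arrays = {f"param_{i}": p.value for i, p in enumerate(net.params())}
    np.savez(path, config=np.bytes_(json.dumps(cfg).encode()), **arrays)


def load_checkpoint(path):
    """Reconstruct a network from :func:`save_checkpoint` output."""
    import json

    from .feature_net import BackboneConfig, FeatureNet
    from .patient_predictor import PredictorConfig, PredictorNet

    z = np.load(path)
    cfg = json.loads(bytes(z["config"]).decode())
    if cfg["kind"] == "feature_net":
        net = FeatureNet(
            BackboneConfig(cfg["architecture"], cfg["depth_preset"]),
            rng=np.random.default_rng(0),
        )
    else:
        net = PredictorNet(
            PredictorConfig(cfg["input_dim"], cfg["hidden_width"],
                            cfg["n_classes"], cfg["dropout"]),
            rng=np.random.default_rng(0),
        )
    net.set_state([z[f"param_{i}"] for i in range(len(net.params()))])
    return net


def write_history_csv(path, history: list[dict]) -> None:
    """Training history (epoch, train loss, val loss, val accuracy)."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["epoch", "train_loss", "val_loss", "val_accuracy"])
        for h in history:
            wr.writerow([h["epoch"], f"{h['train_loss']:.6f}",
                         f"{h['val_loss']:.6f}", f"{h['val_accuracy']:.4f}"])


def write_km_csv(path, times: np.ndarray, survival: np.ndarray) -> None:
    """Kaplan-Meier step function as two-column CSV."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["time_months", "survival_probability"])
        for t, s in zip(times, survival):
            wr.writerow([f"{t:.4f}", f"{s:.6f}"])


def save_pda_npz(path, pda) -> None:
    """Occlusion-impact maps with their occlusion geometry."""
    np.savez(
        path, channel_maps=pda.channel_maps, patch_size=pda.patch_size,
        overlap=pda.overlap, predicted_class=pda.predicted_class,
        baseline_probability=pda.baseline_probability,
    )


def save_png_preview(path, img: ParametricImage) -> None:
    """2 x 2 panel of the parametric channels with the core contour overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = ("MBF (dB)", "SI (dB)", "ESD (um)", "EAC (dB)")
    fig, axes = plt.subplots(2, 2, figsize=(8, 8))
    roi = img.core_mask | img.margin_mask
    for ax, chan, name in zip(axes.ravel(), img.channels, names):
        shown = np.where(roi, chan, np.nan)
        im = ax.imshow(shown, origin="upper", cmap="viridis")
        ax.contour(img.core_mask, levels=[0.5], colors="w", linewidths=0.8)
        ax.set_title(name)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def write_predictions_csv(path, predictions) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["patient_id", "p_nonresponder", "p_responder", "predicted_label"])
        for p in predictions:
            wr.writerow([p.patient_id, f"{p.p_nonresponder:.6f}",
                         f"{p.p_responder:.6f}", p.predicted_label])
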