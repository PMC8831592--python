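# qusresponse

Quantitative-ultrasound (QUS) parametric imaging and deep-learning
prediction of breast cancer response to neoadjuvant chemotherapy (NAC).

## The problem

About a quarter of locally advanced breast cancer patients do not respond
to NAC, but the standard response assessment (post-surgical histopathology)
arrives months too late to adjust treatment. QUS spectral analysis reads
tissue microstructure from the frequency content of raw ultrasound
radiofrequency (RF) echoes, independent of instrument settings — a
candidate pre-treatment biomarker. This package implements the full
pipeline from RF data to a patient-level response prediction:

1. **Spectral estimation** — per 2 mm analysis window, the mean power
   spectrum of Hanning-gated RF lines is normalized by a reference phantom
   (α = 0.576 dB/MHz·cm, c = 1488 m/s) with point attenuation
   compensation `+4·Δα·f·d`; linear regression over the 3–8 MHz band gives
   the mid-band fit (MBF), spectral slope (SS) and 0-MHz intercept (SI),
   and inversion of the spherical Gaussian form factor
   `BSC(f) = C₀·EAC·a⁶·k⁴·exp(−0.827·k²a²)` gives the effective scatterer
   diameter (ESD = 2a) and effective acoustic concentration (EAC, dB).
2. **Parametric mapping** — a sliding-window analysis (95 % overlap in the
   clinical protocol) paints 4-channel images (MBF, SI, ESD, EAC) over the
   manually contoured tumor core and an automatic 5 mm margin shell, then
   produces fixed-size min–max-normalized tensors (core or core+margin
   mode) for the network.
3. **Two-stage model** — a residual or residual-attention convolutional
   backbone (`y = (1+M)⊙T` attention modules) extracts a 256-d feature per
   scan plane; features are averaged over the 4–7 planes of each tumor and
   a 256→100→2 fully connected softmax network predicts
   responder vs non-responder, trained with class-weighted cross-entropy
   (cost 5 on the minority non-responders), Adam, augmentation, and early
   stopping.
4. **Evaluation and explanation** — MR-grade ground-truth labeling,
   stratified splits, accuracy/sensitivity/specificity/AUC in the
   non-responder-positive convention, Kaplan–Meier + log-rank survival
   comparison, and occlusion-based prediction difference analysis (PDA)
   maps showing which image regions drive each prediction.

Clinical RF data of this kind is private, so the package includes a
physics-based synthetic RF simulator (`synthetic_rf`) whose gated segments
have an exactly known expected power spectrum — every stage is testable
against ground truth, end to end.

## Worked example

```python
import numpy as np
from qusresponse import (
    AcousticPulse, FrameGeometry, ScatteringSpec, QusConfig, GatedWindow,
    simulate_rf_frame, simulate_reference_frame,
    mean_power_spectrum, normalize_spectrum, estimate_bsc,
    fit_gaussian_form_factor, gaussian_form_factor_bsc, BscEstimate,
)

pulse = AcousticPulse()                      # 6 MHz, 3-8 MHz band, 40 MHz fs
truth = ScatteringSpec(esd_true=80.0, eac_true_db=30.0,
                       attenuation=1.0, sound_speed=1540.0)
geom  = FrameGeometry.from_acquisition(2000, 512, 60.0, 1540.0, 40.0)
frame = simulate_rf_frame(truth, geom, pulse, seed=101)
ref   = simulate_reference_frame(
    FrameGeometry.from_acquisition(2000, 512, 60.0, 1488.0, 40.0),
    pulse, seed=202)

cfg  = QusConfig()
gate = int(round(2.0 / geom.axial_pitch_mm))           # 2 mm gate
depth = (200 + gate / 2) * geom.axial_pitch_mm / 10    # cm
w  = GatedWindow(frame.samples[:, 200:200 + gate], depth, 40.0)
wr = GatedWindow(ref.samples[:, 207:207 + int(round(2.0 / ref.geometry.axial_pitch_mm))],
                 depth, 40.0)
nfft = cfg.nfft(gate)
norm = normalize_spectrum(mean_power_spectrum(w, nfft),
                          mean_power_spectrum(wr, nfft),
                          cfg.sample_attenuation, cfg.ref_attenuation,
                          depth, cfg.band)
bsc_ref = BscEstimate(norm.freqs,
                      gaussian_form_factor_bsc(norm.freqs, 20.0, 20.0, 1488.0))
esd, eac = fit_gaussian_form_factor(estimate_bsc(norm, bsc_ref),
                                    cfg.sample_sound_speed)
print(f"ESD = {esd:.0f} um (truth 80), EAC = {eac:.2f} dB (truth 30)")
```

This prints (seed-exact):

```
ESD = 77 um (truth 80), EAC = 30.67 dB (truth 30)
```

i.e. a single 2 mm window averaged over 2000 scan lines recovers the
simulated scatterer diameter within a few µm and the acoustic
concentration within ~0.7 dB.

A full synthetic study — simulate a 60-patient cohort, generate parametric
maps, train the residual-attention model two-stage, and evaluate on a
held-out stratified test set — is one call:

```python
from qusresponse.pipeline import synthetic_study
print(synthetic_study(base_seed=1, n_patients=60, n_seeds=5))
# {'aucs': [1.0, 1.0, 1.0, 1.0, 1.0], 'accuracies': [1.0, ...], ...}
```

With the default strong class separation in tissue microstructure the
held-out patient-level AUC is 1.0 for every seed (median ≥ 0.9 is the
regression bound the test suite enforces).

There is also a small CLI:

```bash
qusresponse simulate --n-patients 20 --seed 1 --out cohort.h5
qusresponse run-experiment --cohort cohort.h5 --arch ran --mode core+margin
```

## Layout

```
src/qusresponse/
  synthetic_rf.py        RF/cohort simulator with known ground truth
  qus_spectra.py         spectral parameters (MBF, SS, SI, ESD, EAC)
  parametric_mapping.py  sliding-window maps, margins, network inputs
  nnet.py                minimal NumPy NN core (conv, dense, Adam, ...)
  feature_net.py         residual / residual-attention feature network
  patient_predictor.py   plane-feature averaging + FC response predictor
  evaluation.py          MR grading, splits, metrics, KM/log-rank, PDA
  pipeline.py            end-to-end experiment driver
  io.py, cli.py          HDF5/CSV containers and the command line
```
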