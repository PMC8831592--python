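# Methods

This note documents the models, estimators and design choices in
`qusresponse`: a pipeline that turns raw radiofrequency (RF) breast
ultrasound into quantitative-ultrasound (QUS) parametric images and
predicts, per patient, the response of a locally advanced breast tumor to
neoadjuvant chemotherapy (NAC) with a two-stage convolutional /
fully connected model. Because clinical RF data of this kind is private,
the package ships a physics-based synthetic RF generator with known ground
truth; every stage is validated against it.

## QUS spectral model

For one analysis window the mean power spectrum is the across-line average
of Hanning-gated periodograms, normalized by the gate window energy so
gates of different sample lengths are comparable. The reference-phantom
method divides the sample spectrum by that of a phantom with known
acoustics, cancelling the system transfer function and beam effects:

    N(f) = 10·log10( S_sample(f) / S_ref(f) ) + 4·(α_s − α_r)·f·d   [dB]

with attenuations α in dB/MHz/cm, f in MHz and d the window-center depth
in cm (point compensation; the round-trip attenuation difference at one
depth). The phantom constants are α_r = 0.576 dB/MHz/cm and
c_r = 1488 m/s; the assumed tissue attenuation defaults to
α_s = 1.0 dB/MHz/cm (typical breast-tissue value) and the tissue sound
speed to 1540 m/s. Both are exposed in `QusConfig` because neither is
measurable from a single window.

Linear (Lizzi–Feleppa) regression of N(f) over the −6 dB transducer band
(3–8 MHz) yields the spectral slope SS (dB/MHz), the 0-MHz intercept SI
(dB), and the mid-band fit MBF, evaluated at the band midpoint 5.5 MHz.

The backscatter coefficient is transferred through the known phantom BSC,
BSC(f) = BSC_ref(f)·10^(N(f)/10), and inverted under the spherical
Gaussian form-factor model

    BSC(f) = C₀ · EAC · a⁶ · k⁴ · exp(−0.827 k² a²),  k = 2πf/c,  a = ESD/2.

ESD is found by grid search over 1–300 µm in 1 µm steps; for each
candidate the dB-domain intercept has a closed-form least-squares solution
that directly estimates EAC in dB. C₀ = 1 in internal units, so EAC values
are relative — consistent throughout the package and sufficient for
mapping, classification, and self-consistent recovery tests. On noiseless
model-generated curves the inversion is exact up to the grid step.

FFT length is the next power of two at least 4× the gate length (grid
smoothness without distorting the periodogram expectation).

## Synthetic RF generator

Each scan line is a superposition of sinusoids on a frequency grid of
f_s/1024 ≈ 0.04 MHz (an order of magnitude finer than a 2 mm gate can
resolve), with independent Gaussian quadrature amplitudes per line and a
deterministic envelope per component,

    A_k(t)² = (2·df/f_s)·|P(f_k)|²·BSC(f_k)·10^(−4·α·f_k·d(t)/10),

so the expected periodogram of any gated segment equals the closed-form
product of pulse spectrum, backscatter model and round-trip attenuation at
the gate-center depth, with *continuous* depth dependence. The pulse
amplitude |P| is a Gaussian in log-frequency with separate widths per
side, placing the −6 dB points exactly at 3 and 8 MHz around the 6 MHz
center and giving zero DC response. Earlier block-based synthesis variants
were rejected because block joins (spectral leakage) or coarse piecewise
attenuation produced window-position-dependent artifacts in the estimates.

Spatial ground truth is piecewise-constant: an elliptical tumor core, a
5 mm margin shell, and homogeneous background, each with its own
(ESD, EAC) but a common attenuation so the point-compensation assumption
of the estimator holds exactly.

Cohorts follow the clinical acquisition structure: 40 MHz sampling, 6 cm
lateral field of view, four to seven scan planes per patient, responder
prevalence 0.762 (the 138/181 clinical ratio). Class microstructure is a
free choice (no clinical microstructure statistics exist): responder cores
draw ESD ~ N(60, 8²) µm and EAC ~ N(25, 1.5²) dB, non-responder cores
N(110, 8²) µm and N(31, 1.5²) dB, with smaller margin contrasts — a
strong, cleanly detectable separation. Recurrence-free survival is
exponential per class (responders 0.004/month, non-responders 0.02/month)
with uniform censoring on [0, 120] months, mirroring a 10-year follow-up
with clearly separated survival curves.

What the generator does *not* emulate: speckle from discrete scatterers,
beam diffraction and focusing, nonlinear propagation, heterogeneous
attenuation paths, intra-tumor texture. Passing tests therefore
demonstrate the correctness of the estimators and the learning machinery
under the stated spectral model, not clinical performance.

## Parametric mapping

Analysis windows are 2 mm × 2 mm; the clinical protocol uses 95 % overlap
(0.1 mm isotropic map pixels). A window contributes if its *center* lies
in the core or margin; the parameter vector (MBF, SI, ESD, EAC) is written
to the center pixel; pixels without a window stay 0. The margin is the set
of pixels outside the core within 5 mm of it (Euclidean distance
transform). The reference frame is gated at the same physical depth using
its own axial pitch (1488 m/s vs 1540 m/s).

Network inputs are built by zeroing pixels outside the selected mask (core
or core∪margin), cropping to the mask bounding box — so tumors of any
size fill the canvas — bilinear resampling to a square (512×512 in the
clinical protocol; configurable), then per-channel min–max normalization
with bounds computed on the *training set only* and clipping to [0, 1].
The bounds carry a provenance tag and bounds not tagged "train" are
refused, enforcing the protocol mechanically. Normalization is per channel
and global across the training set, so absolute parameter levels stay
informative.

## Networks and training

The feature network is a convolutional backbone over the 4-channel image:
residual blocks y = F(x) + shortcut(x) (identity shortcut when shape is
preserved; the block is exactly the identity at zero weights), and — in
the residual-attention variant — attention modules
y = (1 + M(x)) ⊙ T(x) with a residual-block trunk T and a sigmoid-ended
bottom-up/top-down mask branch M ∈ (0,1). Global average pooling and a
linear projection give the 256-d plane feature; a 256→100→2 head with
dropout 0.5 after the first and second layers is appended for plane-level
training. Two presets exist: `small` (one block per resolution, the
desk-scale configuration every test uses) and `full` (3-4-6-3 blocks,
provided for completeness). All layers are NumPy with explicit backprop;
training uses Adam (learning rate 1e-4), batch size 8, class-weighted
cross-entropy with cost ratio C = 5 on the non-responder (minority) class,
stochastic horizontal flips and shifts up to 30 % of the image with zero
fill, and early stopping on validation loss (patience 10 by default).

The patient predictor averages the plane features over the tumor volume
(order-invariant by construction) and maps the 256-d mean through the same
100-unit fully connected architecture, trained with the feature network
frozen (two-stage, no joint fine-tuning). The decision rule is argmax
(0.5 threshold); no threshold tuning.

Seeds govern weight initialization, batch order, augmentation and dropout
draws; single-platform reruns are bit-reproducible.

## Evaluation

Ground truth follows the modified-response (MR) grade: MR1 no reduction,
MR2 < 30 %, MR3 30–90 % or very low residual cellularity, MR4 > 90 % with
residual malignant cells, MR5 no malignant cells; responders are MR ≥ 3.
Splitting is stratified with largest-remainder allocation per class
(test ≈ 30 %, validation ≈ 25 % of the remainder). Metrics use the
convention that the positive class is the *non-responder*: sensitivity is
the correctly identified non-responder fraction, specificity the
correctly identified responder fraction; AUC ranks the non-responder
probability (midrank ties). Kaplan–Meier curves and the one-degree
log-rank test come from lifelines; test oracles recompute both by the
brute-force product-limit and calibration simulations rather than by the
same library call.

Prediction difference analysis (PDA) occludes 8×8 patches at 50 % overlap
(stride 4) in one channel of one plane at a time, recomputes that plane's
feature with all other planes' features fixed, and records the absolute
change of the originally predicted class probability at the patch center.
Occluding an already-zero patch is skipped (impact 0 by construction), so
the background convention of the maps and the occlusion semantics agree.

## Desk-scale problem sizes

The synthetic end-to-end study trains the small residual-attention
backbone on a 60-patient cohort (46 responders / 14 non-responders,
4–7 planes each), core semi-axes 4–7 mm at 1.2–2.2 cm depth, maps at 80 %
window overlap (0.4 mm pixels), 64×64 network inputs, 20 training epochs
with early-stopping patience 5, five split/training seeds, plus a
label-permutation control on the same maps. These sizes are the package's
chosen test-bed conditions; the clinical protocol values (95 % overlap,
512×512 inputs, deeper backbones) remain the defaults of the respective
components.

## Numerical notes and limitations

- Gate-smoothing bias: a 2 mm Hanning gate smooths the spectrum with a
  ~0.4 MHz kernel. For strongly tilted spectra (high attenuation × depth)
  this biases ESD down and EAC up; the effect grows with depth and is one
  reason the synthetic tumors sit at clinically typical shallow depths.
  It is inherent to short-gate spectral QUS, not a code artifact.
- Few-line windows (~10 scan lines at 2 mm) give noisy per-window
  estimates; maps are intended to be read through medians/textures, and
  the classifier consumes them whole.
- The ESD grid search is exact on the grid; off-grid truths incur at most
  half a grid step (0.5 µm).
- Window-position counting uses a 1e-9 slack so extents that are exact
  multiples of the step are not lost to floating-point rounding.
- Degenerate inputs raise: empty gates, non-positive reference spectra,
  single-class training sets, contours outside the frame, normalization
  bounds with max ≤ min, occlusion patches larger than the image.
- The label-permutation control's *accuracy* sits systematically below the
  majority-class rate (a noise-overfit network generalizes worse than
  majority voting); chance level is therefore asserted on AUC.
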