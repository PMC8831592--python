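"""Spectral parameter estimation for quantitative ultrasound (QUS).

Implements the classical Lizzi–Feleppa spectral chain for one analysis
window: mean power spectrum of Hanning-gated RF lines, reference-phantom
normalization with point attenuation compensation, linear regression over
the analysis band (spectral slope SS, 0-MHz intercept SI, mid-band fit MBF),
and inversion of a spherical Gaussian form-factor model of the backscatter
coefficient (BSC) for the effective scatterer diameter (ESD) and effective
acoustic concentration (EAC).

Conventions
-----------
* Frequencies are in MHz everywhere in the public API.
* Powers are linear; normalized spectra are in dB.
* The acoustic wavenumber is k = 2*pi*f/c with f in Hz and c in m/s; the
  scatterer radius a = ESD/2 is in metres inside the BSC model.
* EAC is reported as 10*log10 of the linear acoustic concentration in
  internal units (the model amplitude constant C0 is 1), so EAC values are
  relative, which is sufficient for consistent mapping and recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QusConfig",
    "GatedWindow",
    "MeanPowerSpectrum",
    "NormalizedSpectrumDB",
    "BscEstimate",
    "QusEstimate",
    "gaussian_form_factor_bsc",
    "mean_power_spectrum",
    "normalize_spectrum",
    "fit_linear_band",
    "estimate_bsc",
    "fit_gaussian_form_factor",
    "estimate_window",
]

#: Gaussian form-factor exponent constant for a spherical scatterer,
#: F(k) = exp(-0.827 k^2 a^2)  (Insana/Hall spherical Gaussian model).
GAUSSIAN_FF_COEFF = 0.827


@dataclass(frozen=True)
class QusConfig:
    """Tunable analysis parameters with breast-imaging defaults.

    Attributes
    ----------
    band : (low, high) analysis band in MHz (the transducer's -6 dB band).
    sample_attenuation : assumed tissue attenuation, dB/MHz/cm.
    ref_attenuation : reference-phantom attenuation, dB/MHz/cm.
    sample_sound_speed : assumed tissue sound speed, m/s (used for k).
    ref_sound_speed : reference-phantom sound speed, m/s.
    esd_grid_um : search grid of candidate effective scatterer diameters.
    nfft_factor : zero-padding factor; nfft = next pow2 >= factor * gate len.
    """

    band: tuple[float, float] = (3.0, 8.0)
    sample_attenuation: float = 1.0
    ref_attenuation: float = 0.576
    sample_sound_speed: float = 1540.0
    ref_sound_speed: float = 1488.0
    esd_grid_um: np.ndarray = field(
        default_factory=lambda: np.arange(1.0, 301.0, 1.0)
    )
    nfft_factor: int = 4

    def nfft(self, gate_len: int) -> int:
        return int(2 ** np.ceil(np.log2(self.nfft_factor * gate_len)))


@dataclass
class GatedWindow:
    """RF segment of one analysis window: lines x gated samples."""

    segment: np.ndarray
    center_depth_cm: float
    sampling_frequency_mhz: float
    lateral_extent_mm: float = 2.0
    axial_extent_mm: float = 2.0

    def __post_init__(self) -> None:
        self.segment = np.asarray(self.segment, dtype=float)
        if self.segment.ndim != 2 or self.segment.size == 0:
            raise ValueError("gated segment must be a non-empty 2-D array")


@dataclass
class MeanPowerSpectrum:
    freqs: np.ndarray  # MHz
    power: np.ndarray  # linear, window-energy normalized
    n_lines_averaged: int


@dataclass
class NormalizedSpectrumDB:
    freqs: np.ndarray  # MHz, restricted to the analysis band
    values: np.ndarray  # dB
    sample_attenuation: float
    ref_attenuation: float
    depth_cm: float


@dataclass
class BscEstimate:
    freqs: np.ndarray  # MHz
    bsc: np.ndarray  # linear, internal units


@dataclass
class QusEstimate:
    """Spectral parameters of one window."""

    mbf: float  # dB
    ss: float  # dB/MHz
    si: float  # dB
    esd: float  # um
    eac: float  # dB


# ---------------------------------------------------------------------------
# Backscatter-coefficient model
# ---------------------------------------------------------------------------

def gaussian_form_factor_bsc(
    freqs_mhz: np.ndarray,
    esd_um: float,
    eac_db: float,
    sound_speed: float,
) -> np.ndarray:
    """Spherical-Gaussian-form-factor BSC, linear internal units.

    BSC(f) = EAC_lin * a^6 * k^4 * exp(-0.827 * k^2 * a^2)

    with k = 2*pi*f/c and a = ESD/2.  At f = 0 the form factor is 1 and the
    model reduces to the Rayleigh k^4 law.
    """
    f_hz = np.asarray(freqs_mhz, dtype=float) * 1e6
    a_m = 0.5 * esd_um * 1e-6
    k = 2.0 * np.pi * f_hz / sound_speed
    eac_lin = 10.0 ** (eac_db / 10.0)
    return eac_lin * a_m**6 * k**4 * np.exp(-GAUSSIAN_FF_COEFF * k**2 * a_m**2)


def _gaussian_ff_shape_db(
    freqs_mhz: np.ndarray, esd_um: np.ndarray, sound_speed: float
) -> np.ndarray:
    """dB shape term of the model (everything except the EAC intercept).

    Returns an array of shape (len(esd_um), len(freqs_mhz)).
    """
    f_hz = np.asarray(freqs_mhz, dtype=float)[None, :] * 1e6
    a_m = 0.5 * np.asarray(esd_um, dtype=float)[:, None] * 1e-6
    k = 2.0 * np.pi * f_hz / sound_speed
    with np.errstate(divide="ignore"):
        shape_db = (
            60.0 * np.log10(a_m)
            + 40.0 * np.log10(k)
            - 10.0 * GAUSSIAN_FF_COEFF * k**2 * a_m**2 / np.log(10.0)
        )
    return shape_db


# ---------------------------------------------------------------------------
# Spectral estimation chain
# ---------------------------------------------------------------------------

def mean_power_spectrum(window: GatedWindow, nfft: int | None = None) -> MeanPowerSpectrum:
    """Average Hanning-gated periodogram across the scan lines of a window.

    The per-line periodogram is |DFT(hanning * line)|^2 / sum(hanning^2),
    zero-padded to ``nfft`` for a fixed frequency grid.  Normalizing by the
    window energy makes spectra from gates of different sample lengths
    directly comparable (the flat-spectrum level equals the process power
    spectral density up to a fixed constant).
    """
    seg = window.segment
    n_lines, n_samp = seg.shape
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(4 * n_samp)))
    taper = np.hanning(n_samp)
    spec = np.fft.rfft(seg * taper[None, :], n=nfft, axis=1)
    power = np.mean(np.abs(spec) ** 2, axis=0) / np.sum(taper**2)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / window.sampling_frequency_mhz)
    return MeanPowerSpectrum(freqs=freqs, power=power, n_lines_averaged=n_lines)


def normalize_spectrum(
    sample: MeanPowerSpectrum,
    reference: MeanPowerSpectrum,
    alpha_sample: float,
    alpha_ref: float,
    depth_cm: float,
    band: tuple[float, float] = (3.0, 8.0),
) -> NormalizedSpectrumDB:
    """Reference-phantom normalization with point attenuation compensation.

    values(f) = 10*log10(S_sample(f)/S_ref(f)) + 4*(alpha_s - alpha_r)*f*d

    restricted to the analysis band.  The compensation term undoes the
    round-trip attenuation difference between sample and reference at the
    window-center depth ``d`` (cm), with attenuations in dB/MHz/cm.
    """
    if sample.freqs.shape != reference.freqs.shape or not np.allclose(
        sample.freqs, reference.freqs
    ):
        raise ValueError("sample and reference spectra must share a frequency grid")
    mask = (sample.freqs >= band[0]) & (sample.freqs <= band[1])
    freqs = sample.freqs[mask]
    p_s = sample.power[mask]
    p_r = reference.power[mask]
    if np.any(p_r <= 0):
        raise ValueError("reference power must be positive on the analysis band")
    values = 10.0 * np.log10(p_s / p_r) + 4.0 * (alpha_sample - alpha_ref) * freqs * depth_cm
    return NormalizedSpectrumDB(
        freqs=freqs,
        values=values,
        sample_attenuation=alpha_sample,
        ref_attenuation=alpha_ref,
        depth_cm=depth_cm,
    )


def fit_linear_band(norm: NormalizedSpectrumDB) -> tuple[float, float, float]:
    """Ordinary least squares of the normalized spectrum over its band.

    Returns ``(ss, si, mbf)``: spectral slope (dB/MHz), spectral 0-MHz
    intercept (dB), and mid-band fit, the regression line evaluated at the
    band midpoint (5.5 MHz for the 3-8 MHz band).
    """
    f = np.asarray(norm.freqs, dtype=float)
    if f.size < 2 or np.unique(f).size < 2:
        raise ValueError("need at least two distinct frequencies for regression")
    ss, si = np.polyfit(f, norm.values, 1)
    f_mid = 0.5 * (f.min() + f.max())
    mbf = si + ss * f_mid
    return float(ss), float(si), float(mbf)


def estimate_bsc(norm: NormalizedSpectrumDB, bsc_ref: BscEstimate) -> BscEstimate:
    """Transfer the known reference BSC through the normalized ratio."""
    if norm.freqs.shape != bsc_ref.freqs.shape or not np.allclose(
        norm.freqs, bsc_ref.freqs
    ):
        raise ValueError("normalized spectrum and reference BSC grids differ")
    return BscEstimate(freqs=norm.freqs, bsc=bsc_ref.bsc * 10.0 ** (norm.values / 10.0))


def fit_gaussian_form_factor(
    bsc: BscEstimate,
    sound_speed: float,
    esd_grid_um: np.ndarray | None = None,
) -> tuple[float, float]:
    """Grid-search inversion of the spherical Gaussian form-factor model.

    For each candidate diameter the dB-domain intercept has a closed-form
    least-squares solution (the mean residual between measured BSC and the
    model shape), which directly estimates 10*log10(EAC).  The candidate
    minimizing the residual sum of squares wins.  Exact on noiseless
    model-generated curves for diameters on the grid.

    Returns ``(esd_um, eac_db)``.
    """
    if esd_grid_um is None:
        esd_grid_um = QusConfig().esd_grid_um
    esd_grid_um = np.asarray(esd_grid_um, dtype=float)
    if esd_grid_um.size == 0:
        raise ValueError("empty ESD search grid")
    if np.any(bsc.bsc <= 0):
        raise ValueError("BSC must be positive on the analysis band")
    data_db = 10.0 * np.log10(bsc.bsc)
    shape_db = _gaussian_ff_shape_db(bsc.freqs, esd_grid_um, sound_speed)
    resid = data_db[None, :] - shape_db
    intercepts = resid.mean(axis=1)
    rss = np.sum((resid - intercepts[:, None]) ** 2, axis=1)
    if not np.any(np.isfinite(rss)):
        raise ValueError("degenerate form-factor fit: no finite residuals")
    best = int(np.nanargmin(rss))
    return float(esd_grid_um[best]), float(intercepts[best])


def estimate_window(
    window: GatedWindow,
    reference: GatedWindow,
    bsc_ref: "BscEstimate | None" = None,
    config: QusConfig | None = None,
) -> QusEstimate:
    """Full spectral chain for one sample window and its same-depth reference.

    ``bsc_ref`` is the reference phantom's known BSC evaluated on the band
    grid; if omitted, a flat unit BSC is assumed (relative estimates only).
    """
    cfg = config or QusConfig()
    nfft = cfg.nfft(max(window.segment.shape[1], reference.segment.shape[1]))
    s = mean_power_spectrum(window, nfft=nfft)
    r = mean_power_spectrum(reference, nfft=nfft)
    norm = normalize_spectrum(
        s, r, cfg.sample_attenuation, cfg.ref_attenuation,
        window.center_depth_cm, band=cfg.band,
    )
    ss, si, mbf = fit_linear_band(norm)
    if bsc_ref is None:
        bsc_ref = BscEstimate(freqs=norm.freqs, bsc=np.ones_like(norm.freqs))
    bsc = estimate_bsc(norm, bsc_ref)
    esd, eac = fit_gaussian_form_factor(bsc, cfg.sample_sound_speed, cfg.esd_grid_um)
    return QusEstimate(mbf=mbf, ss=ss, si=si, esd=esd, eac=eac)


def export_spectrum_txt(path, freqs_mhz: np.ndarray, values: np.ndarray) -> None:
    """Write a spectrum as two-column text (MHz, value) for debugging."""
    np.savetxt(path, np.column_stack([freqs_mhz, values]), header="MHz value")
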