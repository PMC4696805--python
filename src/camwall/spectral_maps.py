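"""Per-pixel temporal FFT analysis of wall-motion videos.

Each pixel's brightness time series is linearly detrended and Fourier
transformed.  From the per-pixel spectra the module builds co-registered maps
of: RMS amplitude (a proxy for local motion strength), fundamental and
second-harmonic magnitude, their percentage ratio, and the phase angle of the
fundamental component — the quantity that separates translational wall motion
(opposite walls 180 degrees out of phase) from radial dilation (walls in
phase).  Maps are reported inside a mask of pixels whose RMS amplitude lies
within a configurable dB window of the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

from .video_io import PixelSeries, VideoStack

__all__ = [
    "Spectrum",
    "SpectralMapSet",
    "detrend",
    "rms_amplitude",
    "fft_spectrum",
    "find_fundamental",
    "phase_at",
    "compute_map_set",
    "phase_histogram",
]

#: embryonic heart rates fall in this band (the example recording beats at 3.2 Hz)
DEFAULT_BAND = (1.0, 8.0)


def _values(series) -> np.ndarray:
    if isinstance(series, PixelSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


@dataclass
class Spectrum:
    """One-sided FFT of a detrended pixel series.

    ``coefficients[k]`` is the complex rfft output divided by the *source*
    length T (not the padded length), so a unit-amplitude cosine exactly on a
    bin has |coefficient| = 0.5 (two-sided convention) and one-sided magnitude
    1.0.  Bin spacing is frame_rate_hz / padded length.
    """

    frequencies: np.ndarray
    coefficients: np.ndarray
    n_samples: int
    frame_rate_hz: float

    @property
    def bin_spacing_hz(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def magnitude(self, one_sided: bool = True) -> np.ndarray:
        mags = np.abs(self.coefficients)
        if not one_sided:
            return mags
        out = 2.0 * mags
        out[0] = mags[0]  # DC is not mirrored
        padded = round(self.frame_rate_hz / self.bin_spacing_hz)
        if padded % 2 == 0:
            out[-1] = mags[-1]  # neither is Nyquist for even lengths
        return out

    def nearest_bin(self, f_hz: float) -> int:
        return int(np.argmin(np.abs(self.frequencies - f_hz)))

    def total_power(self) -> float:
        """Mean-square power, summed one-sided (Parseval's identity)."""
        p = np.abs(self.coefficients) ** 2
        weights = np.full(p.shape, 2.0)
        weights[0] = 1.0
        padded = round(self.frame_rate_hz / self.bin_spacing_hz)
        if padded % 2 == 0:
            weights[-1] = 1.0
        # with zero padding the padded-grid power sum scales by padded length / T
        return float(np.sum(weights * p) * self.n_samples / padded)


def detrend(series):
    """Remove the least-squares straight line (zero mean, zero linear trend)."""
    x = _values(series)
    if x.size < 2:
        raise ValueError("need at least two samples to detrend")
    d = _linear_detrend(x)
    if isinstance(series, PixelSeries):
        return PixelSeries(d, series.frame_rate_hz, series.location)
    return d


def rms_amplitude(series) -> float:
    """Root-mean-square amplitude of the detrended series, in gray levels."""
    d = _values(detrend(series))
    return float(np.sqrt(np.mean(d**2)))


def fft_spectrum(series: PixelSeries, pad_factor: int = 1) -> Spectrum:
    """FFT of the detrended series, zero-padded to ``pad_factor`` x T samples.

    Padding refines the frequency grid (bin spacing fs / (pad_factor T)) for
    sub-bin peak reporting without changing the underlying resolution.
    """
    if not isinstance(pad_factor, (int, np.integer)) or pad_factor < 1:
        raise ValueError("pad_factor must be an integer >= 1")
    x = _values(detrend(series))
    if x.size < 4:
        raise ValueError("need at least four samples for a spectrum")
    t = x.size
    n = pad_factor * t
    coeffs = np.fft.rfft(x, n=n) / t
    freqs = np.fft.rfftfreq(n, 1.0 / series.frame_rate_hz)
    return Spectrum(freqs, coeffs, t, series.frame_rate_hz)


def find_fundamental(spectrum: Spectrum, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Frequency of the maximum-magnitude bin within a physiological band."""
    f_lo, f_hi = band
    nyquist = spectrum.frame_rate_hz / 2
    if not 0 < f_lo < f_hi <= nyquist:
        raise ValueError(f"band {band} must lie within (0, {nyquist}] Hz")
    sel = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi)
    if not sel.any():
        raise ValueError(f"no spectral bins inside the band {band}")
    mags = np.abs(spectrum.coefficients[sel])
    if mags.max() == 0:
        raise ValueError("spectrum is zero everywhere inside the band")
    return float(spectrum.frequencies[sel][np.argmax(mags)])


def _phase_deg(coefficients: np.ndarray) -> np.ndarray:
    deg = np.degrees(np.arctan2(np.imag(coefficients), np.real(coefficients)))
    return np.where(deg <= -180.0, deg + 360.0, deg)


def phase_at(spectrum: Spectrum, f_hz: float) -> float:
    """Phase angle (degrees, cosine-referenced) at the bin nearest ``f_hz``.

    Four-quadrant arctangent of the imaginary over real parts, mapped into
    (-180, 180]: cos -> 0, -cos -> 180, sin -> -90.
    """
    idx = spectrum.nearest_bin(f_hz)
    c = spectrum.coefficients[idx]
    if np.abs(c) == 0:
        raise ValueError(f"zero coefficient at {f_hz} Hz: phase is undefined")
    return float(_phase_deg(np.array([c]))[0])


@dataclass
class SpectralMapSet:
    """Co-registered wall-motion maps from one video.

    ``ratio_map`` (percent, fundamental / second harmonic x 100) and
    ``phase_map`` (degrees in (-180, 180]) are NaN outside ``mask``, the set of
    pixels whose RMS amplitude is within ``mask_db`` of the maximum RMS.
    """

    rms_map: np.ndarray
    fund_map: np.ndarray
    second_map: np.ndarray
    ratio_map: np.ndarray
    phase_map: np.ndarray
    fundamental_hz: float
    mask: np.ndarray
    frame_rate_hz: float

    @property
    def is_valid(self) -> bool:
        return bool(self.mask.any()) and np.isfinite(self.fundamental_hz)


def _bin_coefficients(detrended: np.ndarray, k: int, n_padded: int) -> np.ndarray:
    """Exact padded-FFT coefficient at bin k for every pixel, via direct dot.

    Equals np.fft.rfft(x, n=n_padded)[k] / T because zero padding only
    truncates the exponential sum at T terms.  Avoids materializing the full
    per-pixel spectrum for large frames.
    """
    t = detrended.shape[0]
    w = np.exp(-2j * np.pi * k * np.arange(t) / n_padded)
    return (w @ detrended) / t


def compute_map_set(
    stack: VideoStack,
    band: tuple[float, float] = DEFAULT_BAND,
    mask_db: float = 6.0,
    pad_factor: int = 4,
) -> SpectralMapSet:
    """Per-pixel FFT maps: RMS, harmonic magnitudes, ratio and phase.

    The fundamental frequency is chosen once per video as the modal in-band
    peak over the top-decile-RMS pixels (one heart rate per recording); the
    second harmonic is read at the bin nearest twice that frequency.  A stack
    with no temporal variation at all returns an all-invalid map set with an
    empty mask.
    """
    if stack.n_frames < 4:
        raise ValueError("need at least four frames")
    t, h, w = stack.frames.shape
    flat = stack.frames.reshape(t, h * w).astype(float)
    detrended = _linear_detrend(flat, axis=0)
    rms = np.sqrt(np.mean(detrended**2, axis=0))
    max_rms = rms.max()
    nan_map = np.full((h, w), np.nan)
    # 8-bit data: anything below a billionth of a gray level is detrending
    # roundoff, i.e. the video does not vary in time at all
    if max_rms < 1e-9:
        return SpectralMapSet(
            rms_map=rms.reshape(h, w),
            fund_map=np.zeros((h, w)),
            second_map=np.zeros((h, w)),
            ratio_map=nan_map.copy(),
            phase_map=nan_map.copy(),
            fundamental_hz=float("nan"),
            mask=np.zeros((h, w), dtype=bool),
            frame_rate_hz=stack.frame_rate_hz,
        )

    n_padded = pad_factor * t
    freqs = np.fft.rfftfreq(n_padded, 1.0 / stack.frame_rate_hz)
    band_sel = (freqs >= band[0]) & (freqs <= band[1])
    if not band_sel.any():
        raise ValueError(f"no spectral bins inside the band {band}")
    band_bins = np.flatnonzero(band_sel)

    # global fundamental: modal in-band peak over the strongest-moving pixels
    strong = rms >= np.quantile(rms, 0.9)
    spectra = np.fft.rfft(detrended[:, strong], n=n_padded, axis=0) / t
    in_band = np.abs(spectra[band_bins, :])
    if in_band.max() == 0:
        raise ValueError("no in-band spectral energy in the high-RMS pixels")
    # only pixels with a substantial in-band peak vote, so near-static pixels
    # that slipped into the top decile cannot outvote the moving wall
    peak_vals = in_band.max(axis=0)
    voters = peak_vals > 0.1 * peak_vals.max()
    peak_bins = band_bins[np.argmax(in_band[:, voters], axis=0)]
    k_fund = int(np.bincount(peak_bins).argmax())
    fundamental_hz = float(freqs[k_fund])
    k_second = int(np.argmin(np.abs(freqs - 2 * fundamental_hz)))

    c1 = _bin_coefficients(detrended, k_fund, n_padded)
    c2 = _bin_coefficients(detrended, k_second, n_padded)
    fund_map = (2 * np.abs(c1)).reshape(h, w)
    second_map = (2 * np.abs(c2)).reshape(h, w)
    mask = (rms >= max_rms * 10 ** (-mask_db / 20)).reshape(h, w)

    ratio_map = nan_map.copy()
    ok = mask & (second_map > 0)
    ratio_map[ok] = 100.0 * fund_map[ok] / second_map[ok]

    phase_map = nan_map.copy()
    phase_full = _phase_deg(c1).reshape(h, w)
    defined = mask & (fund_map > 0)
    phase_map[defined] = phase_full[defined]

    return SpectralMapSet(
        rms_map=rms.reshape(h, w),
        fund_map=fund_map,
        second_map=second_map,
        ratio_map=ratio_map,
        phase_map=phase_map,
        fundamental_hz=fundamental_hz,
        mask=mask,
        frame_rate_hz=stack.frame_rate_hz,
    )


def phase_histogram(map_set: SpectralMapSet, bin_width_deg: float = 5.0) -> pd.DataFrame:
    """Histogram of masked phase-map pixels over (-180, 180].

    Returns a table with columns ``bin_center_deg`` and ``count``.  Two
    dominant bins ~180 degrees apart are the signature of translational wall
    motion; a single dominant bin indicates radial dilation.
    """
    phases = map_set.phase_map[map_set.mask]
    phases = phases[np.isfinite(phases)]
    if phases.size == 0:
        raise ValueError("phase histogram needs a nonempty mask")
    n_bins = max(1, int(round(360.0 / bin_width_deg)))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # half-open bins (lo, hi]: shift exact -180 values onto +180 convention
    counts, _ = np.histogram(np.nextafter(phases, -np.inf), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center_deg": centers, "count": counts})
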