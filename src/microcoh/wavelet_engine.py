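"""Analytic Morlet continuous wavelet transform, time–frequency smoothing and cone of influence.

The engine underlying ensemble wavelet coherency: a complex Morlet CWT with
dyadic scale discretisation (12 voices per octave by default), the smoothing
operator ``S`` used to localise cross- and auto-spectra, and the cone of
influence (COI) marking bins corrupted by edge effects.

Conventions
-----------
* Mother wavelet: ``psi(t) = pi**(-1/4) * exp(1j*omega0*t) * exp(-t**2/2)``
  with ``omega0 = 6`` (admissibility).
* Scales ``sigma_k = s0 * 2**(k / voices)``, ``s0 = 2/fs`` (two samples).
* Equivalent Fourier frequency ``f_k = omega0 / (2*pi*sigma_k)``.
* COI: bins closer than ``sqrt(2)*sigma`` seconds (the e-folding time of the
  Gaussian envelope) to either record edge are invalid at scale ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft, fft, ifft

__all__ = [
    "WaveletSpec",
    "CWTResult",
    "build_scales",
    "cwt_morlet",
    "smooth_tf",
    "coi_mask",
    "coi_boundary",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class WaveletSpec:
    """Scale discretisation and smoothing configuration for the Morlet CWT.

    Attributes
    ----------
    omega0 : nondimensional centre frequency of the mother wavelet.
    voices_per_octave : scales per frequency doubling.
    n_octaves : number of octaves spanned (scales cover ``s0 .. s0*2**n_octaves``).
    s0 : smallest scale in seconds.
    scales : increasing scale grid (s), length ``voices_per_octave*n_octaves + 1``.
    freqs : equivalent Fourier frequencies (Hz), decreasing with scale.
    smooth_scales : width (in scale bins) of the boxcar used for scale smoothing.
    smooth_time_factor : Gaussian time-smoothing std in units of scale.
    """

    omega0: float
    voices_per_octave: int
    n_octaves: int
    s0: float
    scales: np.ndarray = field(repr=False)
    freqs: np.ndarray = field(repr=False)
    smooth_scales: int
    smooth_time_factor: float = 1.0
    scale_kernel: str = "gaussian"  # "gaussian" | "boxcar"
    scale_std_voices: float = 1.0  # Gaussian scale-kernel std, in voices

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def cache_key(self) -> tuple:
        return (
            self.omega0,
            self.voices_per_octave,
            self.n_octaves,
            self.s0,
            self.smooth_scales,
            self.smooth_time_factor,
            self.scale_kernel,
            self.scale_std_voices,
        )


@dataclass
class CWTResult:
    """Complex wavelet coefficients (scale x time) for one trace."""

    coeffs: np.ndarray  # complex, (n_scales, n_times)
    scales: np.ndarray  # (n_scales,) seconds
    freqs: np.ndarray  # (n_scales,) Hz
    fs: float
    coi_boundary: np.ndarray  # (n_times,) max valid scale (s) per time point


def max_octaves(fs: float, duration_s: float) -> int:
    """Largest admissible octave count for a record: ``floor(log2(fs*dt)) - 1``."""
    return int(np.floor(np.log2(fs * duration_s))) - 1


def build_scales(
    fs: float,
    duration_s: float,
    n_octaves: int | None = None,
    voices: int = 12,
    omega0: float = 6.0,
) -> WaveletSpec:
    """Build the dyadic scale grid for a record of ``duration_s`` seconds at ``fs`` Hz.

    ``n_octaves=None`` selects the maximum admissible count.

    Raises
    ------
    ValueError
        If ``n_octaves`` lies outside ``[1, floor(log2(fs*duration_s)) - 1]``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if fs * duration_s < 4:
        raise ValueError("record too short: fs*duration_s must be >= 4")
    bound = max_octaves(fs, duration_s)
    if n_octaves is None:
        n_octaves = bound
    if not (1 <= n_octaves <= bound):
        raise ValueError(
            f"n_octaves={n_octaves} outside the valid range [1, {bound}] "
            f"for fs={fs}, duration={duration_s}s"
        )
    if voices < 1:
        raise ValueError("voices must be >= 1")
    s0 = 2.0 / fs
    k = np.arange(voices * n_octaves + 1)
    scales = s0 * 2.0 ** (k / voices)
    freqs = omega0 / (2.0 * np.pi * scales)
    return WaveletSpec(
        omega0=float(omega0),
        voices_per_octave=int(voices),
        n_octaves=int(n_octaves),
        s0=s0,
        scales=scales,
        freqs=freqs,
        smooth_scales=int(voices),
    )


def cwt_morlet(x: np.ndarray, fs: float, spec: WaveletSpec) -> CWTResult:
    """Continuous wavelet transform of a 1-D signal with the analytic Morlet wavelet.

    FFT-based convolution with zero padding (no circular wrap within the
    record); L2 scale normalisation, ``pi**(-1/4)`` amplitude normalisation.
    Linear in ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN or infinite samples")
    n = x.size
    coeffs = _cwt_batch(x[None, :], fs, spec)[0]
    return CWTResult(
        coeffs=coeffs,
        scales=spec.scales,
        freqs=spec.freqs,
        fs=float(fs),
        coi_boundary=coi_boundary(n, fs),
    )


def _cwt_batch(x: np.ndarray, fs: float, spec: WaveletSpec) -> np.ndarray:
    """CWT of a batch of equal-length traces; returns (n_traces, n_scales, n_times).

    Padding covers the longest wavelet's effective support so the transform is
    a true linear (not circular) convolution over the record.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    pad = int(min(8.0 * spec.scales[-1] * fs, n))
    nfft = next_fast_len(n + 2 * pad)
    xf = fft(x, n=nfft, axis=-1)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    pos = omega > 0
    # psi_hat_sigma(w) = sqrt(2*pi*sigma*fs) * pi^(-1/4) * exp(-(sigma*w - omega0)^2 / 2), w > 0
    sig = spec.scales[:, None]
    psi_hat = np.zeros((spec.n_scales, nfft))
    psi_hat[:, pos] = (
        np.sqrt(2.0 * np.pi * sig * fs)
        * np.pi**-0.25
        * np.exp(-0.5 * (sig * omega[None, pos] - spec.omega0) ** 2)
    )
    out = ifft(xf[:, None, :] * psi_hat[None, :, :], axis=-1)
    return np.ascontiguousarray(out[..., :n])


# --- smoothing operator S -------------------------------------------------

_smooth_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_transfer(n_times: int, fs: float, spec: WaveletSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-scale Gaussian frequency responses and the normalisation field.

    Returns (transfer (n_scales, nfreq), norm (n_scales, n_times), nfft).
    The norm field is a smoothed all-ones record: dividing by it renormalises
    edge-truncated kernels so constants pass through unchanged.
    """
    key = (n_times, float(fs), spec.cache_key())
    cached = _smooth_cache.get(key)
    if cached is not None:
        return cached
    sig_samp = spec.smooth_time_factor * spec.scales * fs  # std in samples
    pad = int(min(5.0 * sig_samp[-1], 4 * n_times))
    nfft = next_fast_len(n_times + 2 * pad)
    omega = 2.0 * np.pi * np.fft.rfftfreq(nfft)
    transfer = np.exp(-0.5 * (sig_samp[:, None] * omega[None, :]) ** 2)
    ones = np.zeros((1, nfft))
    ones[0, :n_times] = 1.0
    norm = irfft(rfft(ones, axis=-1) * transfer, n=nfft, axis=-1)[:, :n_times]
    norm = np.maximum(norm, 1e-300)
    _smooth_cache[key] = (transfer, norm, nfft)
    return transfer, norm, nfft


def _scale_smooth(field: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    """Unit-sum smoothing across ``spec.smooth_scales`` adjacent scale bins.

    Kernel weights are Gaussian in log-scale (std ``scale_std_voices`` voices)
    by default, or flat with ``scale_kernel="boxcar"``; either way the kernel
    is truncated at the scale-axis edges and renormalised. The Gaussian
    weighting keeps the full 12-bin footprint while preserving the curvature
    of spectral ridges — a flat octave-wide boxcar plateaus ridge tops and
    mislocalises their maxima.
    """
    width = spec.smooth_scales
    if width <= 1:
        return field
    n_scales = field.shape[0]
    half = width // 2
    offsets = np.arange(-half, width - half)
    if spec.scale_kernel == "boxcar":
        weights = np.ones_like(offsets, dtype=float)
    elif spec.scale_kernel == "gaussian":
        weights = np.exp(-0.5 * (offsets / spec.scale_std_voices) ** 2)
    else:
        raise ValueError("scale_kernel must be 'gaussian' or 'boxcar'")
    out = np.zeros_like(field)
    norm = np.zeros(n_scales)
    for off, wgt in zip(offsets, weights):
        lo, hi = max(0, -off), min(n_scales, n_scales - off)
        out[lo:hi] += wgt * field[lo + off : hi + off]
        norm[lo:hi] += wgt
    return out / norm.reshape((-1,) + (1,) * (field.ndim - 1))


def smooth_tf(field: np.ndarray, spec: WaveletSpec, fs: float) -> np.ndarray:
    """Apply the smoothing operator S to a (n_scales, n_times) field.

    Time smoothing at scale ``sigma`` uses a unit-sum Gaussian of standard
    deviation ``sigma`` seconds; scale smoothing spans ``spec.smooth_scales``
    adjacent bins (Gaussian-weighted by default, see ``_scale_smooth``). Both
    kernels are truncated and renormalised at the record edges, so constant
    fields are preserved and non-negative fields stay non-negative.
    """
    field = np.asarray(field)
    if field.ndim != 2 or field.shape[0] != spec.n_scales:
        raise ValueError("field must have shape (n_scales, n_times)")
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    n_times = field.shape[1]
    transfer, norm, nfft = _gauss_transfer(n_times, fs, spec)
    if np.iscomplexobj(field):
        out = np.empty_like(field)
        for part, src in ((out.real, field.real), (out.imag, field.imag)):
            buf = np.zeros((spec.n_scales, nfft))
            buf[:, :n_times] = src
            part[:] = irfft(rfft(buf, axis=-1) * transfer, n=nfft, axis=-1)[:, :n_times]
        out /= norm
    else:
        buf = np.zeros((spec.n_scales, nfft))
        buf[:, :n_times] = field
        out = irfft(rfft(buf, axis=-1) * transfer, n=nfft, axis=-1)[:, :n_times]
        out /= norm
        if np.all(field >= 0):
            np.maximum(out, 0.0, out=out)
    return _scale_smooth(out, spec)


# --- cone of influence ----------------------------------------------------


def coi_boundary(n_samples: int, fs: float) -> np.ndarray:
    """Maximum valid scale (seconds) at each time point: min edge distance / sqrt(2)."""
    idx = np.arange(n_samples)
    edge = np.minimum(idx, n_samples - 1 - idx) / fs
    return edge / _SQRT2


def coi_mask(spec: WaveletSpec, n_samples: int, fs: float) -> np.ndarray:
    """Boolean (n_scales, n_times) mask; True where the estimate is unaffected by edges.

    At scale ``sigma`` the first and last ``round(sqrt(2)*sigma*fs)`` samples
    are invalid (e-folding time of the Morlet envelope = operational half
    wavelet length). The mask is symmetric about the record midpoint and the
    invalid margin widens monotonically with scale.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    margins = np.rint(_SQRT2 * spec.scales * fs).astype(int)
    mask = np.ones((spec.n_scales, n_samples), dtype=bool)
    for k, m in enumerate(margins):
        if m > 0:
            mask[k, :m] = False
            mask[k, n_samples - m:] = False
    return mask
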