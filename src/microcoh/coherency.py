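"""Ensemble wavelet-transform coherency (WTC), its imaginary part (IWTC) and phase.

For two channels i, j observed over N event-locked epochs, the ensemble
coherency at scale sigma and time tau is

    rhat_ij = sum_n S(w_i^n * conj(w_j^n))
              / sqrt( sum_n S(|w_i^n|^2) * sum_n S(|w_j^n|^2) )

where w^n are the epoch-wise Morlet CWT coefficients and S the time–scale
smoothing operator. |rhat| is the WTC in [0, 1]; Imag(rhat) is the IWTC,
insensitive to zero-lag (volume-conducted) coupling because a common source
contributes with zero phase difference and hence only to the real part.

Phase convention: arg(rhat_ij) = phi_i - phi_j, so a positive imaginary part
means channel j's oscillation leads channel i's (information flow j -> i).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io_preproc import EpochArray
from .wavelet_engine import WaveletSpec, _cwt_batch, build_scales, coi_mask, smooth_tf

__all__ = ["CoherencyMap", "ensemble_wtc", "iwtc_map", "phase_field", "all_pairs_maps"]


@dataclass
class CoherencyMap:
    """Complex ensemble coherency for one channel pair over scales x time."""

    rhat: np.ndarray  # complex (n_scales, n_times)
    scales: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # seconds relative to the event
    fs: float
    n_epochs: int
    pair: tuple[str, str]
    coi: np.ndarray  # bool (n_scales, n_times), True inside the valid region
    valid: np.ndarray  # bool, False where the denominator vanished

    @property
    def wtc(self) -> np.ndarray:
        """Coherence magnitude |rhat| in [0, 1]."""
        return np.abs(self.rhat)

    @property
    def iwtc(self) -> np.ndarray:
        """Imaginary part of the coherency, in [-1, 1]."""
        return self.rhat.imag

    @property
    def phase(self) -> np.ndarray:
        """Relative phase arg(rhat) in (-pi, pi]."""
        return np.angle(self.rhat)


def _epoch_cwts(epochs: EpochArray, channel: int, spec: WaveletSpec) -> np.ndarray:
    """CWT coefficients for every epoch of one channel: (n_epochs, n_scales, n_times)."""
    return _cwt_batch(epochs.data[:, channel, :], epochs.fs, spec)


def ensemble_coherency_from_cwt(
    wi: np.ndarray, wj: np.ndarray, spec: WaveletSpec, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """rhat from precomputed per-epoch CWT stacks; returns (rhat, valid)."""
    if wi.shape != wj.shape:
        raise ValueError("mismatched CWT stacks")
    num = np.zeros(wi.shape[1:], dtype=complex)
    den_i = np.zeros(wi.shape[1:])
    den_j = np.zeros(wi.shape[1:])
    for n in range(wi.shape[0]):
        num += smooth_tf(wi[n] * np.conj(wj[n]), spec, fs)
        den_i += smooth_tf(np.abs(wi[n]) ** 2, spec, fs)
        den_j += smooth_tf(np.abs(wj[n]) ** 2, spec, fs)
    den = np.sqrt(den_i * den_j)
    valid = den > 0
    rhat = np.zeros_like(num)
    np.divide(num, den, out=rhat, where=valid)
    return rhat, valid


def ensemble_wtc(
    epochs: EpochArray,
    i: int | str,
    j: int | str,
    spec: WaveletSpec | None = None,
) -> CoherencyMap:
    """Ensemble wavelet coherency between two channels of an epoch array.

    Channels may be given by index or label; ``spec=None`` builds the default
    dyadic grid (omega0=6, 12 voices, maximum octaves) for the epoch length.
    """
    ci, cj = _resolve_channel(epochs, i), _resolve_channel(epochs, j)
    if ci == cj:
        raise ValueError("i and j must name distinct channels")
    if spec is None:
        spec = build_scales(epochs.fs, epochs.n_samples / epochs.fs)
    wi = _epoch_cwts(epochs, ci, spec)
    wj = _epoch_cwts(epochs, cj, spec)
    rhat, valid = ensemble_coherency_from_cwt(wi, wj, spec, epochs.fs)
    return CoherencyMap(
        rhat=rhat,
        scales=spec.scales,
        freqs=spec.freqs,
        times=epochs.times,
        fs=epochs.fs,
        n_epochs=epochs.n_epochs,
        pair=(epochs.channel_labels[ci], epochs.channel_labels[cj]),
        coi=coi_mask(spec, epochs.n_samples, epochs.fs),
        valid=valid,
    )


def _resolve_channel(epochs: EpochArray, ch: int | str) -> int:
    if isinstance(ch, str):
        try:
            return epochs.channel_labels.index(ch)
        except ValueError:
            raise KeyError(f"unknown channel {ch!r}; valid: {epochs.channel_labels}") from None
    if not (0 <= ch < epochs.n_channels):
        raise IndexError(f"channel index {ch} out of range")
    return int(ch)


def iwtc_map(cmap: CoherencyMap) -> np.ndarray:
    """Imaginary part of the ensemble coherency (zero-lag coupling suppressed)."""
    return cmap.rhat.imag


def phase_field(cmap: CoherencyMap) -> tuple[np.ndarray, np.ndarray]:
    """Relative phase and lead/lag direction codes per time–frequency bin.

    Returns ``(phase, direction)`` where ``direction = sign(Imag(rhat))``:
    +1 means the second channel of the pair leads the first (information
    flows j -> i), -1 the reverse, 0 purely in-/anti-phase. The real-axis
    sign of rhat separates in-phase (positive) from anti-phase (negative)
    synchronisation.
    """
    return np.angle(cmap.rhat), np.sign(cmap.rhat.imag)


def all_pairs_maps(
    epochs: EpochArray,
    spec: WaveletSpec | None = None,
    memory_cap_bytes: int = 2 * 1024**3,
) -> dict[tuple[str, str], CoherencyMap]:
    """Ensemble coherency maps for all unordered channel pairs.

    Pairs are ordered lexicographically by label; per-epoch CWTs are computed
    once per channel and reused across pairs. Raises ``MemoryError`` when the
    CWT tensor would exceed ``memory_cap_bytes`` (subset channels or reduce
    the scale count in that case).
    """
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if spec is None:
        spec = build_scales(epochs.fs, epochs.n_samples / epochs.fs)
    est = epochs.n_epochs * epochs.n_channels * spec.n_scales * epochs.n_samples * 16
    if est > memory_cap_bytes:
        raise MemoryError(
            f"per-epoch CWT tensor would need ~{est / 1e9:.1f} GB (cap "
            f"{memory_cap_bytes / 1e9:.1f} GB); subset channels or reduce scales"
        )
    order = sorted(range(epochs.n_channels), key=lambda c: epochs.channel_labels[c])
    cwts = {c: _epoch_cwts(epochs, c, spec) for c in order}
    coi = coi_mask(spec, epochs.n_samples, epochs.fs)
    out: dict[tuple[str, str], CoherencyMap] = {}
    for ci, cj in combinations(order, 2):
        rhat, valid = ensemble_coherency_from_cwt(cwts[ci], cwts[cj], spec, epochs.fs)
        pair = (epochs.channel_labels[ci], epochs.channel_labels[cj])
        out[pair] = CoherencyMap(
            rhat=rhat,
            scales=spec.scales,
            freqs=spec.freqs,
            times=epochs.times,
            fs=epochs.fs,
            n_epochs=epochs.n_epochs,
            pair=pair,
            coi=coi,
            valid=valid,
        )
    return out
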