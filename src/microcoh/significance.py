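"""Bootstrap significance of coherency against surrogate background epochs.

The null hypothesis is independence between the two channels. Surrogate
ensembles are built by resampling background epochs with replacement,
independently per channel (breaking any cross-channel pairing), and the
observed coherency is flagged where it exceeds a chosen quantile of the
surrogate distribution. This is non-parametric: no spectral model of the
background is assumed — the user's background epochs *are* the null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coherency import CoherencyMap, _epoch_cwts
from .io_preproc import EpochArray
from .wavelet_engine import WaveletSpec, coi_mask, smooth_tf

__all__ = ["SurrogateDistribution", "SignificanceMask", "surrogate_distribution", "significance_mask"]

_MEASURES = ("wtc", "iwtc_abs")


@dataclass
class SurrogateDistribution:
    """B surrogate coherency fields for one channel pair under independence."""

    samples: np.ndarray  # float32 (B, n_scales, n_times)
    B: int
    measure: str  # "wtc" | "iwtc_abs"
    pooling: str  # "bin" | "scale"
    coi: np.ndarray  # bool (n_scales, n_times)
    seed: int
    pair: tuple[str, str]
    n_match: int

    def threshold(self, q: float) -> np.ndarray:
        """Surrogate q-quantile per (scale, time) bin.

        With ``pooling="scale"`` the quantile pools all inside-COI time bins of
        a scale across resamples (useful for small B); thresholds are then
        constant along time.
        """
        if not (0 < q <= 1):
            raise ValueError("q must be in (0, 1]")
        if self.pooling == "bin":
            return np.quantile(self.samples, q, axis=0)
        thr = np.empty(self.samples.shape[1:])
        for k in range(self.samples.shape[1]):
            inside = self.coi[k]
            pool = self.samples[:, k, inside] if inside.any() else self.samples[:, k, :]
            thr[k] = np.quantile(pool, q)
        return thr


@dataclass
class SignificanceMask:
    """Boolean significance flags per (scale, time); False everywhere outside the COI."""

    flags: np.ndarray
    q: float
    B: int
    measure: str
    pair: tuple[str, str]


def _measure_field(rhat: np.ndarray, measure: str) -> np.ndarray:
    if measure == "wtc":
        return np.abs(rhat)
    if measure == "iwtc_abs":
        return np.abs(rhat.imag)
    raise ValueError(f"measure must be one of {_MEASURES}")


def surrogate_distribution(
    background: EpochArray,
    n_match: int,
    B: int,
    spec: WaveletSpec,
    seed: int,
    i: int | str = 0,
    j: int | str = 1,
    measure: str = "iwtc_abs",
    pooling: str = "bin",
    paired: bool = False,
) -> SurrogateDistribution:
    """Bootstrap distribution of ensemble coherency under channel independence.

    Each of the ``B`` resamples draws ``n_match`` background epochs with
    replacement — independently for the two channels unless ``paired`` —
    computes the ensemble coherency and records ``measure``. Deterministic
    under a fixed ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if background.n_epochs < 2:
        raise ValueError("background must contain at least 2 epochs")
    if measure not in _MEASURES:
        raise ValueError(f"measure must be one of {_MEASURES}")
    if pooling not in ("bin", "scale"):
        raise ValueError("pooling must be 'bin' or 'scale'")
    from .coherency import _resolve_channel

    ci, cj = _resolve_channel(background, i), _resolve_channel(background, j)
    fs = background.fs
    rng = np.random.default_rng(seed)

    wi = _epoch_cwts(background, ci, spec)
    wj = wi if cj == ci else _epoch_cwts(background, cj, spec)
    # per-epoch smoothed auto-spectra, reused across resamples
    s_ii = np.stack([smooth_tf(np.abs(w) ** 2, spec, fs) for w in wi])
    s_jj = s_ii if cj == ci else np.stack([smooth_tf(np.abs(w) ** 2, spec, fs) for w in wj])

    n_bg = background.n_epochs
    shape = wi.shape[1:]
    samples = np.empty((B,) + shape, dtype=np.float32)
    for b in range(B):
        idx_i = rng.integers(0, n_bg, size=n_match)
        idx_j = idx_i if paired else rng.integers(0, n_bg, size=n_match)
        num = np.zeros(shape, dtype=complex)
        for a, c in zip(idx_i, idx_j):
            num += smooth_tf(wi[a] * np.conj(wj[c]), spec, fs)
        den = np.sqrt(s_ii[idx_i].sum(axis=0) * s_jj[idx_j].sum(axis=0))
        rhat = np.zeros(shape, dtype=complex)
        np.divide(num, den, out=rhat, where=den > 0)
        samples[b] = _measure_field(rhat, measure)

    return SurrogateDistribution(
        samples=samples,
        B=int(B),
        measure=measure,
        pooling=pooling,
        coi=coi_mask(spec, background.n_samples, fs),
        seed=int(seed),
        pair=(background.channel_labels[ci], background.channel_labels[cj]),
        n_match=int(n_match),
    )


def significance_mask(cmap: CoherencyMap, dist: SurrogateDistribution, q: float = 0.95) -> SignificanceMask:
    """Flag bins where the observed measure exceeds the surrogate q-quantile.

    Flags are intersected with the cone of influence and the coherency
    validity mask, so nothing outside the COI is ever significant.
    """
    if cmap.rhat.shape != dist.samples.shape[1:]:
        raise ValueError(
            f"axis mismatch: map {cmap.rhat.shape} vs surrogate {dist.samples.shape[1:]}"
        )
    observed = _measure_field(cmap.rhat, dist.measure)
    flags = (observed > dist.threshold(q)) & cmap.coi & cmap.valid
    return SignificanceMask(flags=flags, q=float(q), B=dist.B, measure=dist.measure, pair=cmap.pair)


def flagged_fraction(mask: SignificanceMask, coi: np.ndarray) -> float:
    """Fraction of inside-COI bins that are flagged (empirical type-I rate under the null)."""
    inside = int(coi.sum())
    if inside == 0:
        return float("nan")
    return float(mask.flags[coi].sum()) / inside
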