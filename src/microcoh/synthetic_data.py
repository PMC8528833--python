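"""Seeded synthetic fixtures: the two-channel piecewise oscillator pair and
multichannel event-locked recordings with known directed coupling.

Every generator is a pure function of its ``SimSpec`` (seed included), so
fixtures are bit-reproducible. The two-channel pair interleaves a slow
(10 Hz) and a fast (45 Hz) rhythm with staggered on/off gates and a fixed
quarter-cycle (pi/2) offset between channels — the x channel carries
cosines, the y channel sines — over white noise of standard deviation 0.05.
Where the two gates of a channel overlap in time the components add, so both
rhythms coexist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preproc import EpochArray, EventSet, SignalSet

__all__ = ["SimSpec", "Coupling", "insilico_pair", "ied_network_sim", "background_epochs"]


@dataclass(frozen=True)
class Coupling:
    """Directed lagged coupling: the dst channel repeats src's event transient."""

    src: int
    dst: int
    lag_s: float
    band_hz: float
    amplitude: float = 1.0


@dataclass
class SimSpec:
    """Generator conditions.

    Defaults match the two-channel demo pair: fs=500 Hz, 2 s records, 30
    trials, additive white noise of sd 0.05. The network-fixture fields
    (``n_channels`` onward) configure event-locked recordings with known
    directed coupling on 1/f background noise.
    """

    fs: float = 500.0
    duration: float = 2.0
    n_trials: int = 30
    noise_sd: float = 0.05
    seed: int = 0
    # network fixture parameters
    n_channels: int = 3
    couplings: tuple[Coupling, ...] = field(default_factory=tuple)
    n_events: int = 30
    event_spacing: float = 5.0
    transient_amp: float = 8.0
    transient_decay: float = 0.05  # e-folding time of the damped oscillation (s)
    transient_len: float = 0.25  # transient support (s)
    bg_sd: float = 1.0  # 1/f background standard deviation
    independent_transients: bool = False  # phase/onset-jittered transient on every channel

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


# gates of the piecewise pair: (frequency Hz, t_on, t_off), x = cosines, y = sines
_X_GATES = ((10.0, 0.5, 1.1), (45.0, 0.2, 1.4))
_Y_GATES = ((10.0, 0.7, 1.2), (45.0, 0.5, 1.6))


def _gated(t: np.ndarray, gates, func) -> np.ndarray:
    out = np.zeros_like(t)
    for f, lo, hi in gates:
        gate = (t >= lo) & (t < hi)
        out[gate] += func(2.0 * np.pi * f * t[gate])
    return out


def insilico_pair(spec: SimSpec | None = None) -> EpochArray:
    """Trials of the two-channel piecewise cosine/sine pair with white noise.

    Channel ``x``: cos(2*pi*10 t) on [0.5, 1.1) plus cos(2*pi*45 t) on
    [0.2, 1.4); channel ``y``: sin(2*pi*10 t) on [0.7, 1.2) plus
    sin(2*pi*45 t) on [0.5, 1.6); each trial adds fresh white noise of
    sd ``spec.noise_sd`` per channel. Requires ``duration >= 1.6`` s.
    """
    spec = spec or SimSpec()
    if spec.duration < 1.6:
        raise ValueError("duration must be >= 1.6 s to cover the gated intervals")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) / spec.fs
    x_clean = _gated(t, _X_GATES, np.cos)
    y_clean = _gated(t, _Y_GATES, np.sin)
    data = np.empty((spec.n_trials, 2, spec.n_samples))
    for n in range(spec.n_trials):
        data[n, 0] = x_clean + spec.noise_sd * rng.standard_normal(spec.n_samples)
        data[n, 1] = y_clean + spec.noise_sd * rng.standard_normal(spec.n_samples)
    return EpochArray(data=data, fs=spec.fs, t0_index=0, channel_labels=["x", "y"])


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit-variance scaled to ``sd``."""
    white = rng.standard_normal(n)
    spec_ = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    shaped = np.fft.irfft(spec_ * shape, n=n)
    return sd * shaped / shaped.std()


def _transient(spec: SimSpec, band_hz: float, phase: float = 0.0) -> np.ndarray:
    """Damped oscillation emulating a sub-second epileptiform-like burst."""
    t = np.arange(int(round(spec.transient_len * spec.fs))) / spec.fs
    return np.exp(-t / spec.transient_decay) * np.sin(2.0 * np.pi * band_hz * t + phase)


def ied_network_sim(spec: SimSpec) -> tuple[SignalSet, EventSet, dict]:
    """Multichannel recording with event-locked transients and known directed coupling.

    Background is independent 1/f noise per channel. At each event a damped
    oscillation is placed on every coupling's src channel and copied to its
    dst channel delayed by ``lag_s`` and scaled by ``amplitude``. With
    ``independent_transients`` every channel instead receives its own
    transient with random phase and onset jitter — event-locked power without
    cross-channel coupling (the control condition). Returns the recording,
    the events, and metadata with the ground-truth directed graph.
    """
    for c in spec.couplings:
        if not (0 <= c.src < spec.n_channels and 0 <= c.dst < spec.n_channels):
            raise ValueError(f"coupling references invalid channel: {c}")
        if c.lag_s >= spec.event_spacing:
            raise ValueError(f"lag {c.lag_s}s exceeds the inter-event spacing")
    rng = np.random.default_rng(spec.seed)
    margin = spec.event_spacing / 2.0
    onsets = margin + np.arange(spec.n_events) * spec.event_spacing
    total = float(onsets[-1] + margin)
    n = int(round(total * spec.fs))
    data = np.stack([_pink_noise(rng, n, spec.bg_sd) for _ in range(spec.n_channels)])

    def add(ch: int, t_on: float, wave: np.ndarray, scale: float = 1.0) -> None:
        i0 = int(round(t_on * spec.fs))
        i1 = min(i0 + wave.size, n)
        if i0 < n:
            data[ch, i0:i1] += scale * wave[: i1 - i0]

    bands = [c.band_hz for c in spec.couplings] or [20.0]
    for t_ev in onsets:
        amp = spec.transient_amp * (1.0 + 0.2 * rng.standard_normal())
        if spec.independent_transients:
            for ch in range(spec.n_channels):
                jitter = 0.15 * rng.uniform(-1.0, 1.0)
                wave = _transient(spec, bands[ch % len(bands)], phase=rng.uniform(0, 2 * np.pi))
                add(ch, t_ev + jitter, wave, amp)
        for c in spec.couplings:
            wave = _transient(spec, c.band_hz)
            add(c.src, t_ev, wave, amp)
            add(c.dst, t_ev + c.lag_s, wave, amp * c.amplitude)

    labels = [f"ch{i}" for i in range(spec.n_channels)]
    sig = SignalSet(samples=data, fs=spec.fs, channel_labels=labels)
    events = EventSet([(float(t), "IED") for t in onsets])
    truth = {
        "true_edges": [(labels[c.src], labels[c.dst], c.lag_s, c.band_hz, c.amplitude) for c in spec.couplings],
        "independent_transients": spec.independent_transients,
        "seed": spec.seed,
    }
    return sig, events, truth


def background_epochs(spec: SimSpec) -> EpochArray:
    """Independent white-noise epochs matched in shape to analysis epochs.

    The surrogate-model supplier: ``n_trials`` epochs x ``n_channels``
    channels x ``round(fs*duration)`` samples of N(0, noise_sd^2) noise.
    """
    if spec.n_trials < 2:
        raise ValueError("need at least 2 background epochs")
    rng = np.random.default_rng(spec.seed)
    data = spec.noise_sd * rng.standard_normal((spec.n_trials, spec.n_channels, spec.n_samples))
    labels = [f"bg{i}" for i in range(spec.n_channels)]
    return EpochArray(data=data, fs=spec.fs, t0_index=0, channel_labels=labels)
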