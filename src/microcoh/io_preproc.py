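"""Reading EDF/EDF+ recordings, standard preprocessing and event-locked epoching.

Multichannel electrophysiology enters the pipeline here: signals are read
from EDF/EDF+ (annotations honoured), optionally channel-subset, resampled
and baseline-corrected, then cut into event-locked epochs — the ensemble
units of the coherency estimator.

Units: samples are held in microvolts throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy.signal import resample_poly, detrend as _sp_detrend

__all__ = [
    "SignalSet",
    "EventSet",
    "EpochArray",
    "read_edf",
    "write_edf",
    "preprocess",
    "extract_epochs",
    "save_epochs",
    "load_epochs",
]


@dataclass
class SignalSet:
    """A multichannel recording: ``samples`` is (n_channels, n_times) in µV."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match number of channels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs


@dataclass
class EventSet:
    """Annotated events: (onset_seconds, label), onsets sorted ascending."""

    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted([(float(t), str(lbl)) for t, lbl in self.events])
        if self.events and self.events[0][0] < 0:
            raise ValueError("event onsets must be non-negative")

    def __len__(self) -> int:
        return len(self.events)

    def select(self, label: str) -> "EventSet":
        return EventSet([e for e in self.events if e[1] == label])

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t for t, _ in self.events])


@dataclass
class EpochArray:
    """Event-locked epochs: ``data`` is (n_epochs, n_channels, n_samples) in µV.

    ``t0_index`` is the sample index of the event within each epoch, so the
    epoch time axis is ``(arange(n_samples) - t0_index) / fs`` seconds.
    """

    data: np.ndarray
    fs: float
    t0_index: int
    channel_labels: list[str]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one epoch")
        if not (0 <= self.t0_index < self.data.shape[2]):
            raise ValueError("t0_index must lie within the epoch")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length must match channels")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to the event (t=0)."""
        return (np.arange(self.n_samples) - self.t0_index) / self.fs


# --- EDF I/O ----------------------------------------------------------------


def read_edf(path: str | Path) -> tuple[SignalSet, EventSet]:
    """Read an EDF/EDF+ file into a SignalSet (µV) and an EventSet.

    Uses MNE for parsing; physical scaling from the EDF header is applied and
    the EDF+ annotations channel is mapped to events. Raises ``FileNotFoundError``
    for a missing path and ``ValueError`` for an unparseable file.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # corrupt/invalid file
        raise ValueError(f"could not parse EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE holds volts
    sig = SignalSet(
        samples=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        start_time=0.0,
    )
    events = EventSet(
        [(float(on), str(desc)) for on, desc in zip(raw.annotations.onset, raw.annotations.description)]
    )
    return sig, events


def write_edf(
    path: str | Path,
    sig: SignalSet,
    events: EventSet | None = None,
    record_duration: float = 1.0,
) -> None:
    """Write a SignalSet (+ optional events) as a 16-bit EDF+ file.

    A compact writer covering the subset of EDF+ this package produces:
    equal sampling rate across channels, one annotations signal carrying the
    events as TALs. The final data record is zero-padded if the recording
    length is not a whole number of records.
    """
    path = Path(path)
    spr = sig.fs * record_duration
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("fs * record_duration must be an integer sample count")
    spr = int(round(spr))
    n_records = max(1, math.ceil(sig.n_times / spr))
    nchan = sig.n_channels

    # physical/digital scaling per channel
    dig_min, dig_max = -32767, 32767
    phys_min, phys_max = [], []
    digital = np.empty((nchan, n_records * spr), dtype="<i2")
    for c in range(nchan):
        x = np.zeros(n_records * spr)
        x[: sig.n_times] = sig.samples[c]
        amp = max(np.max(np.abs(x)), 1e-6)
        pmin, pmax = -amp, amp
        phys_min.append(pmin)
        phys_max.append(pmax)
        gain = (dig_max - dig_min) / (pmax - pmin)
        digital[c] = np.clip(np.rint((x - pmin) * gain + dig_min), dig_min, dig_max).astype("<i2")

    # annotation TALs, one block per record
    evts = list(events.events) if events is not None else []
    tal_blocks: list[bytes] = []
    for r in range(n_records):
        onset = r * record_duration
        block = f"+{onset:g}\x14\x14\x00".encode("ascii")
        lo, hi = onset, onset + record_duration
        for t, lbl in evts:
            if lo <= t < hi or (r == n_records - 1 and t >= hi):
                block += f"+{t:g}\x14\x14{lbl}\x14\x00".encode("utf-8")
        tal_blocks.append(block)
    annot_bytes = max(16, max(len(b) for b in tal_blocks))
    annot_bytes += annot_bytes % 2  # whole number of 2-byte samples
    annot_spr = annot_bytes // 2

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    ns = nchan + 1  # + annotations signal
    header_bytes = 256 * (ns + 1)
    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(header_bytes), 8),
            pad("EDF+C", 44),
            pad(str(n_records), 8),
            pad(f"{record_duration:g}", 8),
            pad(str(ns), 4),
        ]
    )
    labels = [pad(lbl, 16) for lbl in sig.channel_labels] + [pad("EDF Annotations", 16)]
    transducer = [pad("", 80)] * ns
    dim = [pad("uV", 8)] * nchan + [pad("", 8)]
    pmin_f = [pad(f"{v:.6g}"[:8], 8) for v in phys_min] + [pad("-1", 8)]
    pmax_f = [pad(f"{v:.6g}"[:8], 8) for v in phys_max] + [pad("1", 8)]
    dmin_f = [pad(str(dig_min), 8)] * nchan + [pad("-32768", 8)]
    dmax_f = [pad(str(dig_max), 8)] * nchan + [pad("32767", 8)]
    prefilter = [pad("", 80)] * ns
    spr_f = [pad(str(spr), 8)] * nchan + [pad(str(annot_spr), 8)]
    reserved = [pad("", 32)] * ns
    for group in (labels, transducer, dim, pmin_f, pmax_f, dmin_f, dmax_f, prefilter, spr_f, reserved):
        hdr += b"".join(group)

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            for c in range(nchan):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())
            fh.write(tal_blocks[r].ljust(annot_bytes, b"\x00"))


# --- preprocessing ----------------------------------------------------------


def preprocess(
    sig: SignalSet,
    channels: list[str] | None = None,
    target_fs: float | None = None,
    baseline: bool = False,
    detrend: bool = False,
) -> SignalSet:
    """Channel selection, polyphase resampling and baseline removal.

    Channels are returned in the requested order. Resampling uses zero-phase
    polyphase filtering (anti-aliasing included), preserving phase structure
    for downstream coherency. Baseline removal subtracts the per-channel mean
    (idempotent); ``detrend`` removes a linear trend instead.
    """
    data = sig.samples
    labels = list(sig.channel_labels)
    if channels is not None:
        missing = [c for c in channels if c not in labels]
        if missing:
            raise KeyError(f"unknown channel(s) {missing}; valid labels: {labels}")
        idx = [labels.index(c) for c in channels]
        data = data[idx]
        labels = list(channels)
    fs = sig.fs
    if target_fs is not None and not np.isclose(target_fs, fs):
        if target_fs > fs:
            raise ValueError(f"target_fs={target_fs} exceeds current fs={fs}")
        frac = Fraction(target_fs / fs).limit_denominator(1000)
        data = resample_poly(data, frac.numerator, frac.denominator, axis=1)
        fs = float(target_fs)
    if detrend:
        data = _sp_detrend(data, axis=1, type="linear")
    if baseline:
        data = data - data.mean(axis=1, keepdims=True)
    return SignalSet(samples=data, fs=fs, channel_labels=labels, start_time=sig.start_time)


def extract_epochs(
    sig: SignalSet,
    ev: EventSet,
    pre_s: float,
    post_s: float,
    baseline: str | None = None,
) -> EpochArray:
    """Cut event-locked epochs spanning ``[onset - pre_s, onset + post_s)``.

    Every epoch has ``round((pre_s + post_s) * fs)`` samples with the event at
    ``t0_index = round(pre_s * fs)``. Events whose window would cross the
    recording edges are skipped (counted in ``EpochArray.n_skipped``) rather
    than zero-padded. ``baseline`` may be ``"mean"`` (per-channel per-epoch
    mean subtraction) or ``"pre_event"`` (mean of the pre-event interval).
    """
    if pre_s <= 0 or post_s <= 0:
        raise ValueError("pre_s and post_s must be positive")
    n_len = int(round((pre_s + post_s) * sig.fs))
    t0 = int(round(pre_s * sig.fs))
    epochs, skipped = [], 0
    for onset, _ in ev.events:
        ev_idx = int(round(onset * sig.fs))
        start, stop = ev_idx - t0, ev_idx - t0 + n_len
        if start < 0 or stop > sig.n_times:
            skipped += 1
            continue
        epochs.append(sig.samples[:, start:stop])
    if not epochs:
        raise ValueError(f"no usable events: all {skipped} event window(s) cross the recording edges")
    data = np.stack(epochs)
    if baseline == "mean":
        data = data - data.mean(axis=2, keepdims=True)
    elif baseline == "pre_event":
        data = data - data[:, :, :t0].mean(axis=2, keepdims=True)
    elif baseline is not None:
        raise ValueError("baseline must be None, 'mean' or 'pre_event'")
    return EpochArray(
        data=data, fs=sig.fs, t0_index=t0, channel_labels=list(sig.channel_labels), n_skipped=skipped
    )


# --- epoch container --------------------------------------------------------


def save_epochs(path: str | Path, epochs: EpochArray) -> None:
    """Store epochs in HDF5 with a JSON metadata sidecar (`<path>.json`)."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data)
        fh.attrs["fs"] = epochs.fs
        fh.attrs["t0_index"] = epochs.t0_index
        fh.attrs["channel_labels"] = json.dumps(epochs.channel_labels)
        fh.attrs["n_skipped"] = epochs.n_skipped
    meta = {
        "fs": epochs.fs,
        "t0_index": int(epochs.t0_index),
        "channel_labels": epochs.channel_labels,
        "n_epochs": int(epochs.n_epochs),
        "n_samples": int(epochs.n_samples),
        "n_skipped": int(epochs.n_skipped),
        "units": "uV",
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_epochs(path: str | Path) -> EpochArray:
    with h5py.File(path, "r") as fh:
        return EpochArray(
            data=fh["data"][()],
            fs=float(fh.attrs["fs"]),
            t0_index=int(fh.attrs["t0_index"]),
            channel_labels=json.loads(fh.attrs["channel_labels"]),
            n_skipped=int(fh.attrs.get("n_skipped", 0)),
        )
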