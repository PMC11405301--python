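"""sEEG recording handling: EDF loading, event cropping, filtering, and
globally normalized windowed power.

The power pipeline mirrors how the animation is driven: the clip around
the marked event is notch-filtered at the powerline frequency (and
harmonics), bandpassed 80–250 Hz with a zero-phase Hamming-window FIR
(the band commonly used for high-frequency-oscillation detection), cut
into consecutive 24-sample windows, and reduced to mean squared amplitude
per window.  A single min–max map across all contacts and windows brings
the values to [0, 1], so any constant factor in the power definition
cancels out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps


@dataclass
class Recording:
    """In-memory multichannel recording in microvolts."""

    channels: list[str]
    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel count does not match data rows")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.duration_s
        for t, label in self.annotations:
            if not 0 <= t <= dur:
                raise ValueError(f"annotation {label!r} at {t} s outside record")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class FilterSpec:
    """Notch + bandpass filtering parameters.

    Only the powerline fundamental is notched by default: its harmonics
    (120, 180, 240 Hz at 60 Hz mains) fall inside the 80-250 Hz analysis
    band and notching them would carve holes out of the very activity the
    power traces are meant to show.  Set ``notch_harmonics`` > 1 for
    recordings with strong harmonic contamination.
    """

    notch_hz: float = 60.0
    band_lo_hz: float = 80.0
    band_hi_hz: float = 250.0
    notch_harmonics: int = 1
    transition_hz: float = 10.0  # FIR transition width (Hamming, >=53 dB)

    def validate(self, fs: float) -> None:
        nyq = fs / 2
        if not 0 < self.band_lo_hz < self.band_hi_hz < nyq:
            raise ValueError(
                f"band {self.band_lo_hz}-{self.band_hi_hz} Hz invalid for fs={fs}"
            )
        if not 0 < self.notch_hz < nyq:
            raise ValueError(f"notch {self.notch_hz} Hz beyond Nyquist")


@dataclass
class PowerTrace:
    """Contacts x windows matrix of windowed power."""

    values: np.ndarray  # (n_channels, n_windows)
    channels: list[str]
    window_len: int  # N, in samples
    fs: float
    normalized: bool = False

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def window_s(self) -> float:
        """Data-time covered by one window, in seconds."""
        return self.window_len / self.fs

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.channels, name="contact"))


def read_recording(path: str | Path) -> Recording:
    """Load an EDF/EDF+ file, preserving channel names verbatim."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if len(raw.ch_names) == 0:
        raise ValueError(f"{path} contains no channels")
    data = raw.get_data() * 1e6  # volts -> microvolts
    annotations = [
        (float(onset), str(desc))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return Recording(list(raw.ch_names), data, float(raw.info["sfreq"]), annotations)


def crop_around_event(
    rec: Recording,
    label: str,
    pre_s: float = 2.0,
    post_s: float = 2.0,
    occurrence: int | None = None,
) -> tuple[Recording, float]:
    """Crop ``pre_s + post_s`` seconds of signal around an annotated event.

    Returns the clip and the event time re-expressed relative to the clip
    start (``pre_s`` unless clamped at a record edge).  If the label occurs
    more than once an explicit 0-based ``occurrence`` is required.
    """
    matches = [t for t, lab in rec.annotations if lab == label]
    if not matches:
        available = sorted({lab for _, lab in rec.annotations})
        raise ValueError(f"no annotation {label!r}; available: {available}")
    if len(matches) > 1 and occurrence is None:
        raise ValueError(
            f"annotation {label!r} occurs {len(matches)} times; "
            "pass an occurrence index"
        )
    t_event = matches[occurrence or 0]
    start = t_event - pre_s
    stop = t_event + post_s
    if start < 0 or stop > rec.duration_s:
        warnings.warn("event window clamped at record edge")
        start = max(start, 0.0)
        stop = min(stop, rec.duration_s)
    i0 = int(round(start * rec.fs))
    i1 = int(round(stop * rec.fs))
    clip = Recording(
        rec.channels,
        rec.samples[:, i0:i1].copy(),
        rec.fs,
        [(t - start, lab) for t, lab in rec.annotations if start <= t <= stop],
    )
    return clip, t_event - start


def apply_filters(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Notch at the powerline frequency and its harmonics, then zero-phase
    windowed-FIR bandpass.

    Both stages are applied forward-backward so burst timing is not
    shifted relative to the seizure marker.
    """
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    data = rec.samples.copy()
    nyq = rec.fs / 2
    for k in range(1, spec.notch_harmonics + 1):
        f = k * spec.notch_hz
        if f >= nyq:
            break
        b, a = sps.iirnotch(f, Q=30.0, fs=rec.fs)
        data = sps.filtfilt(b, a, data, axis=1)
    numtaps = int(np.ceil(3.3 * rec.fs / spec.transition_hz)) | 1  # Hamming rule
    taps = sps.firwin(
        numtaps,
        [spec.band_lo_hz, spec.band_hi_hz],
        pass_zero=False,
        window="hamming",
        fs=rec.fs,
    )
    padlen = min(3 * (numtaps - 1), rec.n_samples - 1)
    data = sps.filtfilt(taps, [1.0], data, axis=1, padlen=padlen)
    return replace(rec, samples=data)


def windowed_power(rec: Recording, window_len: int = 24) -> PowerTrace:
    """Mean squared amplitude over consecutive non-overlapping windows.

    The window count is ``ceil(n_samples / N)``; the final partial window
    averages over its actual length, so a 4 s clip at 1 kHz with N = 24
    yields 167 windows.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    n_win = int(np.ceil(rec.n_samples / window_len))
    sq = rec.samples ** 2
    values = np.empty((len(rec.channels), n_win))
    for w in range(n_win):
        seg = sq[:, w * window_len : (w + 1) * window_len]
        values[:, w] = seg.mean(axis=1)
    return PowerTrace(values, list(rec.channels), window_len, rec.fs)


def minmax_normalize(trace: PowerTrace) -> PowerTrace:
    """Single global affine map across all contacts and windows onto [0, 1].

    A degenerate all-equal trace maps to all zeros with a warning.
    """
    if trace.normalized:
        raise ValueError("trace is already normalized")
    lo = trace.values.min()
    hi = trace.values.max()
    if hi == lo:
        warnings.warn("power trace has zero range; normalized to all zeros")
        values = np.zeros_like(trace.values)
    else:
        values = (trace.values - lo) / (hi - lo)
    return replace(trace, values=values, normalized=True)


def match_channels(
    trace: PowerTrace, contact_names: list[str]
) -> tuple[PowerTrace, list[str]]:
    """Restrict a trace to channels matching contact names
    (case-insensitive exact match); returns the matched trace and the list
    of excluded channel names."""
    lookup = {n.lower(): n for n in contact_names}
    keep_idx, keep_names, excluded = [], [], []
    for i, ch in enumerate(trace.channels):
        if ch.lower() in lookup:
            keep_idx.append(i)
            keep_names.append(lookup[ch.lower()])
        else:
            excluded.append(ch)
    matched = replace(trace, values=trace.values[keep_idx], channels=keep_names)
    return matched, excluded
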