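"""Minimal EDF+C writer for multichannel recordings with annotations.

Only what the phantom generator needs: continuous int16-encoded signals at
a common sampling rate, one-second data records, and text annotations in a
dedicated "EDF Annotations" channel.  Files written here are read back
with :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_ANNOT_SAMPLES = 60  # int16 samples reserved per record for annotations


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _tal(onset: float, label: str = "") -> bytes:
    onset_s = f"{onset:+.4f}".rstrip("0").rstrip(".")
    return onset_s.encode("ascii") + b"\x14" + label.encode("ascii") + b"\x14\x00"


def write_edf(
    path: str | Path,
    channel_names: list[str],
    data_uv: np.ndarray,
    fs: float,
    annotations: list[tuple[float, str]] | None = None,
) -> Path:
    """Write an EDF+C file.

    Parameters
    ----------
    data_uv : ndarray, shape (n_channels, n_samples)
        Signals in microvolts. The last record is zero-padded to a whole
        second.
    annotations : list of (onset seconds, label)
    """
    path = Path(path)
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data_uv.shape
    if n_ch != len(channel_names):
        raise ValueError("channel name count does not match data rows")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("fs must be a positive integer for 1 s records")
    spr = int(round(fs))  # samples per record per channel
    n_rec = int(np.ceil(n_samp / spr))
    annotations = sorted(annotations or [])

    # symmetric physical range per channel, digital range full int16
    pmax = np.maximum(np.abs(data_uv).max(axis=1) * 1.05, 1.0)
    pmax = np.round(pmax, 3)
    dig_max, dig_min = 32767, -32768

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(256 * (n_ch + 2), 8),
            _field("EDF+C", 44),
            _field(n_rec, 8),
            _field(1, 8),
            _field(n_ch + 1, 4),
        ]
    )
    labels = [n[:16] for n in channel_names] + ["EDF Annotations"]
    sig = b"".join(_field(lab, 16) for lab in labels)
    sig += b"".join(_field("", 80) for _ in labels)
    sig += b"".join(_field("uV", 8) for _ in channel_names) + _field("", 8)
    sig += b"".join(_field(-p, 8) for p in pmax) + _field(-1, 8)
    sig += b"".join(_field(p, 8) for p in pmax) + _field(1, 8)
    sig += b"".join(_field(dig_min, 8) for _ in labels)
    sig += b"".join(_field(dig_max, 8) for _ in labels)
    sig += b"".join(_field("", 80) for _ in labels)
    sig += b"".join(_field(spr, 8) for _ in channel_names) + _field(_ANNOT_SAMPLES, 8)
    sig += b"".join(_field("", 32) for _ in labels)

    # digitize
    scale = (dig_max - dig_min) / (2 * pmax)
    digital = np.round((data_uv + pmax[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    pad = n_rec * spr - n_samp
    if pad:
        zero_dig = np.round(pmax * scale) + dig_min
        digital = np.concatenate(
            [digital, np.tile(zero_dig.astype("<i2")[:, None], (1, pad))], axis=1
        )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
            tal = _tal(float(r))
            for onset, label in annotations:
                if r <= onset < r + 1:
                    tal += _tal(onset, label)
            annot_bytes = tal.ljust(2 * _ANNOT_SAMPLES, b"\x00")
            if len(annot_bytes) > 2 * _ANNOT_SAMPLES:
                raise ValueError("annotation record overflow")
            fh.write(annot_bytes)
    return path
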