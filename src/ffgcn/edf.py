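"""Minimal EDF+C writer for synthetic multichannel fixtures.

Writes standard-conformant European Data Format files: 16-bit samples,
one-second data records, and one "EDF Annotations" channel carrying
time-stamped annotation lists (TALs) that mark trial onsets, durations
and class labels (descriptions ``T0``..``T{C-1}``).  Reading goes
through mne's native EDF reader, which doubles as the independent
check that these files conform to the format.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _annotation_payloads(n_records: int, onsets, durations, labels) -> list[bytes]:
    """Per-record TAL byte strings (events attached to their start record)."""
    per_rec: list[bytes] = []
    for rec in range(n_records):
        tal = f"+{rec}\x14\x14\x00".encode("ascii")  # record timestamp TAL
        for onset, dur, lab in zip(onsets, durations, labels):
            if rec == int(onset):  # attach each event once
                tal += (f"+{onset:g}\x15{dur:g}\x14T{lab}\x14\x00"
                        .encode("ascii"))
        per_rec.append(tal)
    return per_rec


def write_edf(path, signals: np.ndarray, channel_names: list[str],
              sampling_rate: float, trial_onsets, trial_durations,
              trial_labels, physical_dim: str = "uV") -> None:
    """Write one continuous multichannel block with trial annotations.

    signals: (n_channels, n_samples) in physical units; trial onsets and
    durations in seconds.  The signal is zero-padded to a whole number
    of one-second records.  Quantization is 16-bit over the data's
    symmetric physical range.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[0] != len(channel_names):
        raise ValueError("signals must be (n_channels, n_samples) matching names")
    fs = int(round(sampling_rate))
    if abs(fs - sampling_rate) > 1e-9:
        raise ValueError("sampling_rate must be an integer number of Hz")
    n_ch, n_samp = signals.shape
    n_records = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = signals

    peak = float(np.max(np.abs(padded)))
    phys = max(peak, 1e-6)
    scale = (2 * phys) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((padded + phys) / scale + _DIG_MIN).astype("<i2")

    tals = _annotation_payloads(n_records, trial_onsets, trial_durations,
                                trial_labels)
    ann_len = max(len(t) for t in tals)
    ann_len += ann_len % 2  # samples are 2-byte
    ann_samples = ann_len // 2

    ns = n_ch + 1
    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate 01-JAN-2000 X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (ns + 1)), 8),
        _field("EDF+C", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(ns), 4),
    ])
    labels = [*(ch[:16] for ch in channel_names), "EDF Annotations"]
    per_sig = [
        (labels, 16),
        ([""] * ns, 80),
        ([physical_dim] * n_ch + [""], 8),
        ([f"{-phys:.6g}"[:8]] * n_ch + ["-1"], 8),
        ([f"{phys:.6g}"[:8]] * n_ch + ["1"], 8),
        ([str(_DIG_MIN)] * ns, 8),
        ([str(_DIG_MAX)] * ns, 8),
        ([""] * ns, 80),
        ([str(fs)] * n_ch + [str(ann_samples)], 8),
        ([""] * ns, 32),
    ]
    for values, width in per_sig:
        header += b"".join(_field(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch, rec * fs:(rec + 1) * fs].tobytes())
            fh.write(tals[rec].ljust(ann_len, b"\x00"))
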