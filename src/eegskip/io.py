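"""Session I/O: EDF+ signals with a JSON event sidecar.

``write_session`` stores the continuous signals as 16-bit EDF+ (one 1 s
data record per second, per-channel physical scaling, a TAL annotation
channel mirroring the trial events) next to a JSON sidecar that carries
the subject id, exact sample count and the full trial/response table.
``read_session`` reads the signals back through ``mne.io.read_raw_edf``;
the JSON sidecar is the source of truth for trial events and labels.

Amplitudes are quantized by the 16-bit container: the round-trip error is
bounded by half the per-channel quantization step
``(phys_max - phys_min) / (2^16 - 1)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import FormatError
from .session import REQUIRED_CHANNELS, Session, TrialEvent

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def _num(value, width: int) -> bytes:
    s = f"{value:.10g}"[:width]
    return _fixed(s, width)


def _annotation_records(s: Session, n_records: int) -> list[bytes]:
    """Per-record TAL byte blocks mirroring the trial events."""
    events: list[tuple[float, str]] = []
    for k, t in enumerate(s.trials):
        events.append((t.baseline_onset / s.fs, f"trial{k} baseline"))
        events.append((
            t.video_onset / s.fs,
            f"trial{k} video skipped={int(t.skipped)} "
            f"interested={int(t.interested)} seen={int(t.seen_before)}",
        ))
        events.append((t.end / s.fs, f"trial{k} end"))
    records: list[bytes] = []
    for rec in range(n_records):
        tal = f"+{rec}\x14\x14\x00".encode("ascii")
        for onset, text in events:
            if rec <= onset < rec + 1:
                tal += f"+{onset:.4f}\x14{text}\x14\x00".encode("utf-8")
        records.append(tal)
    return records


def write_session(s: Session, path: str | Path) -> Path:
    """Write a session as ``<path>.edf`` + ``<path>.json`` (sidecar).

    ``path`` may be given with or without the ``.edf`` suffix; the EDF path
    is returned.  The last partial second of data is zero-padded inside the
    container; the sidecar records the true sample count.
    """
    s.validate()
    fs = s.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writing requires an integer sampling rate")
    fs_i = int(round(fs))
    path = Path(path)
    edf_path = path if path.suffix == ".edf" else path.with_suffix(".edf")

    n_ch, n_samples = s.data.shape
    n_records = int(np.ceil(n_samples / fs_i))
    padded = np.zeros((n_ch, n_records * fs_i))
    padded[:, :n_samples] = s.data

    # physical scaling per channel: symmetric range covering the data,
    # quantized with the container's affine convention
    # x = (d - dig_min) * (pmax - pmin)/(dig_max - dig_min) + pmin
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6) * (1 + 1e-9)
    slope = (2 * phys_max) / (_DIG_MAX - _DIG_MIN)
    digital = np.clip(
        np.round((padded + phys_max[:, None]) / slope[:, None]) + _DIG_MIN,
        _DIG_MIN, _DIG_MAX,
    ).astype("<i2")

    ann_records = _annotation_records(s, n_records)
    ann_bytes = max(max(len(r) for r in ann_records) + 2, 16)
    ann_bytes += ann_bytes % 2  # whole number of 2-byte samples
    ann_samples = ann_bytes // 2

    ns = n_ch + 1  # signals + annotation channel
    header = b"".join([
        _fixed("0", 8),
        _fixed(f"X X X {s.subject_id}", 80),
        _fixed("Startdate 01-JAN-2000 X X X", 80),
        _fixed("01.01.00", 8),
        _fixed("00.00.00", 8),
        _num(256 * (ns + 1), 8),
        _fixed("EDF+C", 44),
        _num(n_records, 8),
        _num(1, 8),
        _num(ns, 4),
    ])
    labels = [_fixed(lab, 16) for lab in s.channel_labels]
    labels.append(_fixed("EDF Annotations", 16))
    header += b"".join(labels)
    header += b"".join(_fixed("AgAgCl electrode", 80) for _ in range(n_ch))
    header += _fixed("", 80)
    header += b"".join(_fixed("uV", 8) for _ in range(n_ch)) + _fixed("", 8)
    header += b"".join(_num(-pm, 8) for pm in phys_max) + _num(-1, 8)
    header += b"".join(_num(pm, 8) for pm in phys_max) + _num(1, 8)
    header += b"".join(_num(_DIG_MIN, 8) for _ in range(ns))
    header += b"".join(_num(_DIG_MAX, 8) for _ in range(ns))
    header += b"".join(_fixed("", 80) for _ in range(ns))
    header += b"".join(_num(fs_i, 8) for _ in range(n_ch)) + _num(ann_samples, 8)
    header += b"".join(_fixed("", 32) for _ in range(ns))
    assert len(header) == 256 * (ns + 1)

    with open(edf_path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            sl = slice(rec * fs_i, (rec + 1) * fs_i)
            fh.write(digital[:, sl].tobytes())
            fh.write(ann_records[rec].ljust(ann_bytes, b"\x00"))

    sidecar = {
        "subject_id": s.subject_id,
        "fs": fs,
        "n_samples": int(n_samples),
        "channel_labels": list(s.channel_labels),
        "trials": [
            {
                "baseline_onset": int(t.baseline_onset),
                "video_onset": int(t.video_onset),
                "end": int(t.end),
                "skipped": bool(t.skipped),
                "interested": bool(t.interested),
                "seen_before": bool(t.seen_before),
            }
            for t in s.trials
        ],
    }
    with open(edf_path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return edf_path


def read_session(path: str | Path) -> Session:
    """Read a session written by :func:`write_session` (or any conformant
    EDF with the JSON event sidecar).

    Raises :class:`FormatError` when the sidecar is missing or the file
    lacks one of the required channels (TP9, TP10, F3, F4).
    """
    import mne

    path = Path(path)
    edf_path = path if path.suffix == ".edf" else path.with_suffix(".edf")
    sidecar_path = edf_path.with_suffix(".json")
    if not edf_path.exists():
        raise FormatError(f"no such EDF file: {edf_path}")
    if not sidecar_path.exists():
        raise FormatError(f"missing event sidecar: {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    missing = [c for c in REQUIRED_CHANNELS if c not in raw.ch_names]
    if missing:
        raise FormatError(f"EDF file lacks required channels: {missing}")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    n_samples = int(meta["n_samples"])
    session = Session(
        subject_id=meta["subject_id"],
        fs=float(meta["fs"]),
        channel_labels=tuple(raw.ch_names),
        data=data_uv[:, :n_samples],
        trials=[TrialEvent(**t) for t in meta["trials"]],
    )
    session.validate()
    return session
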