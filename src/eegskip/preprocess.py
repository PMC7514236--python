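"""Preprocessing: linked-mastoid re-referencing, baseline correction,
epoching, band filtering, downsampling, scalp averaging, band power.

The fixed stage order is: rereference -> baseline_correct -> make_epochs ->
bandpass -> downsample.  Filtering is zero-phase (forward-backward 4th-order
Butterworth), so the three band series stay time-aligned.  All amplitudes
are in µV; sample indexing is 0-based and half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import PreprocessingError
from .session import Session, TrialEvent

TARGET_FS = 500.0


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float


#: The three analysis bands. Mu (8–13 Hz) coincides with the alpha range
#: and serves as the alpha signal in the arousal/valence indices.
BANDS: dict[str, Band] = {
    "theta": Band("theta", 4.0, 7.0),
    "mu": Band("mu", 8.0, 13.0),
    "beta": Band("beta", 14.0, 35.0),
}


@dataclass
class BandEpochSet:
    """Non-overlapping fixed-length epochs of one band-filtered signal.

    ``source`` is one of ``scalp_average``, ``F3``, ``F4``; ``epochs`` is
    an (n_epochs, n_samples) matrix at ``fs`` (500 Hz after downsampling).
    """

    band: Band
    source: str
    epoch_len_s: float
    fs: float
    epochs: np.ndarray
    trial_index: int = -1


def rereference(s: Session) -> Session:
    """Subtract the mastoid average 0.5*(TP9+TP10) from every channel.

    Returns a new Session; the input is left unmodified.
    """
    for ch in ("TP9", "TP10"):
        if ch not in s.channel_labels:
            raise PreprocessingError(f"mastoid channel {ch} missing")
    ref = 0.5 * (s.channel("TP9") + s.channel("TP10"))
    return replace(s, data=s.data - ref[None, :])


def baseline_correct(s: Session, t: TrialEvent) -> np.ndarray:
    """Viewing segment [video_onset, end) with the per-channel mean of the
    trial's baseline window subtracted."""
    if t.baseline_onset < 0 or t.video_onset > s.data.shape[1]:
        raise PreprocessingError("baseline window outside recorded data")
    baseline = s.data[:, t.baseline_onset:t.video_onset]
    if baseline.shape[1] == 0:
        raise PreprocessingError("empty baseline window")
    segment = s.data[:, t.video_onset:t.end]
    return segment - baseline.mean(axis=1, keepdims=True)


def make_epochs(segment: np.ndarray, fs: float, epoch_len_s: float) -> np.ndarray:
    """Cut a 1-D signal into contiguous non-overlapping epochs from its
    start; trailing samples shorter than one epoch are dropped.

    Returns an (n_epochs, epoch_len_s*fs) matrix.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 1:
        raise ValueError("make_epochs expects a 1-D signal")
    n_ep_samples = int(round(epoch_len_s * fs))
    n_epochs = segment.size // n_ep_samples
    if n_epochs < 1:
        raise PreprocessingError(
            f"segment of {segment.size} samples shorter than one "
            f"{epoch_len_s} s epoch at fs={fs}"
        )
    return segment[: n_epochs * n_ep_samples].reshape(n_epochs, n_ep_samples)


def bandpass(epochs: np.ndarray, band: Band, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if fs <= 2 * band.hi:
        raise PreprocessingError(
            f"fs={fs} too low for band {band.name} ({band.lo}-{band.hi} Hz)"
        )
    sos = signal.butter(order, [band.lo, band.hi], btype="bandpass", fs=fs,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(epochs, dtype=np.float64), axis=-1)


def downsample(epochs: np.ndarray, fs_in: float, fs_out: float = TARGET_FS) -> np.ndarray:
    """Decimate band-limited epochs to ``fs_out`` by integer-stride picking.

    The signals are band-passed below 35 Hz first, so at 500 Hz output no
    aliasing is possible and no extra anti-alias filter is applied.
    """
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise PreprocessingError(
            f"fs_in={fs_in} must be a positive integer multiple of fs_out={fs_out}"
        )
    step = int(round(ratio))
    return np.asarray(epochs)[..., ::step]


def scalp_average(epochs: np.ndarray) -> np.ndarray:
    """Sample-wise mean over the channel axis (axis 0)."""
    epochs = np.asarray(epochs)
    if epochs.size == 0:
        raise PreprocessingError("no channels to average")
    return epochs.mean(axis=0)


def band_power(epoch: np.ndarray) -> float | np.ndarray:
    """Mean squared amplitude (µV²) of a band-filtered epoch.

    For a 2-D (n_epochs, n_samples) input, returns the per-epoch powers.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    return np.mean(epoch**2, axis=-1)


@dataclass
class TrialEpochs:
    """All band/source epoch sets of one trial, ready for the feature stage.

    ``entropy`` holds 1 s epoch matrices keyed by (band, source);
    ``power`` holds per-epoch band powers (0.5 s epochs) keyed likewise.
    Sources: ``scalp_average`` (mastoids excluded), ``F3``, ``F4``.
    """

    trial_index: int
    event: TrialEvent
    entropy: dict[tuple[str, str], np.ndarray]
    power: dict[tuple[str, str], np.ndarray]
    fs: float = TARGET_FS


def preprocess_session(
    s: Session,
    entropy_epoch_s: float = 1.0,
    power_epoch_s: float = 0.5,
    include_mastoids_in_average: bool = False,
    reject_uv: float | None = None,
) -> tuple[list[TrialEpochs], list[dict]]:
    """Run the full preprocessing chain on one session.

    Returns ``(trials, exclusions)``: the per-trial band epoch data and a
    log of trials that were excluded (too short for a single epoch).
    ``reject_uv``, when set, drops epochs whose absolute amplitude exceeds
    the threshold anywhere (simple artifact-rejection hook, default off).
    """
    ref = rereference(s)
    labels = list(ref.channel_labels)
    mastoids = {"TP9", "TP10"}
    avg_idx = [
        i for i, lab in enumerate(labels)
        if include_mastoids_in_average or lab not in mastoids
    ]
    f3, f4 = labels.index("F3"), labels.index("F4")

    out: list[TrialEpochs] = []
    exclusions: list[dict] = []
    for k, t in enumerate(ref.trials):
        segment = baseline_correct(ref, t)
        sources = {
            "scalp_average": scalp_average(segment[avg_idx]),
            "F3": segment[f3],
            "F4": segment[f4],
        }
        entropy_sets: dict[tuple[str, str], np.ndarray] = {}
        power_sets: dict[tuple[str, str], np.ndarray] = {}
        try:
            for src_name, sig in sources.items():
                ent_epochs = make_epochs(sig, ref.fs, entropy_epoch_s)
                pow_epochs = make_epochs(sig, ref.fs, power_epoch_s)
                for band in BANDS.values():
                    ent = downsample(bandpass(ent_epochs, band, ref.fs), ref.fs)
                    pwr = downsample(bandpass(pow_epochs, band, ref.fs), ref.fs)
                    if reject_uv is not None:
                        ent = ent[np.max(np.abs(ent), axis=-1) <= reject_uv]
                        pwr = pwr[np.max(np.abs(pwr), axis=-1) <= reject_uv]
                    entropy_sets[(band.name, src_name)] = ent
                    power_sets[(band.name, src_name)] = band_power(pwr)
        except PreprocessingError as exc:
            exclusions.append({"trial": k, "reason": "too_short", "detail": str(exc)})
            continue
        out.append(TrialEpochs(trial_index=k, event=t, entropy=entropy_sets,
                               power=power_sets))
    return out, exclusions
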