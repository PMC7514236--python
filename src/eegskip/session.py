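"""In-memory containers for one participant's recording session."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: 32-channel 10–20 montage (easycap-style layout). Includes the linked
#: mastoids TP9/TP10 used for re-referencing and the frontal pair F3/F4
#: used for the arousal/valence indices.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

REQUIRED_CHANNELS = ("TP9", "TP10", "F3", "F4")


@dataclass
class TrialEvent:
    """Sample-index markers and responses for one video trial.

    Indices are 0-based; spans are half-open ``[start, stop)``. ``end`` is
    the button press for skipped trials and the natural video end otherwise.
    """

    baseline_onset: int
    video_onset: int
    end: int
    skipped: bool
    interested: bool
    seen_before: bool = False

    def validate(self) -> None:
        if not self.baseline_onset < self.video_onset < self.end:
            raise ConfigurationError(
                f"trial markers must be ordered: {self.baseline_onset} < "
                f"{self.video_onset} < {self.end}"
            )


@dataclass
class Session:
    """Continuous multichannel EEG (µV) plus trial events for one subject.

    ``internals`` carries generator-side diagnostics (per-trial envelope
    statistics) for synthetic sessions; it is not persisted by session I/O.
    """

    subject_id: str
    fs: float
    channel_labels: tuple[str, ...]
    data: np.ndarray  # channels x samples, µV
    trials: list[TrialEvent]
    internals: dict = field(default_factory=dict, repr=False, compare=False)

    def validate(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel labels must be unique")
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channel_labels]
        if missing:
            raise ConfigurationError(f"missing required channels: {missing}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ConfigurationError("data must be channels x samples")
        n = self.data.shape[1]
        prev_end = -1
        for t in self.trials:
            t.validate()
            if t.baseline_onset <= prev_end:
                raise ConfigurationError("trial windows must not overlap")
            if t.end > n:
                raise ConfigurationError("trial extends beyond recorded data")
            prev_end = t.end - 1

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's full time series by 10–20 label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ConfigurationError(f"no channel {label!r} in session") from None
        return self.data[idx]
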