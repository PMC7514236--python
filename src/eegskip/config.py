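"""Configuration objects for simulation, evaluation and pipeline runs.

All configurations are plain dataclasses with a ``validate()`` method that
raises :class:`~eegskip.errors.ConfigurationError`, and can be loaded from
YAML mappings (unknown keys are rejected so typos fail loudly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

#: Highest band edge processed by the pipeline (beta band upper edge, Hz).
BETA_EDGE_HZ = 35.0


@dataclass
class NoiseConfig:
    """Amplitudes (µV) of the band-limited sources and the 1/f background.

    ``band_amp`` sets the RMS of each narrowband oscillatory source before
    envelope modulation; ``background_amp`` the RMS of the per-channel pink
    (1/f) background; ``mastoid_gain`` scales the background on the
    reference mastoids (TP9/TP10), which carry no oscillatory sources;
    ``envelope_relvar`` is the baseline relative variance of the log-normal
    amplitude envelope; ``envelope_tau_s`` its correlation time constant.
    """

    band_amp: dict[str, float] = field(
        default_factory=lambda: {"theta": 6.0, "mu": 5.0, "beta": 4.0}
    )
    background_amp: float = 6.0
    common_background_amp: float = 3.0
    mastoid_gain: float = 0.3
    envelope_relvar: float = 0.15
    envelope_tau_s: float = 1.0

    def validate(self) -> None:
        if set(self.band_amp) != {"theta", "mu", "beta"}:
            raise ConfigurationError(
                f"band_amp must have keys theta/mu/beta, got {sorted(self.band_amp)}"
            )
        if any(a <= 0 for a in self.band_amp.values()):
            raise ConfigurationError("band amplitudes must be positive")
        if self.common_background_amp < 0:
            raise ConfigurationError("common_background_amp must be >= 0")
        if self.background_amp < 0 or self.mastoid_gain < 0:
            raise ConfigurationError("background_amp and mastoid_gain must be >= 0")
        if self.envelope_relvar <= 0 or self.envelope_tau_s <= 0:
            raise ConfigurationError("envelope parameters must be positive")


@dataclass
class SimConfig:
    """Design of a synthetic viewing experiment.

    Defaults mirror the experimental design being emulated: 45 videos per
    subject, 32 channels in the 10–20 layout, a 3 s fixation baseline before
    each video. ``fs=500`` is the desk-scale rate; ``fs=2000`` reproduces
    the acquisition rate and exercises the downsampling stage.
    ``effect_size`` >= 0 controls the class-dependent modulation: the
    beta-band envelope variance of not-skipped trials is scaled by
    (1 + effect_size), and an F4-vs-F3 mu/beta asymmetry proportional to
    effect_size is injected for interested trials.
    """

    n_subjects: int = 4
    n_videos_per_subject: int = 45
    fs: float = 500.0
    n_channels: int = 32
    baseline_s: float = 3.0
    video_len_s: float = 20.0
    gap_s: float = 1.0
    skip_rate: float = 0.5
    interest_rate: float = 0.5
    interest_skip_dependence: float = 0.6
    effect_size: float = 0.0
    asymmetry_gain: float = 0.15
    truncate_skipped: bool = True
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_videos_per_subject < 1:
            raise ConfigurationError("n_videos_per_subject must be >= 1")
        if self.fs <= 2 * BETA_EDGE_HZ:
            raise ConfigurationError(
                f"fs={self.fs} must exceed {2 * BETA_EDGE_HZ} Hz "
                f"(2x the {BETA_EDGE_HZ} Hz beta band edge)"
            )
        if self.n_channels != 32:
            raise ConfigurationError("only the 32-channel 10-20 layout is supported")
        if self.baseline_s <= 0:
            raise ConfigurationError("baseline_s must be positive")
        if self.video_len_s <= 0 or self.gap_s < 0:
            raise ConfigurationError("video_len_s must be > 0 and gap_s >= 0")
        for name, rate in (("skip_rate", self.skip_rate), ("interest_rate", self.interest_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name}={rate} must be in [0, 1]")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not 0.0 <= self.interest_skip_dependence <= 1.0:
            raise ConfigurationError("interest_skip_dependence must be in [0, 1]")
        self.noise.validate()


@dataclass
class FeatureConfig:
    """Feature-extraction knobs.

    ``cv_window`` is the length (in 1 s epochs) of the sliding window over
    which the coefficient of variation of the band-entropy series is taken;
    the RCV* features are the max-minus-min of the resulting CV series.
    ``m`` and ``r_factor`` parameterize sample entropy; ``tau_max`` the
    number of coarse-graining scales averaged into the entropy measure.
    ``peak_factor`` is the supra-mean threshold for CV2 peak detection.
    ``cv_across_scales`` switches the RCV features to the alternative
    reading of the CV (across MSE scales within each epoch).
    """

    m: int = 2
    r_factor: float = 0.15
    tau_max: int = 10
    cv_window: int = 5
    peak_factor: float = 2.5
    cv_across_scales: bool = False
    power_epoch_s: float = 0.5
    entropy_epoch_s: float = 1.0

    def validate(self) -> None:
        if self.m < 1:
            raise ConfigurationError("m must be >= 1")
        if self.r_factor <= 0:
            raise ConfigurationError("r_factor must be positive")
        if self.tau_max < 1:
            raise ConfigurationError("tau_max must be >= 1")
        if self.cv_window < 2:
            raise ConfigurationError("cv_window must be >= 2")
        if self.peak_factor <= 0:
            raise ConfigurationError("peak_factor must be positive")


@dataclass
class EvalConfig:
    """Classifier and validation-protocol settings."""

    classifier: str = "knn"
    task: str = "skip"
    knn_k: int = 10
    svm_c: float = 1.0
    rf_trees: int = 100
    holdout_frac: float = 0.1
    holdout_reps: int = 500
    wilcoxon_alpha: float = 0.05
    n_features_for_bonferroni: int = 9
    standardize: bool = True
    stratify_holdout: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.classifier not in {"svm", "knn", "rf"}:
            raise ConfigurationError(f"unknown classifier {self.classifier!r}")
        if self.task not in {"skip", "interest"}:
            raise ConfigurationError(f"unknown task {self.task!r}")
        if not 0.0 < self.holdout_frac < 1.0:
            raise ConfigurationError("holdout_frac must be in (0, 1)")
        if self.holdout_reps < 1:
            raise ConfigurationError("holdout_reps must be >= 1")
        if self.knn_k < 1:
            raise ConfigurationError("knn_k must be >= 1")
        if self.wilcoxon_alpha <= 0 or self.wilcoxon_alpha >= 1:
            raise ConfigurationError("wilcoxon_alpha must be in (0, 1)")

    @property
    def bonferroni_threshold(self) -> float:
        return self.wilcoxon_alpha / self.n_features_for_bonferroni


def _from_mapping(cls: type, data: dict[str, Any]):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    if cls is SimConfig and isinstance(kwargs.get("noise"), dict):
        kwargs["noise"] = NoiseConfig(**kwargs["noise"])
    return cls(**kwargs)


def sim_config_from_yaml(path: str | Path) -> SimConfig:
    """Load and validate a :class:`SimConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_mapping(SimConfig, data)
    cfg.validate()
    return cfg


def eval_config_from_yaml(path: str | Path) -> EvalConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_mapping(EvalConfig, data)
    cfg.validate()
    return cfg


def config_to_dict(cfg) -> dict[str, Any]:
    """Serialize any of the config dataclasses to a plain dict (for manifests)."""
    return asdict(cfg)
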