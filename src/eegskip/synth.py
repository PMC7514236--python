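"""Synthetic EEG viewing sessions with controllable class effects.

Each session emulates one participant watching a sequence of short videos:
a 3 s fixation baseline precedes each video, the video is either watched in
full or skipped early by a button press, and two binary responses (interest,
seen-before) are recorded afterwards.

The signal model sums, per trial and per frequency band (theta, mu, beta),
a narrowband oscillatory source modulated by a slowly varying log-normal
amplitude envelope, on top of a 1/f (pink) background.  Two class effects
can be injected, both scaled by ``effect_size``:

* **skip effect** — the relative variance of the beta-band envelope is
  multiplied by ``1 + effect_size`` for trials that are *not* skipped, so
  not-skipped trials show larger fluctuations of band complexity and power;
* **interest effect** — for interested trials the mu- and beta-band
  amplitudes at F4 and F3 are modulated in opposite directions by a slow
  process whose depth is proportional to ``effect_size``, producing a
  fluctuating frontal asymmetry.

With ``effect_size=0`` the labels have no influence on the signal, so the
two classes are statistically exchangeable (up to trial length, which is
shorter for skipped trials by design of the experiment).
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy import signal

from .config import SimConfig
from .errors import ConfigurationError
from .session import CHANNELS_32, Session, TrialEvent

#: Narrow sub-bands (Hz) of the oscillatory sources, inside the analysis
#: bands theta 4–7, mu 8–13, beta 14–35.
NARROW_BANDS = {"theta": (5.0, 6.5), "mu": (9.0, 12.0), "beta": (17.0, 25.0)}

# Kasdin-style 1/f shaping filter (pole-zero approximation to pink noise).
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


def _subject_seed(seed: int, subject_id: str) -> np.random.SeedSequence:
    """Deterministic, platform-independent seed for one subject."""
    return np.random.SeedSequence([seed, zlib.crc32(subject_id.encode())])


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-std pink (1/f) noise of length n."""
    x = signal.lfilter(_PINK_B, _PINK_A, rng.standard_normal(n))
    return x / x.std()


def _ou_process(rng: np.random.Generator, n: int, fs: float, tau_s: float) -> np.ndarray:
    """Stationary unit-variance Ornstein–Uhlenbeck process sampled at fs."""
    a = np.exp(-1.0 / (tau_s * fs))
    eps = rng.standard_normal(n) * np.sqrt(1.0 - a * a)
    z = signal.lfilter([1.0], [1.0, -a], eps, zi=np.array([a * rng.standard_normal()]))[0]
    return z


def _lognormal_envelope(z: np.ndarray, relvar: float) -> np.ndarray:
    """Positive envelope with unit mean and relative variance ``relvar``.

    e = exp(mu*z - mu^2/2) with mu chosen so Var(e)/E(e)^2 = relvar exactly
    for standard-normal z.
    """
    mu = np.sqrt(np.log1p(relvar))
    return np.exp(mu * z - 0.5 * mu * mu)


def _narrow_source(rng: np.random.Generator, n: int, band: str, fs: float) -> np.ndarray:
    lo, hi = NARROW_BANDS[band]
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # pad so filter transients do not bias the first samples
    pad = int(fs)
    x = signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    return x / x.std()


def generate_session(cfg: SimConfig, subject_id: str) -> Session:
    """Simulate one subject's full recording session.

    Deterministic in ``(cfg, subject_id)``.  Per-trial generator
    diagnostics (beta envelope relative std, labels) are stored in
    ``Session.internals`` for validation of the injected effects; they are
    not part of the persisted session.
    """
    cfg.validate()
    rng = np.random.default_rng(_subject_seed(cfg.seed, subject_id))

    fs = cfg.fs
    n_base = int(round(cfg.baseline_s * fs))
    n_video_full = int(round(cfg.video_len_s * fs))
    n_gap = int(round(cfg.gap_s * fs))
    labels = list(CHANNELS_32)
    mastoid_idx = [labels.index("TP9"), labels.index("TP10")]
    f3_idx, f4_idx = labels.index("F3"), labels.index("F4")
    scalp_idx = [i for i in range(len(labels)) if i not in mastoid_idx]

    # --- trial design -----------------------------------------------------
    trials_meta = []
    for _ in range(cfg.n_videos_per_subject):
        skipped = rng.random() < cfg.skip_rate
        p_int = cfg.interest_rate + cfg.interest_skip_dependence * (
            -0.5 if skipped else 0.5
        )
        interested = rng.random() < min(1.0, max(0.0, p_int))
        seen = rng.random() < 0.2
        if skipped:
            # button press uniformly at 30-90% of the video; the
            # truncate_skipped=False diagnostic mode keeps the skip label
            # but watches the video in full (length-matched control for
            # studying what trial duration alone contributes downstream)
            frac = rng.uniform(0.3, 0.9)
            n_watch = int(round(frac * n_video_full)) if cfg.truncate_skipped \
                else n_video_full
        else:
            n_watch = n_video_full
        trials_meta.append((skipped, interested, seen, n_watch))

    n_total = sum(n_base + n_watch + n_gap for *_, n_watch in trials_meta)
    data = np.zeros((len(labels), n_total))

    # --- backgrounds ------------------------------------------------------
    noise = cfg.noise
    common_bg = noise.common_background_amp * _pink_noise(rng, n_total)
    for i in range(len(labels)):
        gain = noise.mastoid_gain if i in mastoid_idx else 1.0
        data[i] = gain * (noise.background_amp * _pink_noise(rng, n_total) + common_bg)

    # fixed per-channel gain jitter of the oscillatory sources
    band_names = ("theta", "mu", "beta")
    ch_gain = {b: 1.0 + 0.1 * rng.standard_normal(len(labels)) for b in band_names}

    # --- per-trial oscillatory content ------------------------------------
    eta = cfg.asymmetry_gain * cfg.effect_size
    env_relstd_beta, trial_events = [], []
    cursor = 0
    for skipped, interested, seen, n_watch in trials_meta:
        n_trial = n_base + n_watch
        start, end = cursor, cursor + n_trial
        asym = _ou_process(rng, n_trial, fs, noise.envelope_tau_s)
        for band in band_names:
            relvar = noise.envelope_relvar
            if band == "beta" and not skipped:
                relvar = relvar * (1.0 + cfg.effect_size)
            env = _lognormal_envelope(
                _ou_process(rng, n_trial, fs, noise.envelope_tau_s), relvar
            )
            comp = noise.band_amp[band] * env * _narrow_source(rng, n_trial, band, fs)
            if band == "beta":
                env_relstd_beta.append(env.std() / env.mean())
            for i in scalp_idx:
                if i in (f3_idx, f4_idx) and band in ("mu", "beta") and interested:
                    f = np.exp((eta if i == f4_idx else -eta) * asym - 0.5 * eta * eta)
                    data[i, start:end] += ch_gain[band][i] * f * comp
                else:
                    data[i, start:end] += ch_gain[band][i] * comp
        trial_events.append(
            TrialEvent(
                baseline_onset=start,
                video_onset=start + n_base,
                end=end,
                skipped=bool(skipped),
                interested=bool(interested),
                seen_before=bool(seen),
            )
        )
        cursor = end + n_gap

    session = Session(
        subject_id=subject_id,
        fs=fs,
        channel_labels=tuple(labels),
        data=data,
        trials=trial_events,
        internals={
            "beta_env_relstd": np.asarray(env_relstd_beta),
            "skipped": np.array([t.skipped for t in trial_events]),
            "interested": np.array([t.interested for t in trial_events]),
            "asymmetry_eta": eta,
        },
    )
    session.validate()
    return session


def subject_ids(cfg: SimConfig) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(cfg.n_subjects)]


def generate_cohort(cfg: SimConfig) -> list[Session]:
    """Simulate every subject of the design.  Requires >= 2 subjects
    (leave-one-subject-out validation is undefined otherwise)."""
    cfg.validate()
    if cfg.n_subjects < 2:
        raise ConfigurationError("a cohort needs n_subjects >= 2")
    return [generate_session(cfg, sid) for sid in subject_ids(cfg)]


def iter_cohort(cfg: SimConfig):
    """Lazily yield the cohort's sessions one at a time (memory-friendly
    for long recordings); same sessions as :func:`generate_cohort`."""
    cfg.validate()
    if cfg.n_subjects < 2:
        raise ConfigurationError("a cohort needs n_subjects >= 2")
    for sid in subject_ids(cfg):
        yield generate_session(cfg, sid)
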