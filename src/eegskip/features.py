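"""Engagement/arousal/valence indices and the nine trial-level features.

Index definitions (per epoch), with Beta/Mu/Theta either band power
(0.5 s epochs) or band entropy (1 s epochs); mu serves as alpha:

    engagement = Beta / (Mu + Theta)                       (scalp average)
    arousal    = (BetaF3 + BetaF4) / (AlphaF3 + AlphaF4)   (frontal pair)
    valence    = AlphaF4/BetaF4 - AlphaF3/BetaF3           (frontal pair)

Trial features (labels: +1 = not skipped / interested, -1 otherwise):

* RCVB/RCVM/RCVT — range (max-min) of the sliding-window coefficient of
  variation of the per-epoch scale-averaged band entropy (beta/mu/theta,
  scalp-averaged signal);
* REEI/REAI/REVI — range of the entropy-based engagement/arousal/valence
  index series;
* CV2EI/CV2AI/CV2VI — CV2 statistic (mean contrasted difference of
  successive supra-threshold peaks) of the power-based index series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FeatureConfig
from .entropy import batch_multiscale_entropy
from .errors import DegenerateInputError, EvaluationError, LengthError
from .preprocess import TrialEpochs

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "RCVB", "RCVM", "RCVT", "REEI", "REAI", "REVI", "CV2EI", "CV2AI", "CV2VI",
)

#: Column order of the feature table CSV.
TABLE_COLUMNS = ("subject_id", "trial_id", *FEATURE_NAMES, "label_skip",
                 "label_interest")


# --------------------------------------------------------------------------
# index arithmetic
# --------------------------------------------------------------------------

def engagement_index(beta, mu, theta):
    """Beta over mu+theta (power or entropy). Denominator must be > 0."""
    beta, mu, theta = (np.asarray(v, dtype=float) for v in (beta, mu, theta))
    denom = mu + theta
    if np.any(denom <= 0):
        raise DegenerateInputError("mu + theta must be positive")
    return beta / denom


def arousal_index(beta_f3, beta_f4, alpha_f3, alpha_f4):
    """Frontal beta sum over frontal alpha sum. Symmetric in F3<->F4."""
    vals = [np.asarray(v, dtype=float) for v in (beta_f3, beta_f4, alpha_f3, alpha_f4)]
    denom = vals[2] + vals[3]
    if np.any(denom <= 0):
        raise DegenerateInputError("alphaF3 + alphaF4 must be positive")
    return (vals[0] + vals[1]) / denom


def valence_index(alpha_f3, beta_f3, alpha_f4, beta_f4):
    """AlphaF4/BetaF4 - AlphaF3/BetaF3. Antisymmetric in F3<->F4."""
    a3, b3, a4, b4 = (np.asarray(v, dtype=float)
                      for v in (alpha_f3, beta_f3, alpha_f4, beta_f4))
    if np.any(b3 <= 0) or np.any(b4 <= 0):
        raise DegenerateInputError("frontal beta values must be positive")
    return a4 / b4 - a3 / b3


# --------------------------------------------------------------------------
# variability statistics
# --------------------------------------------------------------------------

def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) over the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise LengthError("CV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise DegenerateInputError("zero-mean series has no CV")
    return float(values.std(ddof=1) / mean)


def range_of(values) -> float:
    """max - min; 0 for a single value."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise LengthError("range of an empty series is undefined")
    return float(values.max() - values.min())


def detect_peaks(values, factor: float = 2.5) -> np.ndarray:
    """Strict local maxima exceeding ``factor`` times the series mean.

    Endpoints are ineligible; peaks are returned in temporal order.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise LengthError("peak detection needs at least 3 values")
    mid = values[1:-1]
    is_peak = (mid > values[:-2]) & (mid > values[2:]) & (mid > factor * values.mean())
    return mid[is_peak]


def cv2_statistic(values, factor: float = 2.5) -> float:
    """Mean contrasted difference of successive supra-threshold peaks:

        CV2 = 1/(n-1) * sum_i 2*|p_{i+1} - p_i| / (p_{i+1} + p_i)

    Returns 0 with fewer than two peaks (no variability evidence).  Peak
    pairs summing to zero (possible for sign-changing indices such as
    valence) contribute no term and shrink n accordingly.
    """
    peaks = detect_peaks(values, factor=factor)
    if peaks.size < 2:
        return 0.0
    p0, p1 = peaks[:-1], peaks[1:]
    keep = (p0 + p1) != 0
    if np.count_nonzero(keep) == 0:
        return 0.0
    terms = 2.0 * np.abs(p1[keep] - p0[keep]) / (p1[keep] + p0[keep])
    return float(terms.sum() / terms.size)


def sliding_cv(values, window: int) -> np.ndarray:
    """CV over a sliding window (stride 1) along an epoch series."""
    values = np.asarray(values, dtype=float)
    if values.size < window:
        raise LengthError(f"need >= {window} epochs for the CV window")
    return np.array([
        coefficient_of_variation(values[i:i + window])
        for i in range(values.size - window + 1)
    ])


# --------------------------------------------------------------------------
# trial-level feature rows
# --------------------------------------------------------------------------

@dataclass
class TrialFeatureData:
    """Intermediate per-trial data: per-epoch, per-scale band entropies and
    per-epoch band powers, retained so features can be recomputed at any
    single MSE scale (per-scale relevance curves)."""

    trial_index: int
    label_skip: int
    label_interest: int
    #: (band, source) -> (n_epochs, tau_max) per-scale entropies
    entropies: dict[tuple[str, str], np.ndarray]
    #: (band, source) -> (n_epochs,) band powers
    powers: dict[tuple[str, str], np.ndarray]
    notes: list[str] = field(default_factory=list)


def compute_trial_entropies(trial: TrialEpochs, cfg: FeatureConfig) -> TrialFeatureData:
    """Run the MSE stage on every band/source epoch set of one trial."""
    entropies = {
        key: batch_multiscale_entropy(ep, m=cfg.m, r_factor=cfg.r_factor,
                                      tau_max=cfg.tau_max)
        for key, ep in trial.entropy.items()
    }
    return TrialFeatureData(
        trial_index=trial.trial_index,
        label_skip=-1 if trial.event.skipped else 1,
        label_interest=1 if trial.event.interested else -1,
        entropies=entropies,
        powers=dict(trial.power),
    )


def _entropy_series(per_scale: np.ndarray, scale: int | None) -> np.ndarray:
    """Per-epoch entropy series: scale-averaged (scale=None) or at one
    scale (1-based).  NaN marks epochs with no finite value."""
    if scale is None:
        all_nan = ~np.isfinite(per_scale).any(axis=1)
        with np.errstate(invalid="ignore"):
            series = np.where(all_nan, np.nan,
                              np.nanmean(np.where(np.isfinite(per_scale),
                                                  per_scale, np.nan), axis=1))
    else:
        series = per_scale[:, scale - 1]
    return series


def build_feature_row(data: TrialFeatureData, cfg: FeatureConfig,
                      scale: int | None = None) -> dict[str, float] | None:
    """The nine features of one trial, or None when the trial is too short
    (< cv_window + 1 usable entropy epochs).

    ``scale`` recomputes the six entropy features at a single MSE scale
    instead of the scale average (the power-based CV2 features do not
    depend on it).
    """
    keys = [(b, s) for b in ("theta", "mu", "beta")
            for s in ("scalp_average", "F3", "F4")]
    ent = {k: _entropy_series(data.entropies[k], scale) for k in keys}
    # keep only epochs where every band/source entropy is defined, so the
    # index arithmetic always pairs values from the same 1 s epoch
    finite = np.logical_and.reduce([np.isfinite(ent[k]) for k in keys])
    n_epochs = int(np.count_nonzero(finite))
    if n_epochs < cfg.cv_window + 1:
        logger.info("trial %d excluded: %d usable entropy epochs < %d",
                    data.trial_index, n_epochs, cfg.cv_window + 1)
        return None
    ent = {k: v[finite] for k, v in ent.items()}

    row: dict[str, float] = {}
    try:
        if cfg.cv_across_scales and scale is None:
            # alternative reading: CV across the tau_max scales within each
            # epoch; the feature is the range of that per-epoch CV series
            for name, band in (("RCVB", "beta"), ("RCVM", "mu"), ("RCVT", "theta")):
                per_scale = data.entropies[(band, "scalp_average")]
                cvs = [coefficient_of_variation(r[np.isfinite(r)])
                       for r in per_scale if np.count_nonzero(np.isfinite(r)) >= 2]
                row[name] = range_of(cvs)
        else:
            for name, band in (("RCVB", "beta"), ("RCVM", "mu"), ("RCVT", "theta")):
                row[name] = range_of(
                    sliding_cv(ent[(band, "scalp_average")], cfg.cv_window))

        row["REEI"] = range_of(engagement_index(
            ent[("beta", "scalp_average")], ent[("mu", "scalp_average")],
            ent[("theta", "scalp_average")]))
        row["REAI"] = range_of(arousal_index(
            ent[("beta", "F3")], ent[("beta", "F4")],
            ent[("mu", "F3")], ent[("mu", "F4")]))
        row["REVI"] = range_of(valence_index(
            ent[("mu", "F3")], ent[("beta", "F3")],
            ent[("mu", "F4")], ent[("beta", "F4")]))

        pw = data.powers
        row["CV2EI"] = cv2_statistic(engagement_index(
            pw[("beta", "scalp_average")], pw[("mu", "scalp_average")],
            pw[("theta", "scalp_average")]), factor=cfg.peak_factor)
        row["CV2AI"] = cv2_statistic(arousal_index(
            pw[("beta", "F3")], pw[("beta", "F4")],
            pw[("mu", "F3")], pw[("mu", "F4")]), factor=cfg.peak_factor)
        row["CV2VI"] = cv2_statistic(valence_index(
            pw[("mu", "F3")], pw[("beta", "F3")],
            pw[("mu", "F4")], pw[("beta", "F4")]), factor=cfg.peak_factor)
    except (DegenerateInputError, LengthError) as exc:
        logger.info("trial %d excluded: %s", data.trial_index, exc)
        return None
    return row


def build_feature_table(subject_id: str, trial_data: list[TrialFeatureData],
                        cfg: FeatureConfig,
                        scale: int | None = None) -> pd.DataFrame:
    """Feature rows of one subject as a DataFrame in the fixed column order.

    Trials that are too short or degenerate are dropped (logged).
    """
    rows = []
    for data in trial_data:
        feats = build_feature_row(data, cfg, scale=scale)
        if feats is None:
            continue
        rows.append({
            "subject_id": subject_id,
            "trial_id": data.trial_index,
            **feats,
            "label_skip": data.label_skip,
            "label_interest": data.label_interest,
        })
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def per_scale_feature_curves(trial_data_by_subject: dict[str, list[TrialFeatureData]],
                             feature_name: str, task: str,
                             cfg: FeatureConfig) -> pd.DataFrame:
    """Class-mean curves of one entropy feature across MSE scales.

    For each scale tau = 1..tau_max the named feature is recomputed with
    the per-epoch entropy at that single scale, then averaged within the
    positive (+1) and negative (-1) class of ``task`` ('skip'/'interest').

    Returns a tidy frame with columns: feature, scale, mean_pos, mean_neg,
    diff (positive minus negative class).
    """
    if feature_name not in ("RCVB", "RCVM", "RCVT", "REEI", "REAI", "REVI"):
        raise EvaluationError(f"{feature_name} is not an entropy feature")
    label_col = "label_skip" if task == "skip" else "label_interest"
    records = []
    for tau in range(1, cfg.tau_max + 1):
        tables = [
            build_feature_table(sid, data, cfg, scale=tau)
            for sid, data in trial_data_by_subject.items()
        ]
        table = pd.concat(tables, ignore_index=True)
        pos = table.loc[table[label_col] == 1, feature_name]
        neg = table.loc[table[label_col] == -1, feature_name]
        if pos.empty or neg.empty:
            raise EvaluationError(f"no {task} trials in one class at scale {tau}")
        records.append({
            "feature": feature_name, "scale": tau,
            "mean_pos": pos.mean(), "mean_neg": neg.mean(),
            "diff": pos.mean() - neg.mean(),
        })
    return pd.DataFrame(records)
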