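"""Classifier training and the two validation protocols.

Three classifiers are supported: a soft-margin linear SVM, a k-nearest
neighbor with city-block distance (k=10), and a 100-tree random forest.
Validation is either leave-one-subject-out (LoSOCV, one fold per subject,
unweighted mean of per-subject accuracies) or a pseudorandom 10% holdout
repeated 500 times over the pooled data of all subjects.  Feature-relevance
analysis retrains each classifier on every single feature and compares the
skip vs. interest accuracy distributions with a Bonferroni-corrected paired
Wilcoxon signed-rank test (alpha = 0.05/9).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import EvalConfig
from .errors import EvaluationError
from .features import FEATURE_NAMES

#: Maximum redraws of a holdout split whose test part misses a class.
MAX_SPLIT_RETRIES = 100


def _label_column(task: str) -> str:
    if task not in ("skip", "interest"):
        raise EvaluationError(f"unknown task {task!r}")
    return f"label_{task}"


def make_classifier(cfg: EvalConfig):
    """Unfitted sklearn estimator for the configured classifier.

    SVM and kNN are wrapped with per-training-fold standardization when
    ``cfg.standardize`` (city-block distances are otherwise dominated by
    the largest-scaled feature); the random forest is scale-invariant and
    left unstandardized.
    """
    if cfg.classifier == "svm":
        est = SVC(kernel="linear", C=cfg.svm_c)
    elif cfg.classifier == "knn":
        est = KNeighborsClassifier(n_neighbors=cfg.knn_k, metric="manhattan")
    elif cfg.classifier == "rf":
        return RandomForestClassifier(n_estimators=cfg.rf_trees,
                                      random_state=cfg.seed % (2**31))
    else:
        raise EvaluationError(f"unknown classifier {cfg.classifier!r}")
    if cfg.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def train_classifier(table: pd.DataFrame, cfg: EvalConfig,
                     feature_subset: list[str] | None = None):
    """Fit the configured classifier on a feature table.

    The table must contain both classes of the configured task.
    """
    features = list(feature_subset or FEATURE_NAMES)
    y = table[_label_column(cfg.task)].to_numpy()
    if len(np.unique(y)) < 2:
        raise EvaluationError("training set contains a single class")
    model = make_classifier(cfg)
    if cfg.classifier == "knn" and len(table) < cfg.knn_k:
        # tiny training folds: clip k to the number of training rows
        params = {"n_neighbors": len(table)}
        if cfg.standardize:
            params = {"clf__n_neighbors": len(table)}
        model.set_params(**params)
    model.fit(table[features].to_numpy(), y)
    return model


@dataclass
class CVReport:
    """Accuracy report of one validation run (accuracies in %)."""

    per_fold: dict[str, float]
    mean_accuracy: float
    sd: float
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_fold": self.per_fold, "mean_accuracy": self.mean_accuracy,
                "sd": self.sd, "config": self.config}


def _accuracy_pct(model, table: pd.DataFrame, features: list[str], task: str) -> float:
    y = table[_label_column(task)].to_numpy()
    pred = model.predict(table[features].to_numpy())
    return 100.0 * float(np.mean(pred == y))


def losocv(table: pd.DataFrame, cfg: EvalConfig,
           feature_subset: list[str] | None = None) -> CVReport:
    """Leave-one-subject-out cross-validation.

    One fold per subject: train on all other subjects, test on the held-out
    one.  The reported mean is the unweighted mean of per-subject
    accuracies.
    """
    features = list(feature_subset or FEATURE_NAMES)
    subjects = list(dict.fromkeys(table["subject_id"]))
    if len(subjects) < 2:
        raise EvaluationError("LoSOCV needs >= 2 subjects")
    per_fold: dict[str, float] = {}
    for subj in subjects:
        train = table[table["subject_id"] != subj]
        test = table[table["subject_id"] == subj]
        model = train_classifier(train, cfg, features)
        per_fold[subj] = _accuracy_pct(model, test, features, cfg.task)
    accs = np.array(list(per_fold.values()))
    return CVReport(per_fold=per_fold, mean_accuracy=float(accs.mean()),
                    sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
                    config={"classifier": cfg.classifier, "task": cfg.task,
                            "protocol": "losocv"})


@dataclass
class HoldoutResult:
    """Repeated pseudorandom holdout: summary plus the full accuracy
    distribution (%, one value per repetition) for boxplots and paired
    tests."""

    mean_accuracy: float
    sd: float
    accuracies: np.ndarray
    n_retried_splits: int = 0

    def report(self, cfg: EvalConfig) -> CVReport:
        return CVReport(
            per_fold={f"rep{i:03d}": float(a) for i, a in enumerate(self.accuracies)},
            mean_accuracy=self.mean_accuracy, sd=self.sd,
            config={"classifier": cfg.classifier, "task": cfg.task,
                    "protocol": "holdout", "reps": len(self.accuracies)})


def repeated_holdout(table: pd.DataFrame, cfg: EvalConfig,
                     feature_subset: list[str] | None = None) -> HoldoutResult:
    """Pseudorandom holdout of ``cfg.holdout_frac`` of the pooled rows,
    repeated ``cfg.holdout_reps`` times.

    Splits are drawn from ``cfg.seed`` independently of the labels, so two
    runs with the same seed (e.g. the skip and interest tasks) see the same
    split sequence — the accuracy distributions are paired by repetition.
    Splits whose test part misses a class are redrawn (bounded, logged in
    ``n_retried_splits``).
    """
    features = list(feature_subset or FEATURE_NAMES)
    label_col = _label_column(cfg.task)
    n = len(table)
    n_test = max(1, int(round(cfg.holdout_frac * n)))
    if n - n_test < 2:
        raise EvaluationError("table too small for the holdout split")
    rng = np.random.default_rng(cfg.seed)
    y_all = table[label_col].to_numpy()
    accs = np.empty(cfg.holdout_reps)
    retried = 0
    classes = np.unique(y_all)
    for rep in range(cfg.holdout_reps):
        for _attempt in range(MAX_SPLIT_RETRIES):
            if cfg.stratify_holdout:
                parts = []
                for c in classes:
                    idx = rng.permutation(np.flatnonzero(y_all == c))
                    parts.append(idx[:max(1, int(round(cfg.holdout_frac * idx.size)))])
                test_idx = np.concatenate(parts)
                train_idx = np.setdiff1d(np.arange(n), test_idx)
            else:
                perm = rng.permutation(n)
                test_idx, train_idx = perm[:n_test], perm[n_test:]
            if (len(np.unique(y_all[test_idx])) == 2
                    and len(np.unique(y_all[train_idx])) == 2):
                break
            retried += 1
        else:
            raise EvaluationError("could not draw a two-class holdout split")
        train, test = table.iloc[train_idx], table.iloc[test_idx]
        model = train_classifier(train, cfg, features)
        accs[rep] = _accuracy_pct(model, test, features, cfg.task)
    return HoldoutResult(mean_accuracy=float(accs.mean()),
                         sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
                         accuracies=accs, n_retried_splits=retried)


def wilcoxon_bonferroni(dist_a: np.ndarray, dist_b: np.ndarray,
                        cfg: EvalConfig) -> dict:
    """Two-sided paired Wilcoxon signed-rank test with Bonferroni threshold.

    Zero differences are discarded (standard convention); the p-value is
    exact for <= 25 nonzero pairs, normal approximation with continuity
    correction above.  Rejection threshold: alpha / n_features (0.05/9).
    """
    dist_a, dist_b = np.asarray(dist_a, float), np.asarray(dist_b, float)
    if dist_a.shape != dist_b.shape:
        raise EvaluationError("paired distributions must have equal length")
    diff = dist_a - dist_b
    nz = diff[diff != 0]
    threshold = cfg.bonferroni_threshold
    if nz.size == 0:
        return {"p_value": 1.0, "reject": False, "threshold": threshold,
                "n_pairs": 0}
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(dist_a, dist_b, zero_method="wilcox",
                         correction=(method == "approx"), method=method,
                         alternative="two-sided")
    p = float(res.pvalue)
    return {"p_value": p, "reject": bool(p < threshold), "threshold": threshold,
            "n_pairs": int(nz.size)}


def relevance_report(table: pd.DataFrame, cfg: EvalConfig) -> pd.DataFrame:
    """Per-feature, per-classifier, per-task repeated-holdout accuracies.

    Retrains every classifier on each feature individually; the grid is
    9 features x 3 classifiers x 2 tasks.  For each (feature, classifier)
    pair the skip and interest accuracy distributions — paired by holdout
    repetition — are compared with the Bonferroni-corrected Wilcoxon test.

    Returns a tidy frame: feature, classifier, task, mean_accuracy, sd,
    wilcoxon_p, reject_equal_performance.
    """
    records = []
    for feature in FEATURE_NAMES:
        for clf in ("svm", "knn", "rf"):
            dists = {}
            for task in ("skip", "interest"):
                c = replace(cfg, classifier=clf, task=task)
                dists[task] = repeated_holdout(table, c, feature_subset=[feature])
            test = wilcoxon_bonferroni(dists["skip"].accuracies,
                                       dists["interest"].accuracies, cfg)
            for task in ("skip", "interest"):
                records.append({
                    "feature": feature, "classifier": clf, "task": task,
                    "mean_accuracy": dists[task].mean_accuracy,
                    "sd": dists[task].sd,
                    "wilcoxon_p": test["p_value"],
                    "reject_equal_performance": test["reject"],
                })
    return pd.DataFrame(records)
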