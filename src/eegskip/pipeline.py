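"""One-command orchestration: synth/ingest -> preprocess -> entropy ->
features -> evaluate.

``run`` executes the full pipeline from a single YAML config (or an
equivalent dict) and writes a feature CSV, evaluation reports and a run
manifest (config snapshot, versions, per-stage counts, exclusion log)
under an output directory.  Rerunning the same config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (EvalConfig, FeatureConfig, SimConfig, _from_mapping,
                     config_to_dict)
from .errors import ConfigurationError
from .evaluate import losocv, relevance_report, repeated_holdout
from .features import (TrialFeatureData, build_feature_table,
                       compute_trial_entropies)
from .preprocess import preprocess_session
from .session import Session
from .synth import generate_session, subject_ids


def extract_session_features(
    session: Session, fcfg: FeatureConfig
) -> tuple[pd.DataFrame, list[TrialFeatureData], dict]:
    """Preprocess one session and compute its feature rows.

    Returns the per-trial feature table, the retained intermediate data
    (per-epoch per-scale entropies, for per-scale curves), and stage
    counts for the manifest.
    """
    trials, excluded = preprocess_session(
        session,
        entropy_epoch_s=fcfg.entropy_epoch_s,
        power_epoch_s=fcfg.power_epoch_s,
    )
    trial_data = [compute_trial_entropies(t, fcfg) for t in trials]
    table = build_feature_table(session.subject_id, trial_data, fcfg)
    featured_ids = set(table["trial_id"])
    exclusions = list(excluded) + [
        {"trial": d.trial_index, "reason": "too_short_or_degenerate"}
        for d in trial_data if d.trial_index not in featured_ids
    ]
    counts = {
        "trials_in": len(session.trials),
        "trials_featured": len(table),
        "trials_excluded": len(session.trials) - len(table),
        "exclusions": exclusions,
    }
    return table, trial_data, counts


def cohort_features(
    sim: SimConfig, fcfg: FeatureConfig | None = None
) -> tuple[pd.DataFrame, dict[str, list[TrialFeatureData]], dict]:
    """Generate a synthetic cohort and run it through features.

    Sessions are generated and processed one at a time (the raw signal of
    a session is released before the next is simulated).  Returns the
    pooled feature table, per-subject intermediate data, and manifest
    counts.
    """
    fcfg = fcfg or FeatureConfig()
    sim.validate()
    fcfg.validate()
    if sim.n_subjects < 2:
        raise ConfigurationError("a cohort needs n_subjects >= 2")
    tables, by_subject, counts = [], {}, {}
    for sid in subject_ids(sim):
        session = generate_session(sim, sid)
        table, trial_data, c = extract_session_features(session, fcfg)
        tables.append(table)
        by_subject[sid] = trial_data
        counts[sid] = c
    return pd.concat(tables, ignore_index=True), by_subject, counts


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def run(config: str | Path | dict, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline described by a run config.

    Config keys: ``sim`` (synthetic cohort parameters) or ``input``
    (directory of ``*.edf`` sessions with sidecars), ``features``,
    ``eval``, ``protocols`` (subset of losocv/holdout), ``classifiers``,
    ``tasks``, ``relevance`` (bool).  Artifacts written to ``out_dir``:
    ``features.csv``, ``reports.json``, ``manifest.json`` and, when
    requested, ``relevance.csv``.  On a stage failure the manifest written
    so far is still flushed.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": cfg,
        "versions": {"eegskip": __version__, "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    try:
        fcfg = _from_mapping(FeatureConfig, cfg.get("features", {}))
        fcfg.validate()
        manifest["feature_config"] = config_to_dict(fcfg)

        if "sim" in cfg:
            sim = _from_mapping(SimConfig, cfg["sim"])
            sim.validate()
            manifest["sim_config"] = config_to_dict(sim)
            table, by_subject, counts = cohort_features(sim, fcfg)
        elif "input" in cfg:
            from .io import read_session

            tables, counts, by_subject = [], {}, {}
            paths = sorted(Path(cfg["input"]).glob("*.edf"))
            if not paths:
                raise ConfigurationError(f"no EDF sessions under {cfg['input']}")
            for p in paths:
                session = read_session(p)
                t, trial_data, c = extract_session_features(session, fcfg)
                tables.append(t)
                by_subject[session.subject_id] = trial_data
                counts[session.subject_id] = c
            table = pd.concat(tables, ignore_index=True)
        else:
            raise ConfigurationError("run config needs a 'sim' or 'input' section")
        manifest["stages"]["features"] = counts

        features_csv = out / "features.csv"
        table.to_csv(features_csv, index=False)

        ecfg = _from_mapping(EvalConfig, cfg.get("eval", {}))
        ecfg.validate()
        manifest["eval_config"] = config_to_dict(ecfg)

        protocols = cfg.get("protocols", ["losocv"])
        classifiers = cfg.get("classifiers", ["svm", "knn", "rf"])
        tasks = cfg.get("tasks", ["skip", "interest"])
        reports: dict[str, Any] = {}
        for task in tasks:
            for clf in classifiers:
                c = replace(ecfg, classifier=clf, task=task)
                key = f"{task}_{clf}"
                if "losocv" in protocols:
                    reports[f"{key}_losocv"] = losocv(table, c).to_dict()
                if "holdout" in protocols:
                    reports[f"{key}_holdout"] = repeated_holdout(table, c).report(c).to_dict()
        with open(out / "reports.json", "w") as fh:
            json.dump(reports, fh, indent=1, sort_keys=True)

        if cfg.get("relevance"):
            relevance_report(table, ecfg).to_csv(out / "relevance.csv", index=False)

        manifest["stages"]["evaluate"] = {"reports": sorted(reports)}
        return {"features": features_csv, "reports": reports,
                "manifest": manifest, "table": table, "by_subject": by_subject}
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
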