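"""Leave-one-subject-out classification of skipping and interest.

Builds a small synthetic cohort with a strong injected class effect,
extracts features, and validates the three classifiers subject-wise.
"""

from eegskip import EvalConfig, SimConfig, cohort_features, losocv

sim = SimConfig(n_subjects=4, n_videos_per_subject=15, video_len_s=20.0,
                effect_size=3.0, seed=3)
table, _, _ = cohort_features(sim)
print(f"feature table: {len(table)} trials from "
      f"{table['subject_id'].nunique()} subjects\n")

for task in ("skip", "interest"):
    for clf in ("svm", "knn", "rf"):
        report = losocv(table, EvalConfig(classifier=clf, task=task, seed=1))
        folds = ", ".join(f"{k}={v:.0f}" for k, v in report.per_fold.items())
        print(f"{task:8s} {clf:3s}: mean {report.mean_accuracy:5.1f}%  "
              f"({folds})")

print("\nEach fold trains on three subjects and tests on the held-out one; "
      "the mean is the unweighted average over subjects. Skip accuracy "
      "benefits from both the injected beta-envelope effect and the "
      "shorter duration of skipped trials.")
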