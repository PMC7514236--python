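"""From raw session to the nine trial features.

Runs the preprocessing chain (mastoid re-referencing, baseline correction,
1 s / 0.5 s epoching, theta/mu/beta band filtering, downsampling to 500 Hz)
and the entropy/power feature stage on one synthetic session.
"""

from eegskip import FeatureConfig, SimConfig, extract_session_features, \
    generate_session

cfg = SimConfig(n_subjects=1, n_videos_per_subject=8, video_len_s=20.0,
                effect_size=3.0, seed=5)
session = generate_session(cfg, "s01")
table, trial_data, counts = extract_session_features(session, FeatureConfig())

print(table.round(3).to_string(index=False))
print(f"\n{counts['trials_featured']} of {counts['trials_in']} trials "
      f"featured ({counts['trials_excluded']} too short).")
print("RCV*: range of the windowed coefficient of variation of band "
      "entropy (beta/mu/theta). REEI/REAI/REVI: range of the entropy-based "
      "engagement/arousal/valence indices. CV2*: peak-to-peak variability "
      "of the power-based indices. Labels: +1 = not skipped / interested.")
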