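"""Simulate one viewing session and inspect its structure.

Generates a 6-video session for one subject, prints the trial layout
(baseline, viewing span, skip/interest responses) and writes the session
to EDF+ with a JSON event sidecar.
"""

from pathlib import Path

from eegskip import SimConfig, generate_session, write_session

cfg = SimConfig(n_subjects=1, n_videos_per_subject=6, video_len_s=20.0,
                effect_size=2.0, seed=7)
session = generate_session(cfg, "s01")

print(f"subject {session.subject_id}: {session.data.shape[0]} channels, "
      f"{session.data.shape[1] / session.fs:.0f} s at {session.fs:.0f} Hz")
for k, t in enumerate(session.trials):
    watched = (t.end - t.video_onset) / session.fs
    print(f"  trial {k}: watched {watched:5.1f} s  "
          f"skipped={t.skipped!s:5}  interested={t.interested}")

out = Path("scratch/example_sessions")
out.mkdir(parents=True, exist_ok=True)
path = write_session(session, out / "s01.edf")
print(f"\nwrote {path} (+ .json sidecar)")
print("Skipped trials end early (30-90% of the video); the skip/interest "
      "responses are the labels the classifiers later predict.")
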