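"""Simulate one subject's writing session and extract the indicator catalogue.

Builds a 30 s free-writing recording from subject-level parameters, segments
it into strokes / in-air gaps / pauses, and prints a few indicators from each
domain. The temporal numbers describe the timing structure (how much time on
paper vs in the air); SPARC/LDLJ are smoothness metrics (more negative =
less smooth); tilt describes the pen's inclination to gravity.
"""

from penkit import SubjectParams, extract_all, simulate_recording

params = SubjectParams(pause_prob=0.1, smoothness=0.85, tilt_cv=0.10)
rec = simulate_recording(params, task="list", duration=30.0, seed=42)
result = extract_all(rec)
seg = result.segmentation

print(f"recording: {rec.n} samples at {rec.fs:g} Hz ({rec.duration:.1f} s)")
print(f"strokes: {len(seg.strokes)}, in-air gaps: {len(seg.airs)}, "
      f"pauses (>2 s): {len(seg.pauses)}")
v = result.vector.values
for name in ("execution_time", "rel_stroke_num", "on_sheet_ratio", "mean_pause",
             "sparc", "ldlj_g", "mean_force", "force_overshoot",
             "mean_tilt", "tilt_cv", "a_apen", "g_rpw_8"):
    print(f"  {name:24s} {v[name]:8.3f}")
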