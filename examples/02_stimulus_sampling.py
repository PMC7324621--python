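"""Sampling low/medium/high complexity conditions with animal matching.

Draws a scored scene pool, samples three complexity conditions along the
joint SC-CE axis with animal/non-animal scenes matched within condition,
and builds a 960-trial speed/accuracy schedule.
"""

from sceneddm import assign_conditions, build_trial_schedule, generate_stat_pool

pool = generate_stat_pool(7200, seed=3)
stim = assign_conditions(pool, n_per_condition=160, mode="joint", seed=5)

print("condition  n  animal     SC range        CE range")
for cond, frame in stim.frames.items():
    print(f"{cond:9s} {len(frame):3d} {int(frame.animal.sum()):6d}  "
          f"[{frame.SC.min():.2f}, {frame.SC.max():.2f}]   "
          f"[{frame.CE.min():.4f}, {frame.CE.max():.4f}]")

print("\nanimal vs non-animal matching (all p should exceed 0.25):")
for (cond, stat), t in stim.match_report.entries.items():
    print(f"  {cond:7s} {stat}: t({t.df}) = {t.t:+.2f}, p = {t.p_mean:.2f};  "
          f"z = {t.z:+.2f}, p = {t.p_median:.2f}")

sched = build_trial_schedule(stim, seed=7)
print(f"\nschedule: {len(sched)} trials "
      f"({sched.scene_id.nunique()} scenes x 2 instructions), "
      f"blocks of 20, mean fixation {sched.fixation_ms.mean():.0f} ms")
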