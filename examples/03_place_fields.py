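"""Detect place fields and measure their shape: length, skew, FRAI.

Fields are connected 2 cm-bin regions >= 1 SD above the unit's mean map
rate with a >= 2 SD peak and >= 15 cm linearized extent, split by travel
direction.  Skew is the third standardized moment of the width-averaged
rate profile along the direction of travel; FRAI compares the firing rate
of the first vs second half of in-field spikes per traversal.
"""

import pfls
from pfls.information import SessionContext

spec = pfls.default_session_spec("fields-demo")
spec.n_trials = 40
session, truth = pfls.generate_session(spec, seed=3)

ctx = SessionContext(session, pfls.AnalysisConfig())
planted = truth.field_specs()

for uid in ("hpc_pc_02", "ls_pc_01"):
    fields = pfls.analyze_unit_fields(session, uid, ctx)
    fs = planted[uid]
    print(f"{uid}: planted center {fs.center:.0f} cm, "
          f"skew shape {fs.skew_shape:+.1f}")
    for f in fields:
        lap = (f"mean lap-center drift "
               f"{f.lap_center_distances.mean():.1f} cm"
               if f.lap_center_distances is not None else "too few laps")
        print(f"  {f.direction:17s} center {f.center_u:5.1f} cm  "
              f"length {f.length:4.1f} cm  peak {f.peak_rate:.1f} Hz  "
              f"skew {f.skew:+.3f}  FRAI {f.frai:+.3f}  "
              f"({f.n_traversals} passes, {lap})")
# A positive skew means the rate profile tails in front of the animal
# (ramping down after the peak); negative means it ramps up toward the
# field's end.  FRAI and skew should anticorrelate for ramp-up fields.
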