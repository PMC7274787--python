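"""Where do fields sit on the maze?  Arm tallies and reward-distance profile.

Field centers are labelled forced-side / stem / choice-side (junction zones
excluded), and the probability of finding a field is histogrammed against
along-track distance from the reward sites, with a track-exposure column
for geometry normalization.
"""

import pfls
from pfls.fields import find_place_cells
from pfls.information import SessionContext

spec = pfls.default_session_spec("geometry-demo")
spec.n_trials = 40
session, _ = pfls.generate_session(spec, seed=4)
ctx = SessionContext(session, pfls.AnalysisConfig())

fields = [f for fl in find_place_cells(session, ctx).values() for f in fl]
rows = pfls.assign_field_locations(fields, session.maze)
tally = {}
for r in rows:
    tally[r["arm_label"]] = tally.get(r["arm_label"], 0) + 1
print("field locations:", dict(sorted(tally.items())))

hist = pfls.field_probability_by_distance(fields, session.maze, bin_width=30.0)
print("\ndistance-from-reward histogram (30 cm bins):")
print(" dist[cm]  P(field)  track-bins")
for d, fr, tb in zip(hist["distance_bin_cm"], hist["field_fraction"],
                     hist["track_bins"]):
    print(f"  {d:6.0f}   {fr:6.3f}     {tb:5.0f}")
# P(field) sums to 1; dividing it by the track-bins column corrects for the
# maze geometry (lateral arms contribute twice the track per run coordinate).
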