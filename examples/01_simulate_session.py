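"""Generate a synthetic T-maze session with known ground truth and save it.

The session emulates a ~10-minute recording: a 30 Hz tracked trajectory
running forced-arm -> stem -> choice-arm trials with reward pauses, plus a
mixed population of HPC/LS place cells, Poisson units, speed/acceleration
cells and HPC->LS coupled pairs.
"""

from pathlib import Path

import pfls

spec = pfls.default_session_spec("demo")
spec.n_trials = 28          # ~10 minutes of trials
session, truth = pfls.generate_session(spec, seed=1)

out = Path("scratch/demo_session")
pfls.write_session(session, out)
truth.to_json(out / "ground_truth.json")

n_hpc = sum(t.region == "HPC" for t in session.trains)
n_ls = sum(t.region == "LS" for t in session.trains)
print(f"session '{session.session_id}': {session.duration:.0f} s, "
      f"{len(session.positions)} position samples")
print(f"units: {n_hpc} HPC + {n_ls} LS "
      f"({len(spec.coupled_pairs)} coupled HPC->LS pairs)")
print(f"trials: {len(session.events_of('reward'))} rewarded")
print(f"written to {out}/ (positions.csv, spikes/, manifest.json, "
      "ground_truth.json)")
# The ground-truth JSON records every planted field center/width/peak and
# coupling lag, so downstream analyses can be scored against it.
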