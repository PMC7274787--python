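"""Recover a planted HPC->LS transmission lag from spike cross-correlation.

An HPC place cell drives an LS unit with a 20 ms lag (30% reliability,
2 ms jitter, 1 Hz LS background).  The cross-correlogram of the pair
(10 ms bins, +/-100 ms lags, positive lag = HPC leads) is corrected by
subtracting the mean of correlograms against circularly time-shifted LS
trains.
"""

import pfls
from pfls.coupling import shuffle_correct
from pfls.synth import CouplingSpec, FieldSpec

maze = pfls.build_maze(100.0, 100.0)
pos, events = pfls.simulate_trajectory(maze, n_trials=40, seed=5)
hpc, ls = pfls.generate_coupled_pair(
    FieldSpec(center=250.0, width_sd=8.0, peak_rate=7.0, baseline_rate=0.1,
              side="left"),
    CouplingSpec(lag_ms=20.0, transmission_prob=0.3, jitter_sd_ms=2.0,
                 ls_background_rate=1.0),
    pos, maze, seed=5, events=events)

ccg = shuffle_correct(hpc.spike_times, ls.spike_times, pos.t[0], pos.t[-1],
                      n_shuffles=100, seed=5)
print(f"HPC {len(hpc)} spikes, LS {len(ls)} spikes")
print(f"shuffle mean subtracted: {ccg.shuffle_mean:.2e} per bin")
print("lag[ms]  corrected")
for lag, v in zip(ccg.lags_ms, ccg.corrected):
    bar = "#" * max(0, int(1e5 * v))
    print(f"  {lag:+4.0f}   {v:+.2e}  {bar}")
print(f"\npeak at {ccg.peak_lag_ms:+.0f} ms (planted 20 ms, HPC leading): "
      "the transmission lag is recovered within one 10 ms bin")
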