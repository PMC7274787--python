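# Methods

This note documents the models, estimators and numerical choices behind
`pfls`, in the order the pipeline runs them, together with the design
decisions that were genuinely open and the limitations a user should know.

## Coordinates and the maze model

The double-sided T maze is modeled as five straight segments: two forced
arms and two choice arms of length *a* (default 100 cm) joined to a stem of
length *s* (default 100 cm) at two junctions. Reward sites sit at the
choice-arm ends. Every 2-D point projects to its nearest segment (junction
ties resolved by a fixed segment priority: stem first, then forced and
choice arms), yielding a *run coordinate* u ∈ [0, 2a+s]: 0 at a forced-arm
end, *a* at the forced junction, *a+s* at the choice junction, 2a+s at
reward. Left and right arms mirror onto the same u range, matching the
task's mirrored trial structure; arm labels retain the side, and the
geodesic distance between two points routes through the junction when they
lie on opposite lateral arms of the same T. Distance to reward is the
along-track distance (2a+s) − u, which is identical for the upcoming reward
(toward travel) and the just-visited one (away travel) by the mirror
symmetry. Junction zones are ±10 cm of run coordinate around each T
junction; fields centered there are labelled forced-/choice-point and
excluded from per-arm tallies, since such centers cannot be assigned to an
arm. Points more than 10 cm off the track raise an off-track error.

Time is in seconds (float64), space in cm; pixel coordinates are converted
exactly once using the session's px/cm factor. Spatial bins are half-open
[lo, hi), indexed from 0.

## Kinematics

Speed at sample *i* is the hypotenuse of the displacement between samples
i−1 and i+1 divided by their time gap (one-sided at the ends), smoothed
with a 1 s SD Gaussian, then converted to cm/s. Because tracking drops
samples (≈30 Hz nominal, often ≈15 Hz effective), smoothing is done on a
uniform grid at the nominal rate (linear interpolation across gaps) and
sampled back at the tracked timestamps; this is exact for uniform sampling
and well behaved across dropouts. Acceleration is the central difference
of the already-smoothed speed — the source pipeline is silent here, and
differentiating the smoothed signal keeps the two consistent. Spike
speeds are linear interpolations of the smoothed speed at spike times.

Occupancy credits each sample with half the gap to each neighbor, capped
at 1 s, so an occlusion cannot credit minutes of dwell to one sample. The
cap is our choice; the conversion from variable-rate samples to dwell time
is not specified by the source analysis.

## Maps and spatial information

Occupancy and rate maps are 2-D over the camera plane (1 cm bins for
information, 2 cm for fields; each map carries its bin size and the two
are never mixed). Rates are per-bin spike count over dwell time among
speed-filtered (≥ 12 cm/s) samples, then smoothed with a 10 cm SD Gaussian
normalized over the visited mask, so unvisited bins contribute neither
mass nor zeros. Spikes whose interpolated position falls in an unvisited
bin (corner-cutting across tracking gaps) are snapped to the nearest
visited bin, which keeps the identity R̄ = Σᵢ PᵢRᵢ exact on the raw map.

bits/spike and bits/s use the formulas in the README with 0·log₂0 := 0 and
Pᵢ = 0 bins excluded; bits/s ≡ R̄ × bits/spike holds to float precision and
is tested. Exclusions: mean speed-filtered rate < 0.05 Hz (`low_rate`), or
a session that does not cover every 2 cm track bin at speed
(`no_coverage`). The information cutoff is inclusive (≥ 0.8 bits/spike).

Mutual information between spatial bin and windowed spike count is the
plug-in estimator on one-camera-frame windows with counts clipped at 3.
The source for this measure is not fully specified upstream, so treat MI
as a supplementary, implementation-defined quantity; it is reported but
nothing downstream depends on it. No bias-corrected information
estimators are provided.

The surrogate control draws homogeneous Poisson trains over the whole
session timeline at the recorded LS mean rates (the simplest model
consistent with a rate-matched control), then applies the identical speed
filter and information pipeline.

## Place fields

Detection operates on the unit's smoothed 2 cm map: connected components
(4-connectivity, no diagonals) of bins ≥ μ + 1σ containing at least one
bin ≥ μ + 2σ, with linearized extent ≥ 15 cm. Two interpretation points
are deliberate:

- μ and σ are the mean and SD of the unit's smoothed rate-map values over
  visited bins (a spatial-map SD). The alternative — a temporal firing-
  rate SD — is undefined for a map-level threshold; the spatial reading is
  the one that gates a map.
- The boundary rule is R ≥ μ + 1σ. A perfectly flat map (σ = 0) has no
  fields by definition.

Field length is the extent of the component's bins projected onto the run
coordinate (plus one bin width); the center is the argmax bin, ties broken
toward the lower run coordinate (logged). Units whose map maximum is
below 0.05 Hz are excluded from field analysis (max-rate wording), while
the information stage uses the mean-rate wording; both are recorded.

Direction splitting labels each sample by trial phase — trial start →
reward is *toward*, reward → next trial start is *away* — and builds one
map per direction on the shared grid. Toward/away fields of one unit with
centers separated by strictly less than 20 cm are one bidirectional field;
both direction-specific entries are kept and flagged, since shape
statistics are direction-specific.

Traversals are maximal runs of ≥ 2 consecutive samples inside the field's
bin set (broken by > 1 s tracking gaps); laps count reward-to-reward
segments. Lap stability is the per-pass |peak-spiking location − mean
peak location| along the track (2 cm histogram argmax of in-field spike
positions), for fields traversed ≥ 15 times. FRAI splits each traversal's
spikes by count (odd middle spike to the first half; the time boundary is
the midpoint between the straddling spikes), takes F₁, F₂ as count/time of
each half and averages (F₁−F₂)/(F₁+F₂) across traversals; FRAI ∈ [−1, 1]
by construction. The printed form of this index upstream lacks an
operator; the difference-over-sum form is the one used in the asymmetry
literature and the only dimensionally sensible reading.

Skew width-averages the in-field smoothed rates that share a run-
coordinate bin into a 1-D profile w(x), orients x along the direction of
travel (reversed for away-fields), and computes the weighted third
standardized moment. Zero-variance profiles are reported missing. Note
that 10 cm map smoothing strongly attenuates skew magnitudes (planted
strongly-skewed profiles measure at |skew| ≈ 0.05–0.2); signs are
recoverable, magnitudes are smoothing-dependent.

The kinematic control regresses each bin's smoothed rate on the bin's
dwell-weighted mean speed and acceleration (OLS with intercept, ≥ 10
bins); a rank-deficient design drops the acceleration column with a log
message.

## HPC–LS coupling

Each HPC place field is matched to the LS field (same session) whose
center lies within 20 cm of track, inclusive; among multiple candidates
the LS unit with the most similar mean firing rate wins, with distance and
then field id as deterministic tie-breaks. Multi-field cells contribute
each field.

The cross-correlogram bins both trains at 10 ms over the session and
counts spike pairs by bin-index difference over lags −100…+100 ms
(positive = LS follows HPC), computed sparsely on spike bin indices —
identical to the dense lagged inner product, and verified against a
brute-force pair count. Values default to pair counts per time bin;
rate and lagged-Pearson normalizations are available, since the upstream
normalization is unstated. The control shuffles the LS train by a
circular time shift (uniform offset ≥ 1 s), preserving its ISI structure
and rate; the scalar mean of the control correlogram over lags and
shuffles is subtracted from every raw lag bin. The number of shuffles
defaults to 100 (configurable down to 1) for a lower-variance control.
Group summaries report per-pair mean corrected correlation over ±100 ms
and mean peak lag by arm (forced/middle/choice; junction-centered pairs
fall outside these groups), and the session-thirds variant restricts both
trains to each temporal third (half-open partition; pairs with < 2 spikes
in a third are dropped there).

One caveat the synthetic experiments make explicit: co-located but
temporally independent place cells already show an elevated corrected
correlation across all lags, because the circular shuffle destroys time
alignment but the two cells genuinely co-fire wherever their fields
overlap. Planted-coupling comparisons therefore rate-match the LS
partners across groups so that only the spike-time coupling differs.

## Statistics

Two-sample comparisons use the pooled-variance Student t (df = n₁+n₂−2,
matching the df convention of the reported analyses) rather than Welch;
one-sample, paired t, two-sample KS and Pearson χ² (uncorrected) are also
provided. Proportion comparisons are run as t tests on binary indicators,
with a two-proportion z test emitted alongside for reference. No
multiple-testing correction is applied; all p values are raw. Type-I
error of the pooled t is verified at the nominal 5% over 1000 null
simulations.

## The synthetic session generator

The generator emulates the deposited data's structure, not its biology in
detail. Defaults (the study conditions of all shipped experiments):
100 cm arms and stem; ~30-minute sessions (83 trials ≈ 1810 s; shorter
sessions in the cheap unit tests); per-leg running speeds truncated-normal
around 40 cm/s (floor 1 cm/s), 4 s reward pauses and 2 s forced-end pauses
so the 12 cm/s filter is exercised; forced sides uniform with at most
three consecutive repeats; 30 Hz sampling with 50% random dropout
(effective ≈15 Hz) and 1 px tracking noise at 3.5 px/cm.

Place cells are inhomogeneous Poisson via thinning against the rate upper
bound, with rate baseline + (peak−baseline)·g(u) where g is a skew-normal-
shaped bump rescaled to unit peak and shifted so its *mode* sits at the
nominal center — so the planted center is directly comparable with the
detected argmax center. `skew_shape` is the skew-normal shape parameter
(0 = symmetric, positive = mass toward reward); `side` restricts firing to
one lateral arm, `direction` to one travel phase. Rate at spike-candidate
times is linearly interpolated between position samples. Non-place units
are homogeneous Poisson or rate-linear in speed/acceleration (rectified at
zero). Coupled pairs transmit each HPC spike with probability p at a
fixed lag plus Gaussian jitter over an independent LS Poisson background.

Every generator consumes a spawned child of a single root seed in a fixed
order, so a session is byte-reproducible from (spec, seed), and the ground
truth is serialized next to the session.

Recovery experiments score detection against the *noise-free expected
map*: the planted rate function evaluated at the visited bin centers of
the real occupancy, smoothed and thresholded exactly like an estimated
map. This isolates spiking/occupancy sampling noise from the deterministic
geometry of the detector (whose μ+1σ boundary makes detected lengths much
larger than the planted Gaussian SD — e.g. ≈40 cm for an 8 cm-SD bump
after 10 cm smoothing).

What the generator does not emulate — and hence what passing tests do not
show about real data: theta rhythmicity and phase precession, bursting and
refractoriness, experience-dependent field drift, error trials, non-
stationary rates across a session, and electrode artifacts. Skew in real
fields arises from experience-dependent plasticity; here it is planted
directly in the rate profile.

## Problem sizes in the shipped experiments

Surrogate control: 100 units at 0.5–10 Hz on one ~30-minute trajectory.
Field recovery: 50 planted cells (peaks 5–10 Hz, width SD 3–10 cm) plus 50
rate-matched homogeneous units. Skew sign recovery: 20 seeds of a
strongly skewed field (shape 6, 14 cm SD) — a strong planted effect is
needed because map smoothing attenuates the measured magnitude. Coupling:
50 pairs at 20 ms lag (30% transmission) for lag recovery; 100 independent
pairs for the null; six coupled choice-arm pairs vs six rate-matched
independent forced-arm pairs for the planted group contrast. Statistics
calibration: 1000 null repeats at n = 30 per group. These sizes keep the
full suite to a few minutes on one CPU while leaving comfortable margins
on every recovery criterion.

## Known limitations

- Field extent is measured along the run coordinate; a (rare) component
  wrapping through a junction across arms under-measures its extent.
- The MI estimator is a stand-in for an under-specified upstream measure.
- The corrected cross-correlogram's absolute scale depends on the chosen
  normalization; only comparisons within one normalization are meaningful.
- Lap-stability and FRAI need well-sampled traversals; sparse cells (< 2
  spikes per pass) return missing values rather than estimates.
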