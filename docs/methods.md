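# Methods notes

This note records the models, parameter choices and numerical conventions
behind the package, the way they would appear in a methods section — with
emphasis on the decisions that were genuinely open and on what the
synthetic validation does and does not establish.

## Analysis pipeline

### Ratemaps and templates

Spatial tuning is estimated as spikes per second of dwell on a 20×20 grid
of 3×3 cm bins, restricted to locomotion (speed > 2 cm/s, estimated from
200 ms boxcar-smoothed positions; the smoothing window suppresses 25 Hz
tracking jitter and is our choice — the velocity estimator itself is not
prescribed by the protocol). Bins with under 0.2 s of filtered dwell are
treated as unvisited (NaN). Maps are smoothed with the fixed 5×5 Gaussian
boxcar kernel (centre 0.16, weights summing to 1); at grid edges and next
to unvisited bins the kernel weights over the *defined* neighbours are
renormalised to sum to one, which conserves rate mass for
interior-supported maps and avoids edge deflation. Templates use the
first halves of the two baseline sessions; second halves are reserved for
baseline measurements. The coverage precondition (≥ 90 % of bins visited
during each template half, visits counted irrespective of speed)
tolerates only sparse unvisited bins.

### Remapping exclusion

The exclusion of cells that changed tuning between baseline and test
sessions is stated only qualitatively in the underlying protocol; our
operational criterion is: an environment is judgeable for a cell when its
occupancy-weighted mean POST rate there reaches 0.2 Hz (a handful of
stray spikes — e.g. sparse out-context events — cannot establish a tuning
change); in a judgeable environment the cell is excluded when the
template–POST spatial correlation falls below 0.5 (shift/expansion) or
when > 30 % of its POST rate mass lies in bins where the template was
below 10 % of its peak (new field), evaluated only over bins estimated in
both maps. Cells silent in POST *where their template predicted activity*
are excluded as inactive. All thresholds are configurable and none is
canonical.

### Theta segmentation

The LFP is band-passed with a zero-phase Hamming-window FIR filter,
default 6–11 Hz (the narrow reading of the ambiguous published band;
both edges are configurable). Instantaneous phase comes from the analytic
signal. The cycle border is the phase bin (36 bins of 10°) with the
lowest pooled spike count — the population firing minimum — with ties
resolved to the earliest bin; cycles are cut at successive crossings of
that phase and cycles with periods outside 83–200 ms (5–12 Hz) are
discarded as non-theta. Within a cycle, spike phase is linear in time
between the two borders (0° at the border). Note that the border estimate
carries up to ±10° of quantisation per recording; class comparisons of
spike phase should therefore be made within sessions, where the border
offset cancels (the pipeline's pooled table keeps a session column for
this purpose).

### Classification and incidence

Only spikes from cells with |PESI| = 1 at the linked bin are considered.
The mixed-pattern criterion is read symmetrically (≥ 2 specific cells per
environment), the stricter of the two possible readings, and the 2-vs-1
configuration is left unclassified rather than forced into a pure or
mixed category; both minima are configurable. Incidence is reported per
1000 theta cycles. The default aggregation divides total counts by the
total number of eligible locomotion cycles (equivalent to per-bin
normalisation under uniform dwell); a per-bin averaging mode is also
provided. Within-session trends use equal-duration thirds by default,
with fixed 150 s windows as an option.

### Decoding

The correlation decoder correlates the cycle's spike-count vector (counts,
not rates — Pearson correlation is scale invariant) against each bin's
template rate vector over the retained cell population, requiring ≥ 2
active cells; ties at the maximum resolve to the bin nearest the previous
decode, then the lowest index. Positional error is measured against the
current map for in-context cycles and the alternative map for out-context
cycles. The Bayesian decoder floors template rates at ε = 0.01 Hz so that
spikes from cells with a zero template rate do not produce −∞
log-likelihoods; the posterior is computed in log space and normalised
over all valid bins of both environments under a uniform prior, with
context detection at a strict marginal > 0.95.

### Permutation statistics

All empirical p-values use the (n + 1)/(N + 1) convention. The inter-event
interval statistic — the mean gap between consecutive out-context events,
ranked within 5000 uniform placements of the same event count — responds
to temporal *concentration* of events within the session; it is nearly
invariant to local pairing, because the mean consecutive gap is
approximately range/(n − 1). The theta-bin autocorrelation z-scores the
raw dot product against shuffles that relocate events within the
detection-eligible bins; because the lag-1 statistic is a small integer,
its one-sided p-value is conservative (super-uniform under the null)
rather than exactly uniform — the calibration test asserts validity
(P(p ≤ α) ≤ α), while the continuous statistics (interval test, both
clustering tests) are checked for full uniformity. Spatial clustering is
called only when both randomisations (track-shift within eligible
moments, and occupancy-matched draws from the alternative-context control
session on a 5×5 grid of 12 cm blocks) are significant. The
Watson–Williams circular ANOVA is implemented with the standard
κ-based correction (Fisher's A1-inverse); it warns when the within-group
mean resultant length drops below 0.45, where the F approximation
degrades — broad theta locking (resultant ≈ 0.4 at modulation depth 0.8)
sits near this edge, which is why the suite exercises the test's
type-I/power calibration directly.

## Synthetic data generator

The generator emulates the recordings the pipeline assumes: two 60×60 cm
environments sharing one arena, a 30-cell CA3-like population (12 cells
tuned only to A, 12 only to B, 6 with independent fields in both), 1–2
Gaussian place fields per active environment with σ = 6 cm and peak rates
uniform on 4–12 Hz. Fields are truncated to exact zero beyond 3σ so that
absolute context specificity (PESI = ±1) is attainable, matching the
sharp field boundaries that finite-session ratemaps display. Published
field-count/size statistics were not available for this preparation;
these are conventional values chosen once.

The trajectory is a 2-D Ornstein–Uhlenbeck velocity process (relaxation
3 s, stationary mean speed 10 cm/s) with a weak drift toward a foraging
goal resampled every ~8 s, integrated at the 40 ms tracking period with
reflecting walls; the goal term models crumb-chasing and gives the ≥ 90 %
arena coverage per 5-min template half that the pipeline requires. The
LFP is a cosine at 8 Hz with ±0.5 Hz slow drift, 10 % amplitude jitter
and broadband noise at 2 kHz. Spikes are inhomogeneous Poisson by
thinning: rate = tuning of the currently expressed map at the current
position × (1 + d·cos(φ − φ_pref)) with depth d = 0.8 and a shared
preferred phase of 180° (mid-cycle). The expressed map follows the cue
schedule; teleportation sessions switch cues every 40–60 s after 60–90 s
of free exploration.

### Flicker injection

Injected events are defined generatively: an injected cycle *is* an
expression of the alternative map. Candidate cycles are restricted to
theta-band cycles at detectable positions (eligible bins — by default the
ground-truth eligibility of the cell library; callers can supply the
template-estimated eligibility and specificity so that injected
expression involves cells the detector can recognise, which is what the
validation experiments do) with the animal moving. The target count is
rate × candidates / 1000, optionally weighted toward the session start by
an exponential profile (start/end ratio = `rate_decay`).

In a pure out-context cycle the original spikes are removed and counts
are drawn Poisson from the alternative map's tuning evaluated at a
position jittered by σ = 6 cm — out-context expression is spatially
noisier than in-context coding, which is what makes its positional error
larger; the magnitude is anchored to the reported error ratio of the
phenomenon. Draws are conditioned (rejection sampling, 50 attempts, then
forcing one spike in each of the two strongest specific cells) on ≥ 2
distinct alternative-specific cells firing, because a ground-truth event
must be an actually expressed pattern for sensitivity and incidence
recovery to be well defined. Mixed cycles keep the original in-context
spikes (topped up to two distinct in-context cells at the preferred phase
when the cycle is quiet) and superimpose out-context spikes. Injected
spike phases are von Mises with κ = 4 around the population preferred
phase plus an offset: +25° for pure out-context spikes and +90° for the
out-context component of mixed cycles — the same magnitudes the
phenomenon shows in vivo, used here as simulation conditions rather than
claims.

Default session rates mirror the in-vivo incidence tables: ~1.9 events /
1000 TC (31 % mixed) in baseline sessions and ~5.6 / 1000 TC (36 % mixed)
with a 3× within-session decay in post-teleportation sessions.

### What the synthetic validation shows — and what it does not

Passing recovery tests establishes that the chain of estimators
(templates → specificity → eligibility → cycle segmentation →
classification → decoding → statistics) is internally consistent: events
generated under the pipeline's own model assumptions are recovered at the
injected rate, with near-unit sensitivity, zero-level false positives and
the injected phase structure. Real recordings violate these assumptions
in ways the generator does not model: spike-sorting contamination,
non-Poisson spiking (bursts, refractoriness), phase precession, rate
remapping and slow representational drift, theta harmonics and
speed-dependent theta frequency, and sharp-wave/LIA epochs. Detection
sensitivity on real data is therefore not guaranteed by these tests, and
the in-vivo headline numbers are not reproducible from simulation — the
direction-of-effect checks (post > pre incidence, decaying within-session
trend, larger out-context positional error) are exactly that, direction
checks under injected conditions.

## Problem sizes used in the validation suite

Simulated validation uses 30 cells and 600 s sessions (the scale of one
recorded animal-day), with two baseline and two test sessions per
experiment; calibration tests use 200 repetitions with reduced shuffle
counts (199–300) and the Watson–Williams calibration 500 draws. These
sizes make every reported rate an average over several thousand theta
cycles while keeping the whole suite comfortably desk-scale.

## Known limitations

- The remapping-exclusion criterion is an operationalisation of a
  qualitative rule; its thresholds affect which cells enter the analysis.
- Eligibility estimated from 5-min template halves undershoots true
  eligibility (zero-rate estimates in under-sampled bins); incidence
  denominators are defined over *estimated* eligible cycles, so rates are
  comparable within an experiment but depend on template quality.
- The border of the theta cycle is quantised at 10°; phase comparisons
  across recordings inherit that offset.
- Group-level inference (mixed models, bootstrap confidence intervals)
  is out of scope by design: the pipeline exports tidy per-session tables
  for external statistics packages.
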