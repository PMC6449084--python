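# Methods

This note documents the models, algorithms and numerical choices behind
`zfswim`, and what the synthetic data generator does and does not
emulate. All defaults live in code (`SynthConfig` and function keyword
arguments), never hard-wired inside algorithms.

## Behaviour tracking

A grayscale movie of a larva swimming over a bright background is
reduced, frame by frame, to four quantities: head position, head
orientation φ_H, a 50-point midline, and the total body curvature K.

**Background and head.** The background is the pixelwise mean of 1000
temporally uniformly spaced frames. Each frame is background-subtracted
and sign-inverted (the fish is darker than the background, so the eyes
and swim bladder become the brightest structures), smoothed with a 2-D
Gaussian of 1 mm full width (σ = 0.5 mm; the width is configurable
because "1 mm wide" admits both readings), split with a two-level Otsu
threshold keeping the top class, and the connected blob of highest mean
intensity is reduced to its pixel centroid. A frame with no blob
standing more than 8 robust SDs above the smoothed noise floor raises
`FishNotFoundError` rather than returning a guess.

**Body segmentation.** The full-body mask comes from an iterative
two-class intensity split: Otsu's threshold seeds a Ridler–Calvard
iteration (threshold = midpoint of the two class means) run until the
foreground count changes by <1%, followed by area sanity bounds and a
largest-component selection. The aim is to keep as many genuine body
pixels as possible — the thin tail matters for curvature — while
excluding the noise floor. Pre-smoothing before segmentation is
supported but off by default: it measurably erodes the tail (the
extracted K of a 90° bend drops from ~88° to ~69° as the smoothing σ
goes from 0 to 1 px) without improving stability.

**Midline.** The mask is thinned to a skeleton; the skeleton's main
chain is the longest path between endpoints (side branches longer than
12 px raise `BranchingSkeletonError`). Binary thinning has two
pixel-level pathologies that the subsequent steps correct explicitly:

* its tips hook toward mask corners and stop short of the body ends, so
  4 px are trimmed at each end and the chain is then extended straight
  along its end tangents until the mask boundary — the endpoints are
  thereby defined by the (sub-pixel-stable) body outline rather than by
  thinning idiosyncrasies;
* chain pixels are integer-valued, so each is recentred *along its
  local normal* at the 1-D intensity centroid across the body
  (half-width 0.35 mm). Restricting the pull to the normal keeps bends
  and chain ends unbiased; a full 2-D window drags end points into the
  body.

The refined chain is fit with a least-squares cubic spline with
interior knots every 0.9 mm of arc (enough to average sub-pixel jitter
without distorting the bend; the knot count is capped so each interval
keeps ≥4 data points) and resampled at 50 points equally spaced in arc
length, head first.

**Angles.** Tangent angles along the midline use central differences in
the interior and local quadratic least-squares fits over the outer 9
points at the two ends — exact on smooth arcs (a 50-point midline on a
90° circular arc recovers K = 90° to <0.1°) while averaging the
endpoint noise that a 3-point one-sided difference amplifies. Local
curvature is the angle difference between adjacent tangents; the
cumulative sum from the head gives angles-vs-head and K is the signed
total. φ_H is the direction of the total-least-squares line through the
10 points nearest the head, oriented from the far end of the line
toward the head. Coordinates are (x, y) in mm, origin at the top-left
pixel, y down; angles are degrees from +x.

Continuous-geometry invariances (rotation equivariance of φ_H,
invariance of K under rotation, scaling and reflection-negation) hold
exactly and are tested on analytic midlines. Through the image
pipeline, binary thinning is *not* exactly equivariant under 90° pixel
rotations (the rotated mask is identical; the skeleton is not), which
perturbs K by ~3° on a 90°-bent body; the image-level test tolerance
reflects that measured raster effect.

## Swim episodes and bends

K(t) is zero-phase low-pass filtered at 70 Hz (4th-order Butterworth,
`sosfiltfilt`). |K(t)| convolved with a unit-area Gaussian of 200 ms
FWHM (truncated at ±3σ) gives the envelope S(t). An episode starts
where S(t) crosses and stays above 4° for at least 50 ms and ends at
the start of the next ≥50 ms sub-threshold run.

**Onset refinement.** The 200 ms smoothing blurs the onset: the raw
threshold crossing is early by an amplitude-dependent margin (0–120 ms
across categories), and the nearest preceding local maximum of d²S/dt²
— the foot of the envelope rise — leads the true onset by approximately
one kernel σ (85 ms), with category-dependent spread. (For an onset
that is abrupt at the kernel's timescale, the preceding S″ maximum of a
Gaussian-smoothed step sits exactly σ before the edge; we verified the
offsets numerically on labelled synthetic mixtures.) The default
refinement therefore anchors the onset on the signal that still has the
temporal resolution: within a 250 ms window around the coarse onset it
finds the first sustained activity of the filtered curvature itself —
|K| above max(1°, 5% of the episode's peak curvature; the relative term
keeps the zero-phase filter's pre-ringing below the floor for large
episodes) for 8 ms. On labelled synthetic mixtures this recovers ≥98%
of onsets within ±10 ms. The literal S″-peak rule and a σ-corrected
variant remain available via `onset_refinement="d2" / "d2_corrected"`.

**Bends.** Bends are the alternating-sign local extrema of the filtered
curvature inside an episode, gated by a 2° prominence floor (below the
4° episode threshold, above tracking noise). Bend metrics follow
A(1) = |K(t₁) − K(t_on)|, P(1) = t₁ − t_on; for n > 1 the default
*contiguous* convention assigns bend n the interval ending at its peak,
A(n) = |K(tₙ) − K(tₙ₋₁)| and P(n) = tₙ − tₙ₋₁, so bends tile the
episode; the alternative convention that indexes bend n by the
*following* interval is available behind `indexing="printed"`. Bend
metrics default to the filtered series (the same series the episode
bounds came from); the raw series can be passed when exactness matters
more than denoising.

**Global parameters** per episode: summed frame-to-frame displacement
of the body point at 35% of midline arc length (just caudal to the swim
bladder — chosen because the head oscillates during escapes), duration,
mean and maximum velocity (central differences at the native frame
rate, no extra smoothing), bend count, maximum |dK/dt|, and — when a
stimulus time is supplied — onset latency.

## Swim categorisation and stereotypy

Spontaneous episodes are sorted by first-bend amplitude with a 1-D
Gaussian mixture fit for k = 1..6; the model minimising
AIC = 2(3k−1) − 2 log L (k means, k SDs, k−1 free weights) is kept, and
components sorted by ascending mean map to scoot < routine turn <
high-angle turn. Escapes are stimulus-evoked and never enter the
mixture.

The EM settings are part of the model-selection behaviour and deserve a
note. With aggressive optimisation (many restarts, tolerance 1e-6) a
spurious extra component reliably realises the ~2–4 log-likelihood
units it can always find in a finite sample, and AIC then overselects k
on data that is an *exact* k-component mixture (k = 4 chosen in ~half
of draws at n ≈ 6000). At scikit-learn's standard settings (k-means
initialisation, tolerance 1e-3, ≤100 iterations, a few restarts) those
marginal gains are not realised and the AIC minimum sits at the
generating component count in every seed we tested. The defaults follow
the standard settings; restarts and tolerance are keyword-configurable.

Within-category curvature traces are aligned by integer-frame lags
against an iteratively updated mean template (±50 ms search); escape
traces, whose beat frequency is strongly chirped, are correlated only
over the first 80 ms after onset. Returned lags are corrective
(`np.roll(trace, lag)` aligns).

Bend-timing stereotypy: for each adjacent bend pair (n, n+1) up to the
10th bend, the AUC is the Mann–Whitney statistic P(t_{n+1} > t_n) with
ties counted ½ over the two peak-time samples; both the raw AUC and the
directionless discriminability max(AUC, 1−AUC) are reported.

Normality gating for parametric modelling uses the R² of a straight
line fit to the normal Q-Q plot at plotting positions (i−0.5)/n, with
pass at R² > 0.8 (log-transforming latency-like quantities and
re-testing is the intended workflow).

## Fictive swimming and whole-cell metrics

Ventral-root channels (6 kHz) are transformed with a 10 ms moving
sample SD (centred; edges use the available samples; ddof = 1).
Episodes are runs where either side exceeds a threshold, merged across
gaps <50 ms and discarded below 20 ms (noise blips). The default
threshold — a stand-in for a threshold the experimenter would pick by
eye — is the quiescent noise floor (location = 25th percentile, scale
from q50−q25 of a Gaussian, valid while swimming occupies <50% of the
record) plus 4.5 noise SDs. Burst peaks are local maxima of the
processed signal at ≥8 ms separation after a 3 ms Gaussian smoothing
(the windowed-SD envelope of a short burst is double-humped: the SD is
larger when the window straddles the burst edge than when it covers the
whole packet). Cycle frequencies are reciprocals of successive burst
intervals on the dominant side; cycles are classed fast (>35 Hz) or
slow (<35 Hz).

Weak/strong classification fits a two-component Gaussian mixture to the
log maximum burst amplitudes; the lower-mean component is the weak
spontaneous regime and the cutoff is the amplitude with <0.1%
probability under it, exp(μ_weak + 3.0902 σ_weak). Two consequences are
worth stating. First, the rule *by construction* labels any >3.09σ weak
draw as strong, so perfect label recovery is only meaningful when the
generating regimes are bounded; the schedule generator truncates its
amplitude draws at ±2.5 SD so each episode's nominal label is its
Bayes-optimal label. Second, when a session contains no strong swims a
forced two-component fit splits the single regime arbitrarily and puts
the cutoff inside the bulk of the data; the classifier detects heavy
component overlap (|μ₂−μ₁| < 1.5(σ₁+σ₂)) and falls back to the pooled
mean/SD, which restores the intended ≤0.1% tail behaviour.

Whole-cell sweeps: spikes are upward threshold crossings with a 1 ms
refractory window; subthreshold depolarisation per cycle is the peak of
the 60 Hz low-passed trace minus the minimum voltage in the 200 ms
before swim onset (truncated with a warning if the onset is earlier).
Input resistance averages ΔV/I over ≥5 hyperpolarising steps, with ΔV
from the mean of the last 20% of each step against a 50 ms pre-step
baseline; mV/pA is converted to MΩ.

## Calcium regression

Movies are T×Z×Y×X at 2 Hz. Motion correction finds, per volume, the
integer 3-D shift maximising the cross-correlation against a reference
volume (FFT; shifts beyond a configurable bound are flagged), and
applies it with edge-value filling. ΔF/F uses the ROI-mean trace with
F₀ = the bottom 20th percentile of the whole series. Event-triggered
averages align ΔF/F at swim onsets, drop events whose window leaves the
record (reporting the count), and take the peak of the mean trace.

Regressors convolve a fictive motor signal with the GCaMP6s impulse
response h(t) = (1 − e^(−t/0.5 s)) e^(−t/2 s), unit-peak normalised
(closed-form peak at t* = τ_r ln(1 + τ_d/τ_r) ≈ 0.80 s); a
difference-of-exponentials form is selectable since both reproduce the
stated time constants. The convolution runs at the trace resolution
with steady-state edge padding (a constant signal convolves to an exact
constant, making the affine-invariance of the standardised regressor
exact and the zero-variance error well defined), is sampled at the
volume times, and is z-scored. The voxel GLM is ordinary least squares
of Y = Xβ + ε per voxel with an intercept always included (regressors
are standardised but Y is not centred); t = β̂/SE(β̂) with T − p − 1
degrees of freedom and two-sided p values (activity decreases are as
meaningful as increases). Multiple comparisons are controlled with
Benjamini–Hochberg over all voxels jointly at q = 0.05.

## Synthetic data: what it emulates, and what it does not

The generator provides ground-truth-labelled inputs for every stage.

* **Kinematics.** An episode is a train of alternating-sign half-sine
  curvature lobes whose first peak equals the drawn first-bend
  amplitude and whose peaks decay by 0.95 per half-beat; lobe
  boundaries snap to the sampling grid so recorded bend times and
  amplitudes are exact. Spontaneous categories arrive Poisson-like at
  0.5 /s with weights 0.672/0.265/0.064 (scoot/routine turn/high-angle
  turn — the relative category frequencies observed in real spontaneous
  swimming) and first-bend amplitude components N(20°, 4.5°),
  N(50°, 8°), N(95°, 11°), truncated at 0. The means/SDs are free
  parameters chosen once for the canonical ordering with ~4.5σ
  separations, and such that essentially all category mass is
  detectable by the 4° envelope rule — a coherence requirement, since
  the real mixture is a distribution over *detected* episodes. Escapes
  (N(155°, 20°), 55–70 Hz) occur only after a stimulus, with ~12 ms
  latency. Heading ramps during turns and forward speed is proportional
  to the instantaneous beat amplitude × frequency.
* **Rendering.** A fixed 2-D body of 4 mm with a width profile widest
  near the swim bladder and a tail tip of 0.14 mm (≈2.5 px at the
  0.057 mm/px scale — a sub-pixel tail would make the mask's caudal end
  unresolvable), darkest at the head, over a flat bright background
  with i.i.d. Gaussian sensor noise (SD 8 on a 0–255 scale). Edges are
  anti-aliased over one pixel, standing in for optical blur; without
  it, hard binary edges quantise away the sub-pixel information every
  tracker relies on. Curvature is distributed over the caudal 65% of
  the body with a smoothstep weight (the head and swim-bladder region
  is stiff), so the curve's summed tangent rotation equals K exactly.
* **Fictive traces.** Bursts are rectified 300 Hz tone packets of 5 ms
  (matching the 100–1000 Hz band-passed character of the recordings),
  anti-phase across channels, scaled so the windowed-SD transform of a
  noiseless burst peaks at the scheduled amplitude. Weak episodes beat
  at 15–30 Hz, strong at 40–60 Hz, straddling the 35 Hz boundary;
  amplitude regimes default to 1.0 ± 0.2 and 8 ± 1.6 (a.u.).
* **Calcium movies.** Responding voxels carry baseline 100 +
  amplitude × (signal ⊛ kernel, unit-peak) + noise, with noise set by
  the configured SNR 5 (peak response / noise SD); the truth mask is
  exact.
* **Vm sweeps.** Resting −65 mV, per-cycle raised-cosine depolarisation
  bumps from a recruitment rule, triangular ~1.5 ms spikes inserted
  when the bump would cross threshold, passive RC responses
  (R = 100 MΩ, C = 100 pF by default) to current steps.

Not emulated — and therefore not demonstrated by passing tests:
hydrodynamics and 3-D posture, photorealistic appearance, occlusions or
reflections at arena walls, non-stationary backgrounds, burst-shape
biophysics beyond threshold bumps, bleaching/drift in fluorescence, and
correlated (shot/readout-structure) imaging noise. Recovery rates on
synthetic data bound what the algorithms can do when their model
assumptions hold; real recordings will be harder in ways the generator
does not represent.

## Problem sizes

The shipped tests and analysis scripts run on sizes chosen to exercise
the statistics honestly at desk scale: 600 s behaviour records
(~200–230 episodes) for detection, n = 6056 amplitudes for the mixture
fit, 40–60 episode fictive sessions, 240-volume calcium movies with
10,000 voxels and 100 responders, and 10-seed repetitions for the
calibration checks.
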