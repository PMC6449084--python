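# zfswim

Analysis pipeline for larval zebrafish locomotion and its hindbrain
correlates: video-based midline and body-curvature tracking,
swim-episode detection with bend-by-bend kinematics, Gaussian-mixture
categorisation of spontaneous swims, ROC-based stereotypy statistics,
fictive (ventral-root) swim-burst analysis with weak/strong
classification, cycle-wise whole-cell recruitment metrics, and
voxelwise calcium-imaging regression maps — together with a
synthetic-data generator that produces ground-truth-labelled inputs for
every stage, so the whole chain is testable without any recording.

## The measurements

**Behaviour.** Each video frame is reduced to the head position (blob
centroid after background subtraction, inversion and 1 mm Gaussian
smoothing), a 50-point midline C (skeletonise → intensity-weighted
refinement → spline), the head orientation φ_H (line fit to the 10
points nearest the head) and the total body curvature
K = Σ local tangent-angle differences along C (degrees, signed).

**Episodes.** With S(t) = |K(t)| ⊛ (200 ms Gaussian) after a 70 Hz
low-pass, an episode starts where S crosses and stays above 4° for
50 ms. Bend n has amplitude A(n) = |K(tₙ) − K(tₙ₋₁)| (A(1) against the
onset) and period P(n) = tₙ − tₙ₋₁. Spontaneous episodes are sorted by
first-bend amplitude with a 1-D Gaussian mixture, k selected by
AIC = 2(3k−1) − 2 log L; bend-timing stereotypy of adjacent bends is
the Mann–Whitney AUC of their peak-time distributions.

**Fictive swimming.** Ventral-root channels are transformed with a
10 ms windowed SD; per-episode maximum burst amplitudes are
log-transformed, fit with a 2-component Gaussian mixture, and episodes
above the weak component's 0.1% tail (μ + 3.0902σ in log space) are
strong swims. Cycle frequencies are reciprocals of burst intervals,
classed fast/slow at 35 Hz.

**Calcium maps.** Voxel time courses Y are fit by OLS, Y = Xβ + ε,
against regressors built by convolving fictive motor signals with the
GCaMP6s impulse response (1 − e^(−t/0.5 s)) e^(−t/2 s) and z-scoring;
t-maps are thresholded at a Benjamini–Hochberg FDR of q = 0.05.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

The `analysis/` scripts run the full chain on synthetic data and write
tables under `results/`. In order:

```sh
python analysis/01_synthesize_behavior.py
python analysis/02_track_video.py
python analysis/03_swim_episodes.py
python analysis/04_classify_swims.py
python analysis/05_fictive_bursts.py
python analysis/06_calcium_maps.py
```

Representative output (abridged):

```
generated 225 episodes over 600 s: {'escape': 9, 'high_angle_turn': 11,
                                    'routine_turn': 52, 'scoot': 153}
tracked 1000/1000 frames
median |K error|   : 2.26 deg
median |phi error| : 0.62 deg
detected 219 episodes vs 225 true
onsets within ±10 ms of truth: 97.3%
AIC selected k=3; means=[19.9 49.8 95. ] deg, weights=[0.66 0.275 0.065]
category assignment accuracy vs generator truth: 99.1%
adjacent-bend AUC: {'1-2': 1.0, '2-3': 0.955, '3-4': 0.935, '4-5': 0.839, ...}
detected 60/60 episodes; strong/weak cutoff = 1.67 a.u.
label accuracy vs schedule: 100.0%
median cycle frequency: weak 21.9 Hz, strong 51.7 Hz (boundary 35 Hz)
input resistance from 5 hyperpolarising steps: 100.0 MΩ
FDR map (q=0.05): 107 voxels; sensitivity 100.00%, realised FDP 6.54%
```

Reading these numbers: tracking recovers curvature to a couple of
degrees and heading to well under a degree on noisy frames; episode
detection finds essentially every generated bout and places onsets at
millisecond accuracy (the six missed bouts are low-amplitude scoots
below the 4° envelope threshold); AIC identifies the three spontaneous
swim categories and the per-episode labels match the generating
component 99% of the time; the fictive classifier separates weak from
strong swims exactly at the configured amplitude regimes; and the
voxelwise FDR map recovers every implanted responder while keeping the
realised false-discovery proportion near the nominal 5%.

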