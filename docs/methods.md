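# Methods

This note documents the models, numerical choices and deliberate design
decisions behind gaitloop, and what the synthetic-data validation does and
does not demonstrate.

## Coordinate conventions

Pose CSVs use image coordinates (y grows downward), the three-header-row
dialect (scorer / bodyparts / coords) of common markerless pose tools, and
0-based frame indices at a default 156 frames/s. All joint angles are angles
between vectors, hence independent of axis orientation, translation,
rotation and uniform scale; a checkerboard calibration (scalar mm-per-pixel)
therefore never changes an angle. The single orientation-dependent quantity
is the pendulum angle — the hip→MTP axis against the downward vertical,
positive toward the direction of travel — so the travel direction (+x or
−x in the image) is a session flag rather than an assumption.

## Event detection

Stance onsets are local maxima of the smoothed pendulum angle (touch-down at
maximal protraction), swing onsets local minima (lift-off at maximal
retraction). Three parameters, all config keys:

* smoothing: centred moving average, default 5 frames (~32 ms at 156 fps);
* refractory period: same-sign extrema closer than 60 ms are duplicates and
  the more extreme one is kept (60 ms ≈ half the shortest physiological
  swing);
* prominence floor: peaks must rise at least 0.2 of the trace's 5–95
  percentile span above their surroundings. Smoothing alone leaves
  low-amplitude jitter wiggles on the slow stance-phase retraction; without
  a prominence criterion those wiggles can pair up with noise minima,
  survive the refractory guard, and split cycles. A relative prominence
  floor is the standard peak-picking remedy and leaves noise-free traces
  untouched.

Alternation is enforced after merging (exactly one swing onset between
consecutive stance onsets); cycles whose local alternation is violated are
skipped rather than guessed. Durations are frame counts × 1000/fps, so all
recovered durations are quantised to the 6.41 ms frame period.

Detection at pendulum extrema (rather than velocity sign changes) is robust
to belt-speed drift; frames with likelihood below 0.8, or degenerate
geometry, are abnormal and override any phase label, and a cycle containing
any abnormal frame fails QC and is excluded from all statistics.

## Metrics and statistics

Duty factor is computed per cycle and then averaged per animal
(mean of ratios); the ratio-of-means variant is available but not the
default. Group statistics are means/SDs over per-animal means — cycles are
never pooled across animals, which would pseudoreplicate. Welch's unpaired
*t*-test (unequal variances, Welch–Satterthwaite df) operates on group
summary statistics; the p-value is two-sided. Normalised cycles use a
101-point 0–100 % grid (grid size is a convention; the data do not fix it)
with linear interpolation, and averaging across cycles is pointwise.

## Synthetic gait generator

The generator emulates treadmill sessions of two groups, sham and spinal
cord injured (SCI), with these defaults:

* temporal: cycle duration ~ N(438.87, 51.62²) ms sham, N(295.36, 45.34²) ms
  SCI; per-cycle duty factor ~ N(67.14, 0.76²) % sham, N(67.66, 1.89²) % SCI;
  all truncated at ±3 SD and at two frame periods. Cycle duration and duty
  factor are the jointly drawn pair, with stance = duty × cycle, so the
  recovered duty factor has the configured mean by construction. Drawing
  stance and cycle independently instead would inflate the mean per-cycle
  duty factor by the Jensen term E[1/c]·E[s] ≈ +1.9 points, which is why
  that parameterisation was rejected.
* dispersion interpretation: group SDs are applied as *per-cycle* dispersion
  and every virtual animal shares the group mean (inter-animal SD of means
  defaults to 0, exposed as `inter_animal_sd_ms`). With only 3 animals per
  group, putting the full printed dispersion between animals would make the
  cohort mean itself fluctuate by ±18 ms and no fixed-size recovery band
  could be guaranteed; parameter-recovery validation targets the pipeline,
  not inter-animal biology, so the variance is placed within animals.
* joint-angle templates: per-joint keypoints over the normalised cycle
  (ankle: stance-onset 88.48°, maximum 118.30° at end of stance, minimum
  74.37° at mid-swing for sham; 73.67°/76.42°/42.32° for SCI; hip rises then
  falls in sham early stance and initially falls in SCI; knee falls then
  rises), interpolated with shape-preserving PCHIP splines so extrema are
  attained exactly at keypoints and never overshot, then time-warped to each
  cycle's own stance/swing split and jittered (default SD 1°).
* pendulum: +20° at stance onset to −20° at swing onset. Each extremum sits
  in a symmetric parabolic neighbourhood (half-width 30 ms, 20 % of
  amplitude) joined by monotone cubic Hermite arcs. The symmetry is
  deliberate: a symmetric smoothing kernel applied to an asymmetric peak
  (the stance lobe is ~2× flatter than the swing lobe) displaces the
  detected extremum toward the flatter side by up to a frame per boundary,
  systematically biasing stance durations; locally symmetric extrema remove
  that bias by construction.
* landmark emission: a 2-D chain with segment lengths 8/15/16/9 mm
  (crest–hip, hip–knee, knee–ankle, ankle–MTP — plausible mouse values;
  they affect geometry only, never angles) posed from the joint angles with
  alternating flexion sides, then rigidly rotated about the hip to realise
  the prescribed pendulum angle (rigid rotation preserves all joint angles),
  on a slowly orbiting hip anchor. Recovered angles equal the generating
  angles to 1e−6° on noise-free frames.
* abnormal bouts: Poisson starts (default 0.02 /s), 0.5–1.5 s long; at least
  two landmarks are displaced by a *minimum-offset* annulus perturbation
  (0.8–2× of 10 mm) and their likelihoods dropped to [0.2, 0.6]. The
  guaranteed offset makes abnormal poses geometrically separated from normal
  gait, which is what lets a 3-feature classifier reach near-perfect
  abnormal recall; Gaussian perturbations were rejected because their small
  draws produce abnormal-labelled frames with normal geometry, capping
  recall around 86 %.

What the generator does *not* emulate: real pose-estimator error structure
(correlated, heteroscedastic, occlusion-driven), belt slip, bilateral or
forelimb coordination, inter-animal kinematic idiosyncrasies, and video
itself. Consequently, pipeline accuracies measured on synthetic sessions
(e.g. classifier validation accuracy ≈ 0.98, abnormal recall ≥ 0.99,
runtime agreement ≥ 0.99) characterise correctness of the machinery under
the generative model, not expected performance on animal video, which is
known to be substantially lower for real recordings.

## Classifier

The 3–32–32–3 MLP is implemented directly in numpy: the network is ~1.3 k
parameters and the explicit forward pass doubles as the reference for what
would run on a microcontroller. Loss is categorical cross-entropy (forced by
the softmax-classification framing); optimiser Adam with conventional
defaults (1e−3, β₁ 0.9, β₂ 0.999), batch 128, up to 300 epochs, early
stopping on validation loss (patience 25) with restoration of the best
checkpoint. Inputs are z-scored per feature with statistics from the
training split, stored with the model; a raw-degrees mode
(`scale_inputs=False`) is kept for parity with deployments that feed raw
angles. The 80/20 split is a seeded uniform shuffle; class proportions are
deliberately left at their natural imbalance (stance is inherently the
longest phase). Models serialise to self-describing JSON with bit-exact
weights.

## Stimulation and runtime

The softmax post-processing is argmax plus an N-frame debounce (default 2):
a new stance/swing candidate must persist N consecutive frames, while an
abnormal candidate switches immediately and lowers both indicator lines —
safety demands that stimulation stops at once when tracking is unreliable,
but may tolerate two frames of lag when it starts. Pulses are synthesized on
a 1 MHz grid (200 µs phases are then exactly 200 samples): negative phase
first, then positive, each at the configured DAC level, summing to exactly
zero. While a phase persists, pulses repeat at the configured frequency
(default 100 Hz, `phase_locked` mode; a `fixed_duration` burst mode is also
provided since onset-triggered recordings do not fully disambiguate the
two). A pulse only starts if it can complete before the phase ends — trains
truncate between pulses, never mid-pulse.

The streaming runtime consumes frames strictly in order with no lookahead;
offline pendulum-based labelling (used to build training sets) and runtime
classifier-driven state are deliberately separate paths. Serial transport is
modelled analytically: n_bytes × 10 bits (8N1 framing) / baud, giving
0.23 ms for the fixed 21-byte ASCII angle frame ("DDD.DD,DDD.DD,DDD.DD\n")
at 921,600 bps and 1.82 ms at 115,200 bps. Reported latencies are labelled
simulations; wall-clock stage timings depend on the host and are not claims
about embedded hardware.

## Problem sizes and determinism

Validation workloads are sized for a laptop-class single core: recovery
cohorts use 3 virtual animals × 180 s (≈400 cycles each), classifier
training material 2 × 30 s sessions, and the complete test suite runs in
well under a minute. All randomness flows through numpy Generators seeded
from explicit config fields; identical config and seed give byte-identical
session files, metrics and waveforms.

## Known limitations

* The pendulum-angle labelling defaults (smoothing, refractory, prominence)
  are this package's choices; published pendulum methods do not fix them.
* 2-D sagittal kinematics only; no stride length in world units beyond the
  scalar calibration, no 3-D or bilateral modelling.
* The Welch test on 3 + 3 animals has very low power; it is provided for
  workflow parity, not as an endorsement of n = 3 inference.
* DAC levels are abstract amplitude units; mapping to current or charge
  density, electrode impedance and tissue safety limits are out of scope.
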