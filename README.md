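# gaitloop

Desk-scale simulation and analysis toolkit for closed-loop, gait-phase-triggered
neuromodulation in mice. It covers the full signal path of a vision-based
closed-loop stimulation system: hindlimb landmark trajectories (as produced by
markerless pose estimation on treadmill video) → joint angles → stance / swing /
abnormal labelling → spatiotemporal gait metrics → a lightweight phase
classifier suitable for microcontroller deployment → phase-locked,
charge-balanced biphasic stimulation waveforms. A synthetic gait generator with
full ground truth stands in for animal video, so every stage can be validated
end to end.

Intended users: neuroengineering and motor-systems labs prototyping
phase-triggered stimulation controllers, and anyone post-processing
DeepLabCut-style landmark CSVs of rodent treadmill locomotion.

## The science in brief

**Kinematics.** Five hindlimb landmarks are tracked per frame: iliac crest
(P1), hip (P2), knee (P3), ankle (P4) and metatarsophalangeal joint (P5).
Joint angles are interior angles by the vector-cosine method,
θ = arccos(u·v / |u||v|), with the hip angle at P2 (rays to P1, P3), knee at
P3 (P2, P4) and ankle at P4 (P3, P5). Frames where any landmark's pose
likelihood falls below 0.8 are unreliable and labelled *abnormal*.

**Gait events.** The limb axis hip→MTP behaves like a pendulum: its signed
angle from the vertical peaks at touch-down (maximal protraction = stance
onset) and bottoms at lift-off (maximal retraction = swing onset). Cycles run
stance-onset to stance-onset; the stance duty factor is
100 × stance / cycle duration. Cycles containing any unreliable frame are
excluded from statistics, and animals — not cycles — are the biological
replicates (Welch's *t*-test on per-animal means).

**Phase classifier.** A 3–32–32–3 multilayer perceptron (ReLU hidden layers,
softmax output, 1283 trainable parameters) maps one frame's
(hip, knee, ankle) angles to a posterior over {stance, swing, abnormal};
trained with Adam (batch 128, ≤300 epochs, early stopping on validation
loss with best-checkpoint restore).

**Stimulation.** Detected phases trigger symmetric biphasic pulses (negative
then positive phase, 200 µs each, zero net charge) at 100 Hz on a 12-bit DAC
amplitude scale (4096 levels); one channel serves stance, the other swing,
with reciprocal indicator lines and an immediate abnormal override that
silences both — no stimulation during unreliable tracking.

## Worked example

`examples/` contains one short script per capability. The first generates
sham and spinal-cord-injured (SCI) cohorts and measures their gait:

```sh
$ python examples/01_simulate_and_measure_gait.py
sham: stance 292.0 ms, cycle 435.0 ms, duty factor 67.10 % (n=3 animals)
sci: stance 197.4 ms, cycle 292.0 ms, duty factor 67.63 % (n=3 animals)
stance_ms reduced by 32 % after injury
cycle_ms reduced by 33 % after injury
swing_ms reduced by 34 % after injury
stance duration sham vs sci: t=31.54, df=2.8, p=0.0001
```

Injury shortens every temporal parameter by about a third while the duty
factor — the fraction of the cycle spent in stance — is preserved, the
signature pattern of faster but structurally similar stepping. The other
examples train the classifier (`02`, prints validation accuracy and
abnormal-frame recall), stream a held-out session through the closed loop
(`03`, prints runtime-vs-ground-truth agreement and pulse counts), and
synthesize stimulation waveforms (`04`, prints pulse shape and measured
rate). A thin CLI wraps the same functions:
`gaitloop simulate|label|analyze|train|run|stim-demo --help`.

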