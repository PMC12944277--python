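"""Synthesize phase-triggered biphasic stimulation waveforms.

Pulses are symmetric biphasic (negative then positive phase, 200 us
each) at 100 Hz, amplitude on a 12-bit DAC scale (4096 levels); one
channel fires during stance, the other during swing, and abnormal
segments silence both.
"""

import numpy as np

import gaitloop as gl
from gaitloop.gait_events import PhaseLabel

config = gl.StimConfig(amplitude_level=1000)
pulse = gl.synth_pulse(config)
print(f"one pulse: {len(pulse)} samples at 1 MHz "
      f"({(pulse != 0).sum()} nonzero), sum = {pulse.sum():.0f} (charge balance)")

# a gait-like timeline: 300 ms stance / 150 ms swing, with one abnormal bout
fps = 156.0
timeline = ([PhaseLabel.STANCE] * 47 + [PhaseLabel.SWING] * 23) * 6
timeline[150:180] = [PhaseLabel.ABNORMAL] * 30

for channel in ("stance", "swing"):
    train = gl.schedule_train(timeline, fps, config, channel)
    intervals = train.inter_onset_intervals_s()
    within = intervals[intervals < 1.5 / config.frequency_hz]
    print(f"{channel} channel: {len(train.pulse_onsets_s)} pulses, "
          f"intra-phase interval {within.mean() * 1000:.1f} ms "
          f"(= {1000 / config.frequency_hz:.0f} ms at {config.frequency_hz:.0f} Hz)")

# one second of sustained stance gives exactly the pulse rate
train = gl.schedule_train([PhaseLabel.STANCE] * int(fps), fps, config, "stance")
rate = 1.0 / np.mean(train.inter_onset_intervals_s())
print(f"sustained stance: {len(train.pulse_onsets_s)} onsets/s, "
      f"measured rate {rate:.1f} Hz")
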