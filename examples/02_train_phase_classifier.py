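"""Train the lightweight gait-phase classifier on synthetic sessions.

The model is a 3-32-32-3 multilayer perceptron (1283 parameters): one
frame's hip/knee/ankle angles in, a posterior over stance / swing /
abnormal out.  Abnormal frames come from simulated tracking dropouts.
"""

import numpy as np

import gaitloop as gl
from gaitloop import kinematics

sessions = []
for group, seed in [("sham", 11), ("sci", 12)]:
    cfg = gl.GaitGenConfig(group=group, duration_s=30.0, seed=seed,
                           abnormal_rate_per_s=0.05)
    session, truth = gl.generate_session(cfg)
    sessions.append((kinematics.angles_from_session(session), truth.labels))

dataset = gl.build_dataset(sessions, seed=0)
print(f"dataset: {len(dataset)} frames "
      f"({int(dataset.train_mask.sum())} train / {int(dataset.val_mask.sum())} val)")
print(f"class counts (stance, swing, abnormal): {np.bincount(dataset.labels)}")

model, history = gl.train(dataset, epochs_max=80, batch=128, seed=0)
print(f"parameters: {gl.count_parameters(model)}")
print(f"trained {len(history)} epochs; "
      f"validation accuracy {history.val_acc[-1]:.3f}")

probs = model.forward(dataset.features[dataset.val_mask])
pred = probs.argmax(axis=1)
y = dataset.labels[dataset.val_mask]
recall = np.mean(pred[y == 2] == 2)
print(f"abnormal-frame recall: {recall:.3f} "
      "(missed abnormal frames would stimulate during unreliable tracking)")

gl.phase_classifier.serialize_model(model, "phase_model.json")
print("model saved to phase_model.json")
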