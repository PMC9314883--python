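"""Train the 2.5D multi-decoder network on synthetic subjects and segment
a held-out one.

Uses the scaled-down study conditions (64^3 phantoms, base_features 4,
4 pooling steps); training three orientations takes a couple of minutes
on one CPU.  Prints per-tissue Dice on the held-out subject.
"""

import numpy as np

from persardose import evaluate_segmentation, fuse_2p5d, predict_volume, train
from persardose.study import StudyConfig, make_subject

cfg = StudyConfig(n_subjects=3, seed=0)
subjects = [make_subject(cfg, i) for i in range(cfg.n_subjects)]

held_out = 0
train_vols = [(img, lab) for i, (lab, img) in enumerate(subjects) if i != held_out]
nets, history = train(train_vols, cfg.train_config(cfg.seed), cfg.network_spec())
for orientation, h in history.items():
    print(f"{orientation}: train loss {h['train_loss'][0]:.3f} -> {h['train_loss'][-1]:.3f}")

gt, image = subjects[held_out]
probs = predict_volume(nets, image)
pred = fuse_2p5d(probs["transverse"], probs["coronal"], probs["sagittal"], gt.voxel_size)
result = evaluate_segmentation(pred, gt)
print("held-out per-tissue Dice:")
for name, value in result["per_class"].items():
    print(f"  {name:13s} {value:.3f}")
print(f"mean Dice {result['mean']:.3f} +/- {result['sd']:.3f}")
# Dice is the overlap 2|A&B|/(|A|+|B|); 1.0 is a perfect segmentation
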