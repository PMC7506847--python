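"""Localize the class-discriminative region of a fall window with CAM.

The class activation map weights the last conv layer's channel sequences
by the head's fall-class weights.  Normalized to [0, 255] and upsampled
to the 100-frame input, high intensities ("yellow" in a hot map) mark the
frames the classifier relies on — for falls, the weightless early-fall
region rather than the impact spike.
"""

import numpy as np

import fallcam as fc
from fallcam.cnn import CLASS_FALL

windows = fc.make_training_windows(60, 60, fs=50.0, seed=4)
train_w, test_w = fc.split_windows(windows, ratio=2.3, seed=4)
model = fc.train(fc.build_classifier(seed=4), train_w,
                 fc.TrainSpec(epochs=10, seed=4), val_windows=test_w)

fall_win = next(w for w in test_w if w.label == "fall")
amap = fc.activation_map(model, fall_win, CLASS_FALL)

print(f"raw map length L = {len(amap.raw)} (temporal positions after conv3)")
print(f"normalized range: {amap.normalized.min()}..{amap.normalized.max()}")
runs = fc.contiguous_highlight(amap.upsampled, intensity_threshold=200)
for a, b in runs:
    print(f"highlighted run: frames [{a}, {b}) = {(b - a) / 50.0:.2f} s")
print("(the dominant run marks the early-fall weightless region the "
      "threshold detector was calibrated on)")

# the CAM identity: the temporal mean of the raw map is the logit - bias
fm, _ = fc.forward(model, fall_win)
print(f"mean(M_fall) = {amap.raw.mean():.4f}  vs  "
      f"g_fall - b_fall = {fm.logits[1] - model.fc_bias[1]:.4f}")
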