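"""Train the 1D CNN on a small synthetic windowed dataset.

Windows are (6 x 100) snippets of the six IMU channels around each
activity start; the network (conv 32/64/128 + GAP + linear head) is
trained with Adam at lr 1e-4 and batch size 4 on a 2.3:1 split.
"""

import fallcam as fc

windows = fc.make_training_windows(60, 60, fs=50.0, seed=0)
train_w, test_w = fc.split_windows(windows, ratio=2.3, seed=0)
print(f"{len(train_w)} training / {len(test_w)} held-out windows")

model = fc.build_classifier(seed=0)
spec = fc.TrainSpec(learning_rate=1e-4, batch_size=4, epochs=10, seed=0)
model = fc.train(model, train_w, spec, val_windows=test_w)

for h in model.history[::3]:
    print(f"epoch {h['epoch']:2d}: loss={h['train_loss']:.3f} "
          f"val_acc={h['val_accuracy']:.2f}")

report = fc.evaluate_classifier(model, test_w)
print(f"held-out: accuracy {report.accuracy}% "
      f"(sensitivity {report.sensitivity}%, specificity {report.specificity}%)")
fc.save_checkpoint(model, "scratch_model.npz")
print("checkpoint written to scratch_model.npz")
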