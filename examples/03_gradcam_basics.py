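"""Compute a Grad-CAM map from a small classifier and inspect it.

The map is relu(sum_k alpha_k A^k) at the last convolutional layer, where
alpha_k pools the class-score gradient over each feature map.
"""

import numpy as np

from lesioncam import (ModelConfig, build_model, compute_cam, normalize_cam,
                       predict, upsample_cam)

model = build_model(ModelConfig(architecture="tiny-test", n_classes=2,
                                input_side=16, width=4, seed=0))
frame = np.random.default_rng(5).random((3, 16, 16)).astype(np.float32)

probs = predict(model, frame[None])[0]
print(f"class probabilities: {probs.round(3)} (sum {probs.sum():.6f})")

cam = compute_cam(model, frame, class_index=int(probs.argmax()))
print(f"raw CAM {cam.values.shape}, min {cam.values.min():.4f} "
      f"(never negative), max {cam.values.max():.4f}")
print(f"channel weights alpha_k: {cam.channel_weights.round(4)}")

norm = normalize_cam(cam)
full = upsample_cam(norm, (16, 16))
print(f"normalised max {norm.values.max():.1f}; upsampled to {full.values.shape}")

# The raw map lives at feature resolution (here 8x8 after one pooling
# stage); normalising to [0, 1] and bilinear upsampling to the frame size
# is what the localization evaluation operates on.
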