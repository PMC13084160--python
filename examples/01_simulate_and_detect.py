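"""Simulate a ground-truthed neuron scene and detect its mRNA spots.

Builds a small synthetic cell (soma + two neurites, 60 diffraction-limited
mRNA spots at 10x the noise SD), runs difference-of-Gaussians detection
with the auto-tuned response threshold, and scores the detections against
the planted truth at a 2-px match tolerance.
"""

import numpy as np
from scipy.spatial import cKDTree

from ncfish import DetectionParams, ScenarioParams, detect_spots_dog, generate_scene

params = ScenarioParams(
    image_shape=(512, 512),
    soma_radius_um=3.0,
    neurite_specs=((7.0, 1.4, 30.0), (6.0, 1.2, 200.0)),
    n_spots_per_channel={"rna": 60, "ribosome": 60},
    mito_specs=(20, 1.5, 0.4),
    noise_sd=0.05,
)
scene = generate_scene(params, seed=1)
detected = detect_spots_dog(scene.images.channels["rna"],
                            DetectionParams(threshold_mode="auto"))

truth = scene.truth.spots["rna"]
d, idx = cKDTree(truth).query(detected.positions(), k=1)
tp = len(set(idx[d <= 2.0]))
fp = int((d > 2.0).sum())
f1 = 2 * tp / (2 * tp + fp + (len(truth) - tp))

print(f"planted spots:  {len(truth)}")
print(f"detected spots: {len(detected)} (threshold {detected.realized_threshold:.4f})")
print(f"true positives: {tp}, false positives: {fp}, F1 = {f1:.3f}")
print(f"median localization error: {np.median(d[d <= 2.0]):.3f} px")
# F1 near 1 with sub-half-pixel error means the detector recovers the
# planted single-molecule spots essentially perfectly at this SNR.
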