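"""Generate a synthetic otoscopy-like dataset with planted biases.

The generator emulates the failure modes that corrupt real otoscopic
collections: a color artifact correlated with the label, a per-site framing
style, and near-duplicate images leaking across the train/validation split.
Ground truth for every planted bias is returned alongside the images, so
audit output can be checked against what was actually planted.
"""
import numpy as np

from otoaudit.synthetic import SyntheticConfig, generate_images

config = SyntheticConfig(
    n_per_class=100,
    clinical_contrast=80.0,      # a genuine lesion-like signal on the membrane
    saturation_bias=1.0,         # abnormal images get wider saturation spread
    duplicate_fraction=0.2,      # 20% of images duplicated 1-3 times
    duplicate_jitter=0.0,
    leak_across_split=True,      # one copy of each duplicate crosses the split
    seed=7,
)
manifest, truth, images = generate_images(config)

labels = np.array(manifest.labels)
print(f"records: {len(manifest)} "
      f"({int(labels.sum())} abnormal / {int((1 - labels).sum())} normal)")
print(f"train/internal_val: {len(manifest.subset('train'))}"
      f"/{len(manifest.subset('internal_val'))}")
print(f"planted duplicate sets: {len(truth.true_duplicate_sets)}")
styles = set(truth.per_image_style.values())
print(f"framing styles present: {sorted(styles)}")
print("planted biases: "
      f"clinical_contrast={config.clinical_contrast}, "
      f"saturation_bias={config.saturation_bias}, "
      f"duplicate_fraction={config.duplicate_fraction}, "
      f"leak_across_split={config.leak_across_split}")
# Every audit in the other examples runs against data like this, where the
# right answer is known in advance.
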