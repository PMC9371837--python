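"""Image path: blank-frame cleaning, head fine-tuning, pool5 extraction.

Builds a toy slice dataset (per-class blobs, 25% planted blank frames),
removes the blanks, fine-tunes the classification head of a small
ResNet-style backbone, and extracts pool5 descriptors.  The full resnet101
entry emits the standard 2048-wide descriptor; the micro entry used here is
fast enough for a demonstration.
"""

from brainfuse import (BackboneConfig, SyntheticImageSpec, TrainConfig,
                       build_model, extract_features, filter_blank_images,
                       finetune, make_image_fixture)

images, blank_ids = make_image_fixture(SyntheticImageSpec(
    n_per_class=8, n_classes=4, height=64, width=64,
    blank_fraction=0.25, seed=0))
cleaned, removed = filter_blank_images(images, max_intensity_threshold=0.0)
print(f"loaded {len(images)} frames; removed {removed} blank "
      f"(planted: {len(blank_ids)}) -> {len(cleaned)} kept")

model = build_model(BackboneConfig(architecture="resnet_micro",
                                   num_classes=4, init_seed=0))
model = finetune(model, cleaned, TrainConfig(epochs=5, learning_rate=0.05,
                                             batch_size=8, seed=0))
print("head-training loss per epoch:",
      [round(v, 4) for v in model.training_log])

fm = extract_features(model, cleaned)
print(f"pool5 feature matrix: {fm.n} x {fm.d} "
      f"(one row per image, in input order)")
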