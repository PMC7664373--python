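"""Expand one wrapped phase image into an augmented class dataset.

Segments a generator WQPI out of a simulated slide, builds the default
21 x 21 x 36 x 11 augmentation lattice, and materializes a small sample,
reporting the lattice cardinality and the wrap-closure of the outputs.
"""

import numpy as np

from holoplankton import (
    RunConfig,
    build_grid,
    demodulate,
    extract_wqpi,
    form_hologram,
    generate_dataset,
    make_phantom_slide,
    segment_slide,
    split_train_val,
)

cfg = RunConfig(seed=0, n_classes=1, slide_shape=(256, 256))
optics = cfg.optics_for(cfg.slide_shape)
slide = make_phantom_slide(1, cfg.slide_shape, cfg.morphology, seed=2)
wqpi = extract_wqpi(demodulate(form_hologram(slide, optics)))
generator = segment_slide(wqpi)[0].wqpi_crop
generator.class_id = 1
print(f"generator WQPI: {generator.shape} px, values in "
      f"[{generator.phase.min():.2f}, {generator.phase.max():.2f}) rad")

grid = build_grid()
print(f"default lattice: {grid.dims} -> {grid.cardinality:,} tuples per class")
print(f"over 50 classes -> {50 * grid.cardinality:,} images")

manifest, images = generate_dataset(
    [generator], grid, per_class=200, seed=0, out_shape=(56, 56)
)
train, val = split_train_val(manifest, 0.8, seed=0)
print(f"materialized {len(manifest)} sampled augmentations "
      f"({len(train)} train / {len(val)} val after the stratified 80/20 split)")
print(f"wrap closure: min {images.min():.4f} >= -pi, max {images.max():.4f} < pi")
print(f"parameter ranges drawn: scale x [{manifest.scale_x.min():+.2f}, "
      f"{manifest.scale_x.max():+.2f}], angles {manifest.angle_deg.nunique()} distinct, "
      f"biases [{manifest.bias_rad.min():.2f}, {manifest.bias_rad.max():.2f}] rad")
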