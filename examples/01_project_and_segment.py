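"""Render a synthetic organoid field, project it to 2D and segment it.

A 3-channel (DNA / actin / permeability), 16-slice stack is flattened with a
maximum-contrast projection -- per pixel, the slice whose 3x3 neighbourhood
has the highest intensity variance -- then organoids are segmented by
intensity thresholding plus a watershed split, and objects of 300 px or
smaller are discarded as debris.
"""

import numpy as np

import orgaprofiler as op

params = op.ImageSimParams(
    n_organoids=10, mode="mixed", radius_range=(11, 18), shape=(220, 220),
    noise_sd=2.0, psf_sigma=1.0,
)
field = op.simulate_image_stacks(None, params, seed=7)[0]
print(f"simulated stack: {field.stack.pixels.shape} (channel, z, y, x), "
      f"{field.mask.max()} organoids in the ground-truth mask")

projected = op.max_contrast_project(field.stack, window=3)
used = np.unique(projected.z_index_map)
print(f"projection chose pixels from z-slices {used.min()}..{used.max()} "
      "(each organoid is sharpest near its own focal plane)")

mask = op.segment_organoids(projected, smoothing_sd=2.0, min_seed_distance=10)
mask = op.filter_small_objects(mask, max_removed_area=300)
areas = np.bincount(mask.ravel())[1:]
print(f"segmentation found {mask.max()} organoids "
      f"(areas {areas.min()}..{areas.max()} px after removing objects <= 300 px)")
print("a count matching the ground truth means projection + segmentation "
      "recovered every rendered organoid as one object")
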