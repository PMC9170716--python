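"""Extract per-organoid features, apply the well-definedness filter, fit PCA.

Each segmented organoid gets shape/moment features, per-channel intensity
statistics and co-occurrence texture features at offsets 1/2/4/8 px.  The
filter then drops texture offsets larger than the smallest organoids and any
feature whose median absolute deviation is zero, centres per batch, and PCA
compresses the screen-level feature table.
"""

import orgaprofiler as op
from orgaprofiler import synthetic_data as sd
from orgaprofiler.features import filter_and_center_features, fit_pca_transform

# image-level features for one field
field = op.simulate_image_stacks(
    None, op.ImageSimParams(n_organoids=8, radius_range=(11, 18), shape=(200, 200)),
    seed=1,
)[0]
projected = op.max_contrast_project(field.stack)
mask = op.filter_small_objects(op.segment_organoids(projected), 300)
fm_img = op.extract_organoid_features(projected, mask)
print(f"image features: {fm_img.features.shape[0]} organoids x "
      f"{fm_img.features.shape[1]} named features "
      "(shape, moments, intensity, texture)")

# screen-level feature table + filtering + PCA
lib = sd.clinical_library_spec(n_drugs=6, seed=0)
plates = op.generate_plate_layout(["D004T", "D013T"], lib, seed=1)
fm, _ = op.simulate_feature_table(plates, op.EffectConfig(n_per_well=40), seed=2)
filtered = filter_and_center_features(fm)
report = {k: len(v) for k, v in filtered.filter_report.items()}
print(f"screen table: {fm.features.shape} -> {filtered.features.shape} "
      f"after filtering ({report}); per-batch means are now zero")

model, scores = fit_pca_transform(filtered, n_components=25, incremental_chunk=1000)
print(f"25 PCs explain {100 * model.explained_variance_ratio.sum():.1f}% of the "
      "filtered feature variance (the synthetic table is low-dimensional by "
      "construction); downstream stages work on these scores")
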