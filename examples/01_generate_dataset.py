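"""Generate a small labelled synthetic food-image dataset.

Writes PNG images and a manifest CSV (columns: image_path, labels,
split) to ./example_dataset.  Training images are single-label; 30% of
test rows are multi-label composites of 2-5 categories, mimicking a
plate with several foods on it.
"""

from bowfood import generate_dataset

manifest = generate_dataset(
    n_categories=5,
    train_per_category=(4, 8),
    test_per_category=(6, 8),
    multi_label_fraction=0.3,
    seed=1,
    out_dir="example_dataset",
)

frame = manifest.frame
print(f"manifest: {manifest.path}")
print(f"{(frame['split'] == 'train').sum()} train rows, "
      f"{(frame['split'] == 'test').sum()} test rows")
print("categories:", ", ".join(manifest.categories))
multi = frame[frame["labels"].str.contains(";")]
print(f"{len(multi)} multi-label test rows, e.g. "
      f"{multi.iloc[0]['labels'] if len(multi) else '(none)'}")
# Each row maps one PNG to the food categories rendered into it; the
# train/test split is disjoint by construction.
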