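"""Train the bag-of-words pipeline and predict labels for test images.

Builds chi-squared K-means codebooks and one-vs-rest linear SVMs from
the train split of a manifest (run 01_generate_dataset.py first), then
scores two test images: once with the single-label rule (argmax of the
decision scores) and once with the multi-label rule (every category
whose score exceeds the recognition sensitivity).
"""

from bowfood import (
    PipelineConfig,
    extract_features,
    load_image,
    load_manifest,
    maybe_downscale,
    predict_multi,
    predict_single,
    train_from_manifest,
)
from bowfood.pipeline import score_image

manifest = load_manifest("example_dataset/manifest.csv")
config = PipelineConfig(codebook_sizes={"shape": 40, "texture": 20,
                                        "colour": 20})
bundle = train_from_manifest(manifest, config)
print(f"trained {len(bundle.models)} one-vs-rest classifiers "
      f"over a {sum(cb.K for cb in bundle.codebooks.values())}-word "
      "vocabulary")

for path, truth in manifest.rows("test")[:2]:
    image = maybe_downscale(load_image(path))
    scores = score_image(bundle, extract_features(image))
    single = predict_single(scores)
    multi = predict_multi(scores, sensitivity=0.0)
    print(f"\n{path}")
    print(f"  truth:        {sorted(truth)}")
    print(f"  single-label: {single}")
    print(f"  multi-label (eps=0): {sorted(multi)}")
# The single-label rule picks the best-scoring category; the
# multi-label rule can return several categories (or none) depending on
# the sensitivity threshold.
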