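"""From raw feature ratings to category feature profiles.

Simulates binary and 1-7 raters, aggregates them into the actions x
features matrix, prunes redundant (highly correlated) features, and
contrasts one category's feature profile against all remaining actions
with permutation p-values and BH-FDR correction.
"""

from actionspace import (
    CategoryAssignment,
    aggregate_ratings,
    category_contrast,
    gen_feature_ratings,
    gen_ground_truth,
    prune_correlated,
)

gt = gen_ground_truth(seed=3)
records = gen_feature_ratings(gt, seed=30)
print(f"collected {len(records)} ratings "
      f"({len(records) // len(gt.item_ids) // 59} raters per action on average)")

fm = aggregate_ratings(records, gt.schema, actions=list(gt.item_ids))
fm, drop_log = prune_correlated(fm, threshold=0.9)
dropped = [e["feature"] for e in drop_log if e["action"] == "dropped"]
print(f"pruned {len(dropped)} redundant features -> {len(fm.features)} retained")

assignment = CategoryAssignment(gt.assignment, (), len(gt.categories), gt.categories)
cat = gt.categories[0]
profile = category_contrast(fm, assignment, cat, seed=0)
top = profile.table.sort_values("z", ascending=False).head(5)
print(f"\nfeatures most elevated in category {cat} vs the rest "
      "(z > 0: higher ratings; q: BH-FDR adjusted p):")
print(top[["mean", "z", "q", "significant"]].round(3).to_string())
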