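"""Run the full pipeline end to end on a simulated study.

Writes a study to disk (trial logs, ratings), then runs every stage
through the single run_pipeline entry point and prints the manifest
summary.  The same flow is available from the shell:

    actionspace simulate --seed 11 --out study/ --actions 24 --categories 4 --participants 5
    actionspace run --config pipeline.yaml
"""

import tempfile
from dataclasses import replace
from pathlib import Path

from actionspace import StudyConfig, gen_feature_ratings, gen_ground_truth, gen_participant_trials
from actionspace.io import PipelineConfig, run_pipeline, write_ratings, write_trials
from actionspace.synthetic import ProtocolConfig

tmp = Path(tempfile.mkdtemp())
cfg = replace(StudyConfig(), n_actions=24, n_categories=4, min_category_size=4,
              n_redundant=4, participant_sd=0.05)
gt = gen_ground_truth(21, cfg)
write_trials(gen_participant_trials(gt, 5, seed=22, protocol=ProtocolConfig(max_trials=6)),
             tmp / "trials.jsonl")
write_ratings(gen_feature_ratings(gt, seed=23, raters_per_cell=8), tmp / "ratings.csv")

result = run_pipeline(PipelineConfig.from_dict({
    "seed": 5,
    "out_dir": str(tmp / "out"),
    "trials_path": str(tmp / "trials.jsonl"),
    "ratings_path": str(tmp / "ratings.csv"),
    "k_min": 2, "k_max": 10,
    "n_folds": 6, "test_actions": 5, "test_participants": 2,
    "embed_restarts": 2,
}))

m = result["manifest"]
print(f"selected linkage: {m['selected_linkage']} "
      f"(cophenetic {m['cophenetic_scores'][m['selected_linkage']]:.3f})")
print(f"2-D embedding stress: {m['mds_stress']:.3f}")
print(f"silhouette-selected clusters: {m['silhouette_best_k']} "
      f"-> {m['categories_retained']} categories retained")
print(f"features retained after pruning: {m['features_retained']}")
print(f"outputs written to {result['out_dir']}:")
for name in m["outputs"]:
    print("  ", name)
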