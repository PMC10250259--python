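"""Readers, writers, pipeline configuration, and the end-to-end pipeline.

All formats are plain text: JSON-lines for arrangement trials, CSV for
RDMs (full symmetric matrix with an item-id header row/column), ratings,
feature matrices and result tables, JSON for schemas, ground truth and the
run manifest.  A single root seed fans out to per-stage substreams so that
identical configurations produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arrangement import ArrangementTrial, TrialError, aggregate_participant
from .cluster import (
    CategoryAssignment,
    extract_categories,
    select_linkage,
    silhouette_scan,
    to_newick,
    upgma_tree,
)
from .features import (
    FeatureMatrix,
    FeatureSchema,
    RatingRecord,
    aggregate_ratings,
    load_default_schema,
    prune_correlated,
)
from .profiles import category_contrast
from .rdm import RDM, Embedding, average_rdms, embed_2d
from .rsa import CVConfig, FeatureRDMs, bootstrap_models, build_feature_rdms, cv_reweight, default_models


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trials (JSON-lines)


def write_trials(trials: Sequence[ArrangementTrial], path) -> None:
    with open(path, "w") as fh:
        for t in trials:
            fh.write(
                json.dumps(
                    {"participant": t.participant_id, "items": list(t.items), "xy": t.coords.tolist()}
                )
                + "\n"
            )


def read_trials(path) -> list:
    trials = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TrialError(f"{path}:{lineno}: malformed JSON ({exc.msg})") from None
            try:
                trials.append(
                    ArrangementTrial(obj["participant"], tuple(obj["items"]), np.asarray(obj["xy"], dtype=float))
                )
            except (KeyError, TrialError, ValueError) as exc:
                raise TrialError(f"{path}:{lineno}: invalid trial: {exc}") from None
    return trials


# ---------------------------------------------------------------------------
# RDMs and embeddings (CSV)


def write_rdm_csv(rdm: RDM, path) -> None:
    df = pd.DataFrame(rdm.to_square(), index=list(rdm.item_ids), columns=list(rdm.item_ids))
    df.to_csv(path)


def read_rdm_csv(path) -> RDM:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ConfigError(f"{path}: RDM row and column item ids differ")
    return RDM.from_square(tuple(df.index), df.to_numpy(), {"source": str(path)})


def write_embedding(emb: Embedding, path) -> None:
    df = pd.DataFrame(emb.coords, index=list(emb.item_ids), columns=["x", "y"])
    df.index.name = "item_id"
    df.to_csv(path)
    Path(str(path) + ".json").write_text(
        json.dumps({"stress": emb.stress, "variant": emb.variant})
    )


# ---------------------------------------------------------------------------
# Ratings and feature matrices (CSV)


def write_ratings(records: Sequence[RatingRecord], path) -> None:
    pd.DataFrame(
        [(r.rater_id, r.action_id, r.feature_id, r.answer) for r in records],
        columns=["rater_id", "action_id", "feature_id", "answer"],
    ).to_csv(path, index=False)


def read_ratings(path, schema: FeatureSchema) -> list:
    df = pd.read_csv(path, dtype={"answer": str})
    required = {"rater_id", "action_id", "feature_id", "answer"}
    if not required.issubset(df.columns):
        raise ConfigError(f"{path}: ratings CSV needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        if row.feature_id not in schema:
            raise ConfigError(f"{path}: unknown feature id {row.feature_id!r}")
        ans = row.answer
        if schema[row.feature_id].scale == "continuous":
            try:
                ans = int(float(ans))
            except ValueError:
                pass  # validation error raised with context at recode time
        records.append(RatingRecord(str(row.rater_id), str(row.action_id), str(row.feature_id), ans))
    return records


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    fm.values.rename_axis("action_id").to_csv(path)
    fm.counts.rename_axis("action_id").to_csv(Path(path).with_suffix(".counts.csv"))


def read_feature_matrix(path, schema: FeatureSchema) -> FeatureMatrix:
    values = pd.read_csv(path, index_col=0)
    counts_path = Path(path).with_suffix(".counts.csv")
    if counts_path.exists():
        counts = pd.read_csv(counts_path, index_col=0)
    else:
        counts = pd.DataFrame(1, index=values.index, columns=values.columns)
    return FeatureMatrix(values, counts, schema)


# ---------------------------------------------------------------------------
# Assignments, profiles, model tables


def write_assignment(assignment: CategoryAssignment, path) -> None:
    rows = [(i, c) for i, c in assignment.assignment.items()]
    rows += [(i, "") for i in assignment.dropped]
    pd.DataFrame(rows, columns=["item_id", "category"]).to_csv(path, index=False)


def read_assignment(path) -> CategoryAssignment:
    df = pd.read_csv(path, dtype=str).fillna("")
    mapping = {r.item_id: r.category for r in df.itertuples(index=False) if r.category}
    dropped = tuple(r.item_id for r in df.itertuples(index=False) if not r.category)
    labels = tuple(dict.fromkeys(mapping.values()))
    return CategoryAssignment(mapping, dropped, k_total=len(labels) + len(dropped), labels=labels)


def write_profiles(profiles, path) -> None:
    frames = []
    for prof in profiles:
        t = prof.table.copy()
        t.insert(0, "category", prof.category)
        t.index.name = "feature"
        frames.append(t.reset_index())
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_ground_truth(gt, path) -> None:
    obj = {
        "config": dataclasses.asdict(gt.config),
        "seed": gt.seed,
        "assignment": gt.assignment,
        "sizes": list(gt.sizes),
        "weights": gt.w.to_dict(),
        "loadings": {a: gt.F.loc[a].round(6).to_dict() for a in gt.item_ids},
        "redundant": [list(p) for p in gt.redundant],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def write_schema(schema: FeatureSchema, path) -> None:
    Path(path).write_text(json.dumps(schema.to_json_obj(), indent=1))


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Full-run settings; unknown keys are rejected and a seed is mandatory."""

    seed: int
    out_dir: str
    trials_path: str
    ratings_path: str
    schema_path: str | None = None
    linkage_methods: tuple = ("single", "complete", "average", "weighted")
    k_min: int = 3
    k_max: int = 50
    min_cluster_size: int = 2
    prune_threshold: float = 0.9
    embed_restarts: int = 8
    mds_variant: str = "nonmetric"
    n_folds: int = 50
    test_actions: int = 10
    test_participants: int = 5
    n_boot: int = 0  # 0: skip bootstrap inference in the pipeline run

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in obj:
            raise ConfigError("config must set an explicit seed")
        missing = {"out_dir", "trials_path", "ratings_path"} - set(obj)
        if missing:
            raise ConfigError(f"config missing required keys: {sorted(missing)}")
        obj = dict(obj)
        if "linkage_methods" in obj:
            obj["linkage_methods"] = tuple(obj["linkage_methods"])
        return cls(**obj)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        if not isinstance(obj, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(obj)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage end to end and write the report bundle.

    Stages: per-participant RDM aggregation -> group RDM -> 2-D embedding
    -> linkage selection, UPGMA, silhouette scan, category extraction ->
    rating aggregation, pruning -> category profiles/contrasts -> RSA with
    cross-validated reweighting (bootstrap inference if ``n_boot`` > 0).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.SeedSequence(config.seed)
    embed_seed, cv_seed = (int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(2))

    trials = read_trials(config.trials_path)
    by_participant: dict = {}
    for t in trials:
        by_participant.setdefault(t.participant_id, []).append(t)
    if not by_participant:
        raise ConfigError("no trials found")
    item_ids = sorted({i for t in trials for i in t.items})
    subject_rdms = [
        aggregate_participant(ts, item_ids=item_ids) for ts in by_participant.values()
    ]
    group = average_rdms(subject_rdms)
    write_rdm_csv(group, out / "group_rdm.csv")

    emb = embed_2d(group, seed=embed_seed, restarts=config.embed_restarts, variant=config.mds_variant)
    write_embedding(emb, out / "embedding.csv")

    method, score_table = select_linkage(group, config.linkage_methods)
    tree = upgma_tree(group)
    k_max = min(config.k_max, group.n - 1)
    best_k, sil = silhouette_scan(group, tree, k_min=config.k_min, k_max=k_max)
    assignment = extract_categories(tree, best_k, group.item_ids, min_size=config.min_cluster_size)
    pd.DataFrame(tree.Z, columns=["left", "right", "height", "size"]).to_csv(
        out / "dendrogram.csv", index=False
    )
    (out / "dendrogram.nwk").write_text(to_newick(tree, group.item_ids))
    write_assignment(assignment, out / "assignment.csv")

    schema = FeatureSchema.from_json(config.schema_path) if config.schema_path else load_default_schema()
    records = read_ratings(config.ratings_path, schema)
    fm = aggregate_ratings(records, schema, actions=item_ids)
    fm, drop_log = prune_correlated(fm, threshold=config.prune_threshold)
    write_feature_matrix(fm, out / "feature_matrix.csv")

    profiles = [
        category_contrast(fm, assignment, c)
        for c in assignment.categories
        if len(assignment.members(c)) >= 2
    ]
    write_profiles(profiles, out / "profiles.csv")

    feature_rdms = build_feature_rdms(fm)
    models = default_models(fm)
    cfg = CVConfig(
        n_folds=config.n_folds,
        test_actions=config.test_actions,
        test_participants=config.test_participants,
        n_boot=max(config.n_boot, 1),
        seed=cv_seed,
    )
    if config.n_boot > 0:
        fits, model_table, diffs = bootstrap_models(subject_rdms, models, feature_rdms, fm, cfg)
        diffs.to_csv(out / "model_differences.csv", index=False)
    else:
        fits = cv_reweight(subject_rdms, models, feature_rdms, fm, cfg)
        model_table = pd.DataFrame(
            [
                {"model": f.name, "tau": f.tau, "nc_lower": f.nc_lower, "nc_upper": f.nc_upper}
                for f in fits.values()
            ]
        ).set_index("model")
    model_table.to_csv(out / "model_table.csv")
    weights = fits["weighted_multi_feature"].weights
    weights.rename_axis("feature").rename("weight").to_csv(out / "weights.csv")

    manifest = {
        "package": "actionspace",
        "version": __version__,
        "python": platform.python_version(),
        "versions": {m.__name__: m.__version__ for m in (np, pd)},
        "config": dataclasses.asdict(config),
        "derived_seeds": {"embed": embed_seed, "cv": cv_seed},
        "selected_linkage": method,
        "cophenetic_scores": score_table,
        "mds_stress": emb.stress,
        "silhouette_best_k": best_k,
        "clusters_before_filter": assignment.k_total,
        "categories_retained": len(assignment.categories),
        "features_retained": len(fm.features),
        "features_dropped": [e["feature"] for e in drop_log if e["action"] == "dropped"],
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "group_rdm": group,
        "embedding": emb,
        "tree": tree,
        "assignment": assignment,
        "feature_matrix": fm,
        "fits": fits,
        "model_table": model_table,
        "manifest": manifest,
        "out_dir": str(out),
    }
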