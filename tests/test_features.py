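import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from actionspace import (
    FeatureMatrix,
    RatingRecord,
    StudyConfig,
    aggregate_ratings,
    gen_feature_ratings,
    gen_ground_truth,
    load_default_schema,
    prune_correlated,
    recode_rating,
    theme_submatrix,
)
from actionspace.features import FeatureDef, FeatureSchema, RatingError, SchemaError


@pytest.fixture(scope="module")
def schema():
    return load_default_schema()


class TestShippedSchema:
    def test_size_and_theme_structure(self, schema):
        assert len(schema) == 59
        assert len(schema.themes) == 19
        binary_themes = {f.theme for f in schema if f.scale == "binary"}
        continuous_themes = {f.theme for f in schema if f.scale == "continuous"}
        assert len(binary_themes) == 13 and len(continuous_themes) == 6
        assert not binary_themes & continuous_themes

    def test_theme_partition(self, schema):
        union = [f for t in schema.themes for f in schema.theme_features(t)]
        assert sorted(union) == sorted(schema.feature_ids)


class TestRecode:
    def test_binary_endpoints(self, schema):
        assert recode_rating(RatingRecord("r", "a", "harm", "Yes"), schema) == 1.0
        assert recode_rating(RatingRecord("r", "a", "harm", "No"), schema) == 0.0

    @pytest.mark.parametrize("raw,expected", [(1, 0.0), (4, 0.5), (7, 1.0)])
    def test_continuous_rescaling(self, schema, raw, expected):
        assert recode_rating(RatingRecord("r", "a", "pace", raw), schema) == expected

    def test_monotone_in_raw_answer(self, schema):
        vals = [recode_rating(RatingRecord("r", "a", "pace", x), schema) for x in range(1, 8)]
        assert vals == sorted(vals) and len(set(vals)) == 7

    @pytest.mark.parametrize(
        "feature,answer", [("pace", 0), ("pace", 8), ("pace", "Yes"), ("harm", "maybe"), ("harm", 5)]
    )
    def test_invalid_answers_rejected_with_context(self, schema, feature, answer):
        with pytest.raises(RatingError, match="rater"):
            recode_rating(RatingRecord("r9", "a1", feature, answer), schema)


class TestAggregate:
    def test_single_record_per_cell(self, schema):
        recs = [
            RatingRecord("r1", "a1", "harm", "Yes"),
            RatingRecord("r1", "a1", "pace", 4),
            RatingRecord("r1", "a2", "harm", "No"),
            RatingRecord("r1", "a2", "pace", 7),
        ]
        fm = aggregate_ratings(recs, schema)
        assert fm.values.loc["a1", "harm"] == 1.0
        assert fm.values.loc["a2", "pace"] == 1.0
        assert (fm.counts.values == 1).all()

    def test_mean_of_mixed_answers(self, schema):
        recs = [RatingRecord(f"r{i}", "a1", "harm", a) for i, a in enumerate(["Yes", "Yes", "No"])]
        fm = aggregate_ratings(recs, schema)
        assert fm.values.loc["a1", "harm"] == pytest.approx(2 / 3)

    def test_missing_cell_reported(self, schema):
        recs = [
            RatingRecord("r1", "a1", "harm", "Yes"),
            RatingRecord("r1", "a2", "harm", "No"),
            RatingRecord("r1", "a1", "pace", 3),
        ]
        with pytest.raises(RatingError, match="a2/pace"):
            aggregate_ratings(recs, schema)

    def test_record_order_invariance(self, schema):
        rng = np.random.default_rng(0)
        recs = [
            RatingRecord(f"r{i}", f"a{j}", "pace", int(rng.integers(1, 8)))
            for j in range(3)
            for i in range(4)
        ]
        a = aggregate_ratings(recs, schema).values
        b = aggregate_ratings(recs[::-1], schema).values
        pd.testing.assert_frame_equal(a, b)

    def test_simulator_round_trip(self):
        cfg = replace(StudyConfig(), n_actions=30, n_categories=4, n_redundant=4)
        gt = gen_ground_truth(3, cfg)
        # continuous features at zero noise agree up to the 1/6 rating grid
        quiet = replace(cfg, rater_sd=0.0, rater_flip=0.0)
        gt_q = replace(gt, config=quiet)
        recs = gen_feature_ratings(gt_q, seed=30, raters_per_cell=1)
        fm = aggregate_ratings(recs, gt.schema, actions=list(gt.item_ids))
        cont = [f.feature_id for f in gt.schema if f.scale == "continuous"]
        err = (fm.values[cont] - gt.F[cont]).abs().to_numpy()
        assert err.max() <= 1 / 12 + 1e-9
        # at default noise, aggregated ratings track the true loadings
        recs = gen_feature_ratings(gt, seed=31, raters_per_cell=9)
        fm = aggregate_ratings(recs, gt.schema, actions=list(gt.item_ids))
        corrs = [np.corrcoef(fm.values[f], gt.F[f])[0, 1] for f in fm.features]
        assert min(corrs) >= 0.85


def toy_fm(X, ids=None):
    n, f = X.shape
    ids = ids or [f"f{j}" for j in range(f)]
    schema = FeatureSchema([FeatureDef(i, i, "T", "continuous") for i in ids])
    actions = [f"a{i}" for i in range(n)]
    vals = pd.DataFrame(X, index=actions, columns=ids)
    return FeatureMatrix(vals, pd.DataFrame(1, index=actions, columns=ids), schema)


class TestPrune:
    def test_duplicated_column_dropped(self, rng):
        x = rng.random(20)
        fm = toy_fm(np.column_stack([x, x, rng.random(20)]))
        reduced, log = prune_correlated(fm, threshold=0.9)
        assert len(reduced.features) == 2
        dropped = [e for e in log if e["action"] == "dropped"]
        assert len(dropped) == 1 and dropped[0]["r"] == pytest.approx(1.0)

    def test_orthogonal_columns_kept(self):
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]])
        X[:, 1] = [0, 1, 0, 1.0]
        reduced, log = prune_correlated(toy_fm(X), threshold=0.95)
        assert len(reduced.features) == 2

    def test_planted_pair_matches_brute_scan(self, rng):
        X = rng.random((40, 6))
        X[:, 3] = 0.97 * X[:, 1] + 0.03 * rng.random(40)  # one planted high-r pair
        fm = toy_fm(X)
        r = np.corrcoef(X.T)
        np.fill_diagonal(r, 0)
        assert (np.abs(r) >= 0.9).sum() == 2  # exactly the planted pair
        reduced, log = prune_correlated(fm, threshold=0.9)
        dropped = [e["feature"] for e in log if e["action"] == "dropped"]
        assert len(dropped) == 1 and dropped[0] in ("f1", "f3")
        # post-condition: no surviving pair at or above threshold
        rr = reduced.values.corr().abs().to_numpy()
        np.fill_diagonal(rr, 0)
        assert rr.max() < 0.9

    def test_constant_column_flagged_not_dropped(self):
        X = np.column_stack([np.full(10, 0.5), np.linspace(0, 1, 10), np.linspace(1, 0, 10) ** 2])
        reduced, log = prune_correlated(toy_fm(X), threshold=0.99)
        assert any(e["action"] == "flagged_constant" for e in log)
        assert "f0" in reduced.features

    def test_default_study_prunes_to_about_44(self):
        gt = gen_ground_truth(1)
        recs = gen_feature_ratings(gt, seed=100, raters_per_cell=9)
        fm = aggregate_ratings(recs, gt.schema, actions=list(gt.item_ids))
        reduced, log = prune_correlated(fm, threshold=0.9)
        assert 40 <= len(reduced.features) <= 46
        dropped = {e["feature"] for e in log if e["action"] == "dropped"}
        planted = {d for d, _ in gt.redundant} | {b for _, b in gt.redundant}
        # the planted near-duplicates dominate what gets removed
        assert len(dropped & planted) >= 0.8 * len(dropped)


class TestThemeSubmatrix:
    def test_single_feature_theme(self, schema):
        gt = gen_ground_truth(2, replace(StudyConfig(), n_actions=20, n_categories=3, n_redundant=0))
        fm = FeatureMatrix(gt.F, gt.F.copy() * 0 + 1, schema)
        sub = theme_submatrix(fm, "Pace")
        assert sub.features == ("pace",)

    def test_theme_partition_covers_matrix(self, schema):
        gt = gen_ground_truth(2, replace(StudyConfig(), n_actions=20, n_categories=3, n_redundant=0))
        fm = FeatureMatrix(gt.F, gt.F.copy() * 0 + 1, schema)
        cols = [f for t in schema.themes for f in theme_submatrix(fm, t).features]
        assert sorted(cols) == sorted(fm.features)

    def test_unknown_theme_rejected(self, schema):
        gt = gen_ground_truth(2, replace(StudyConfig(), n_actions=20, n_categories=3, n_redundant=0))
        fm = FeatureMatrix(gt.F, gt.F.copy() * 0 + 1, schema)
        with pytest.raises(SchemaError):
            theme_submatrix(fm, "Nonexistent theme")
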