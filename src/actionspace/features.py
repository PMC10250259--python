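"""Feature-rating pipeline: recode raw answers, aggregate raters, prune redundancy.

Raters judge each action on a fixed schema of features organized into
themes.  Binary features take Yes/No answers, continuous features a 1-7
scale; both are recoded onto [0, 1] (Yes -> 1, No -> 0, x -> (x-1)/6) and
averaged across raters into an actions x features matrix.  Highly
correlated features are then removed iteratively so that the retained set
can serve as a multicollinearity-safe multi-feature model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    pass


class RatingError(ValueError):
    pass


_YES = {"yes", "y", "1", "true"}
_NO = {"no", "n", "0", "false"}


@dataclass(frozen=True)
class FeatureDef:
    feature_id: str
    name: str
    theme: str
    scale: str  # "binary" | "continuous"
    question: str = ""


class FeatureSchema:
    """Ordered feature definitions with a theme map."""

    def __init__(self, features: Sequence[FeatureDef]):
        ids = [f.feature_id for f in features]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate feature ids in schema")
        for f in features:
            if f.scale not in ("binary", "continuous"):
                raise SchemaError(f"unknown scale {f.scale!r} for feature {f.feature_id!r}")
        self._features = tuple(features)
        self._by_id = {f.feature_id: f for f in features}

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self):
        return iter(self._features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def __getitem__(self, feature_id: str) -> FeatureDef:
        try:
            return self._by_id[feature_id]
        except KeyError:
            raise SchemaError(f"unknown feature id: {feature_id!r}") from None

    @property
    def feature_ids(self) -> tuple:
        return tuple(f.feature_id for f in self._features)

    @property
    def themes(self) -> tuple:
        out: dict = {}
        for f in self._features:
            out.setdefault(f.theme, None)
        return tuple(out)

    def theme_features(self, theme: str) -> tuple:
        ids = tuple(f.feature_id for f in self._features if f.theme == theme)
        if not ids:
            raise SchemaError(f"unknown theme: {theme!r}")
        return ids

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            obj = json.load(fh)
        return cls._from_obj(obj)

    @classmethod
    def _from_obj(cls, obj: dict) -> "FeatureSchema":
        return cls(
            [
                FeatureDef(f["id"], f.get("name", f["id"]), f["theme"], f["scale"], f.get("question", ""))
                for f in obj["features"]
            ]
        )

    def to_json_obj(self) -> dict:
        return {
            "features": [
                {"id": f.feature_id, "name": f.name, "theme": f.theme, "scale": f.scale, "question": f.question}
                for f in self._features
            ]
        }


def load_default_schema() -> FeatureSchema:
    """The packaged 59-feature / 19-theme action-feature schema.

    This fixture is a synthetic reconstruction: theme names, scale types
    and theme sizes follow the emulated study design, while individual
    feature names are plausible completions and should not be treated as
    the original rating instrument.
    """
    ref = resources.files("actionspace.data") / "feature_schema_synthetic.json"
    return FeatureSchema._from_obj(json.loads(ref.read_text()))


@dataclass(frozen=True)
class RatingRecord:
    rater_id: str
    action_id: str
    feature_id: str
    answer: object  # "Yes"/"No" for binary, int 1..7 for continuous


def recode_rating(record: RatingRecord, schema: FeatureSchema) -> float:
    """Recode one raw answer onto [0, 1]."""
    feat = schema[record.feature_id]
    ans = record.answer
    if feat.scale == "binary":
        token = str(ans).strip().lower()
        if token in _YES:
            return 1.0
        if token in _NO:
            return 0.0
        raise RatingError(
            f"invalid binary answer {ans!r} for feature {feat.feature_id!r} "
            f"(rater {record.rater_id!r}, action {record.action_id!r})"
        )
    try:
        x = int(ans)
    except (TypeError, ValueError):
        x = None
    if x is None or not (1 <= x <= 7) or float(ans) != x:
        raise RatingError(
            f"invalid 1-7 answer {ans!r} for feature {feat.feature_id!r} "
            f"(rater {record.rater_id!r}, action {record.action_id!r})"
        )
    return (x - 1) / 6.0


class FeatureMatrix:
    """Actions x features mean recoded ratings in [0, 1] with rater counts."""

    def __init__(self, values: pd.DataFrame, counts: pd.DataFrame, schema: FeatureSchema):
        if values.shape != counts.shape or not values.columns.equals(counts.columns):
            raise RatingError("values and counts must be aligned")
        if ((values.values < -1e-12) | (values.values > 1 + 1e-12)).any():
            raise RatingError("feature values must lie in [0, 1]")
        unknown = [c for c in values.columns if c not in schema]
        if unknown:
            raise SchemaError(f"columns not in schema: {unknown}")
        self.values = values
        self.counts = counts
        self.schema = schema

    @property
    def actions(self) -> tuple:
        return tuple(self.values.index)

    @property
    def features(self) -> tuple:
        return tuple(self.values.columns)

    def subset(self, features: Iterable[str]) -> "FeatureMatrix":
        cols = list(features)
        return FeatureMatrix(self.values[cols], self.counts[cols], self.schema)


def aggregate_ratings(
    records: Iterable[RatingRecord],
    schema: FeatureSchema,
    actions: Sequence[str] | None = None,
    features: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Mean recoded rating per (action, feature) cell; every cell needs >= 1 record."""
    rows = [
        (r.action_id, r.feature_id, recode_rating(r, schema)) for r in records
    ]
    if not rows:
        raise RatingError("no rating records")
    df = pd.DataFrame(rows, columns=["action", "feature", "value"])
    values = df.pivot_table(index="action", columns="feature", values="value", aggfunc="mean")
    counts = df.pivot_table(index="action", columns="feature", values="value", aggfunc="count")
    if actions is None:
        actions = sorted(values.index)
    if features is None:
        features = [f for f in schema.feature_ids if f in values.columns]
    values = values.reindex(index=list(actions), columns=list(features))
    counts = counts.reindex(index=list(actions), columns=list(features))
    if values.isna().any().any():
        missing = [
            (a, f) for a in values.index for f in values.columns if pd.isna(values.at[a, f])
        ]
        shown = ", ".join(f"{a}/{f}" for a, f in missing[:10])
        raise RatingError(f"{len(missing)} empty (action, feature) cell(s): {shown}")
    return FeatureMatrix(values, counts.astype(int), schema)


def prune_correlated(fm: FeatureMatrix, threshold: float = 0.9):
    """Iteratively remove one member of every feature pair with |r| >= threshold.

    While any retained pair of (non-constant) features correlates at
    |Pearson r| >= threshold across actions, the pair with the largest |r|
    is located and the member with the larger mean absolute correlation to
    all other retained features is dropped (ties: later schema order).

    Returns ``(reduced FeatureMatrix, drop_log)`` where each log entry is a
    dict with the dropped/kept feature, the triggering r, or a flag for
    constant columns.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if len(fm.features) < 2:
        raise RatingError("need at least two features to prune")
    values = fm.values
    log: list = []
    constant = [c for c in values.columns if values[c].nunique() <= 1]
    for c in constant:
        log.append({"feature": c, "action": "flagged_constant"})
    active = [c for c in values.columns if c not in constant]
    corr = values[active].corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    order = {f: k for k, f in enumerate(fm.schema.feature_ids)}
    while len(corr) > 1:
        flat = corr.values
        i, j = np.unravel_index(np.argmax(flat), flat.shape)
        r = flat[i, j]
        if r < threshold:
            break
        fi, fj = corr.index[i], corr.columns[j]
        mi, mj = corr.loc[fi].mean(), corr.loc[fj].mean()
        if mi > mj or (mi == mj and order[fi] > order[fj]):
            drop, keep = fi, fj
        else:
            drop, keep = fj, fi
        log.append({"feature": drop, "action": "dropped", "against": keep, "r": float(r)})
        corr = corr.drop(index=drop, columns=drop)
    kept = [c for c in values.columns if c not in {e["feature"] for e in log if e["action"] == "dropped"}]
    reduced = fm.subset(kept)
    # post-hoc guarantee: no retained non-constant pair at |r| >= threshold
    check = reduced.values[[c for c in kept if c not in constant]].corr().abs().values
    np.fill_diagonal(check, 0.0)
    assert check.size == 0 or check.max() < threshold
    return reduced, log


def theme_submatrix(fm: FeatureMatrix, theme: str) -> FeatureMatrix:
    """Columns of one theme (restricted to features retained in ``fm``)."""
    ids = [f for f in fm.schema.theme_features(theme) if f in fm.features]
    if not ids:
        raise SchemaError(f"theme {theme!r} has no retained features")
    return fm.subset(ids)
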