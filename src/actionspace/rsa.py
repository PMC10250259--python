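"""Representational similarity analysis with cross-validated feature reweighting.

Feature-based model RDMs (single features, themes, the joint unweighted
multi-feature model, and a non-negatively reweighted combination of
single-feature RDMs) are compared against behavioral RDMs with Kendall's
tau-a.  Weights are fit by non-negative least squares on training data and
evaluated out of sample, cross-validating jointly over stimuli and
participants; noise ceilings bound the performance any true model could
attain given inter-participant variability, and inference uses bootstrap
resampling of the stimuli with BH-FDR correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls as _scipy_nnls
from scipy.spatial.distance import pdist

from .features import FeatureMatrix
from .profiles import bh_fdr
from .rdm import RDM, condensed_index

log = logging.getLogger(__name__)


class RSAError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Rank correlation


def _tie_term(v: np.ndarray) -> int:
    _, counts = np.unique(v, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def kendall_tau_a(x, y) -> float:
    """Kendall's tau-a: (concordant - discordant) / (m*(m-1)/2).

    Tied pairs in either vector count toward neither C nor D, so ties
    penalize the correlation (unlike tau-b).  Returns a value in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise RSAError("inputs must be 1-D vectors of equal length")
    m = x.size
    if m < 2:
        raise RSAError("need at least two entries")
    n0 = m * (m - 1) // 2
    n1, n2 = _tie_term(x), _tie_term(y)
    if n0 - n1 == 0 or n0 - n2 == 0:
        return 0.0  # constant vector: C = D = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau_b = stats.kendalltau(x, y).statistic
    if np.isnan(tau_b):
        return 0.0
    cd = round(tau_b * np.sqrt((n0 - n1) * (n0 - n2)))
    return cd / n0


# ---------------------------------------------------------------------------
# Non-negative least squares


def nnls_fit(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """w >= 0 minimizing ||A w - b||^2 (zero columns get weight 0)."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise RSAError("non-finite values in NNLS inputs")
    zero_cols = ~np.any(A != 0, axis=0)
    if zero_cols.any():
        log.warning("NNLS design has %d all-zero column(s); their weights are 0", zero_cols.sum())
    w, _ = _scipy_nnls(A, b)
    return w


# ---------------------------------------------------------------------------
# Model specifications and feature RDMs


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model RDM: a feature subset and how it is combined."""

    name: str
    kind: str  # "weighted" | "unweighted" | "single" | "theme"
    features: tuple

    def __post_init__(self):
        if self.kind not in ("weighted", "unweighted", "single", "theme"):
            raise RSAError(f"unknown model kind: {self.kind!r}")
        if not self.features:
            raise RSAError("model feature subset must be non-empty")


@dataclass(frozen=True)
class FeatureRDMs:
    """Single-feature RDM design: columns of F are condensed 1-D distance vectors."""

    item_ids: tuple
    feature_ids: tuple
    F: np.ndarray  # (n_pairs, n_features)


def build_feature_rdms(fm: FeatureMatrix) -> FeatureRDMs:
    X = fm.values.to_numpy()
    cols = [pdist(X[:, [j]]) for j in range(X.shape[1])]
    return FeatureRDMs(tuple(fm.actions), tuple(fm.features), np.column_stack(cols))


def default_models(fm: FeatureMatrix, min_theme_features: int = 2) -> list:
    """Weighted + unweighted multi-feature, all single-feature, all multi-feature-theme models."""
    feats = tuple(fm.features)
    models = [
        ModelSpec("weighted_multi_feature", "weighted", feats),
        ModelSpec("unweighted_multi_feature", "unweighted", feats),
    ]
    for f in feats:
        models.append(ModelSpec(f"single:{f}", "single", (f,)))
    for theme in fm.schema.themes:
        ids = tuple(f for f in fm.schema.theme_features(theme) if f in feats)
        if len(ids) >= min_theme_features:
            models.append(ModelSpec(f"theme:{theme}", "theme", ids))
    return models


def model_vector(model: ModelSpec, fm: FeatureMatrix) -> np.ndarray:
    """Condensed model RDM for any non-weighted model (Euclidean over its features)."""
    if model.kind == "weighted":
        raise RSAError("the weighted model has no fixed vector; weights are fit per fold")
    X = fm.values[list(model.features)].to_numpy()
    return pdist(X)


# ---------------------------------------------------------------------------
# Cross-validated reweighting


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 50
    test_actions: int = 10
    test_participants: int = 5
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        if min(self.n_folds, self.test_actions, self.test_participants, self.n_boot) < 1:
            raise RSAError("all CV settings must be positive")


@dataclass
class ModelFit:
    name: str
    tau: float
    nc_lower: float
    nc_upper: float
    weights: pd.Series | None = None
    ci: tuple | None = None
    p: float | None = None
    q: float | None = None
    meta: dict = field(default_factory=dict)


def noise_ceiling(subject_vectors) -> tuple:
    """(lower, upper) tau-a noise ceiling of per-participant RDM vectors.

    upper: mean correlation of each participant with the group mean
    including that participant; lower: with the leave-one-out mean.
    """
    if isinstance(subject_vectors, (list, tuple)) and isinstance(subject_vectors[0], RDM):
        S = np.vstack([r.d for r in subject_vectors])
    else:
        S = np.asarray(subject_vectors, dtype=float)
    P = S.shape[0]
    if P < 2:
        raise RSAError("noise ceiling needs at least two participants")
    total = S.sum(axis=0)
    upper = np.mean([kendall_tau_a(S[i], total / P) for i in range(P)])
    lower = np.mean([kendall_tau_a(S[i], (total - S[i]) / (P - 1)) for i in range(P)])
    return float(lower), float(upper)


def _pair_items(n: int) -> tuple:
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def _run_cv(S, F, vectors, weighted_names, ia, ib, n_items, cfg, rng):
    """Core fold loop over an arbitrary pair universe.

    S: (P, m) subject vectors; F: (m, nf) single-feature design;
    vectors: {model name: (m,) fixed model vector}; ia/ib: item index of
    each pair's endpoints; returns per-model mean tau, mean weights,
    mean noise-ceiling bounds.
    """
    P = S.shape[0]
    if P < cfg.test_participants + 1:
        raise RSAError("need more participants than test_participants")
    if n_items < cfg.test_actions + 2:
        raise RSAError("need at least test_actions + 2 items")
    names = list(weighted_names) + list(vectors)
    taus = {name: [] for name in names}
    ws, lowers, uppers = [], [], []
    used = 0
    for _ in range(cfg.n_folds):
        test_items = rng.choice(n_items, size=cfg.test_actions, replace=False)
        test_p = rng.choice(P, size=cfg.test_participants, replace=False)
        item_is_test = np.zeros(n_items, dtype=bool)
        item_is_test[test_items] = True
        test_pair = item_is_test[ia] & item_is_test[ib]
        train_pair = ~item_is_test[ia] & ~item_is_test[ib]
        p_is_test = np.zeros(P, dtype=bool)
        p_is_test[test_p] = True
        b_test = S[p_is_test][:, test_pair].mean(axis=0)
        if test_pair.sum() < 2 or np.ptp(b_test) == 0:
            log.warning("degenerate fold (constant test vector); skipped")
            continue
        b_train = S[~p_is_test][:, train_pair].mean(axis=0)
        w = nnls_fit(F[train_pair], b_train)
        ws.append(w)
        for name in weighted_names:
            taus[name].append(kendall_tau_a(F[test_pair] @ w, b_test))
        for name, vec in vectors.items():
            taus[name].append(kendall_tau_a(vec[test_pair], b_test))
        lo, up = noise_ceiling(S[p_is_test][:, test_pair])
        lowers.append(lo)
        uppers.append(up)
        used += 1
    if used == 0:
        raise RSAError("all cross-validation folds were degenerate")
    return {
        "tau": {name: float(np.mean(v)) for name, v in taus.items()},
        "weights": np.mean(ws, axis=0),
        "nc_lower": float(np.mean(lowers)),
        "nc_upper": float(np.mean(uppers)),
        "n_folds_used": used,
    }


def _prepare(subject_rdms, models, feature_rdms, fm):
    ids = feature_rdms.item_ids
    S = []
    for r in subject_rdms:
        if r.item_ids != ids:
            raise RSAError("subject RDMs and feature RDMs must share one item set/order")
        S.append(r.d)
    S = np.vstack(S)
    vectors = {}
    weighted = []
    for m in models:
        if m.kind == "weighted":
            weighted.append(m.name)
        else:
            vectors[m.name] = model_vector(m, fm)
    return S, vectors, weighted


def cv_reweight(
    subject_rdms: Sequence[RDM],
    models: Sequence[ModelSpec],
    feature_rdms: FeatureRDMs,
    fm: FeatureMatrix,
    cfg: CVConfig,
) -> dict:
    """Cross-validated model evaluation; returns {model name: ModelFit}.

    Per fold, NNLS weights are fit to the training-participant mean RDM on
    training-action pairs and every model's tau-a is evaluated against the
    test-participant mean RDM on test-action pairs; taus, weights and
    noise-ceiling bounds are averaged over folds.  Deterministic given
    ``cfg.seed``.
    """
    S, vectors, weighted = _prepare(subject_rdms, models, feature_rdms, fm)
    n = len(feature_rdms.item_ids)
    ia, ib = _pair_items(n)
    rng = np.random.default_rng(cfg.seed)
    res = _run_cv(S, feature_rdms.F, vectors, weighted, ia, ib, n, cfg, rng)
    wser = pd.Series(res["weights"], index=list(feature_rdms.feature_ids))
    fits = {}
    for m in models:
        fits[m.name] = ModelFit(
            name=m.name,
            tau=res["tau"][m.name],
            nc_lower=res["nc_lower"],
            nc_upper=res["nc_upper"],
            weights=wser if m.kind == "weighted" else None,
            meta={"n_folds_used": res["n_folds_used"]},
        )
    return fits


def _bootstrap_universe(n: int, rng):
    """Resampled-stimulus pair universe, excluding self-pairs of duplicated items."""
    while True:
        pos = rng.integers(0, n, size=n)
        if np.unique(pos).size >= 3:
            break
        log.warning("bootstrap sample with < 3 distinct items; redrawn")
    src, ka, kb = [], [], []
    for a in range(n - 1):
        for b in range(a + 1, n):
            if pos[a] == pos[b]:
                continue
            src.append(condensed_index(int(pos[a]), int(pos[b]), n))
            ka.append(a)
            kb.append(b)
    return np.asarray(src), np.asarray(ka), np.asarray(kb)


def bootstrap_models(
    subject_rdms: Sequence[RDM],
    models: Sequence[ModelSpec],
    feature_rdms: FeatureRDMs,
    fm: FeatureMatrix,
    cfg: CVConfig,
    q_level: float = 0.05,
):
    """Stimulus-bootstrap inference over the cross-validated model taus.

    Each bootstrap sample redraws the stimuli with replacement (pairs of
    duplicated identical items are excluded from the condensed vectors) and
    reruns the full cross-validation; per-model two-sided p-values are
    bootstrap tail probabilities of tau <= 0, pairwise model differences
    are tested on the paired bootstrap distributions, and both families are
    BH-FDR corrected.  p-values are floored at 1/(n_boot + 1).

    Returns ``(fits, model_table, difference_table)``.
    """
    fits = cv_reweight(subject_rdms, models, feature_rdms, fm, cfg)
    S, vectors, weighted = _prepare(subject_rdms, models, feature_rdms, fm)
    n = len(feature_rdms.item_ids)
    names = [m.name for m in models]
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]).generate_state(1)[0])
    boot = {name: np.empty(cfg.n_boot) for name in names}
    for b in range(cfg.n_boot):
        src, ka, kb = _bootstrap_universe(n, rng)
        vec_b = {name: v[src] for name, v in vectors.items()}
        res = _run_cv(S[:, src], feature_rdms.F[src], vec_b, weighted, ka, kb, n, cfg, rng)
        for name in names:
            boot[name][b] = res["tau"][name]
    floor = 1.0 / (cfg.n_boot + 1)

    def tail_p(v):
        lo = np.mean(v <= 0)
        hi = np.mean(v >= 0)
        return float(np.clip(2 * min(lo, hi), floor, 1.0))

    rows = []
    for name in names:
        v = boot[name]
        rows.append(
            {
                "model": name,
                "tau": fits[name].tau,
                "ci_lo": float(np.percentile(v, 2.5)),
                "ci_hi": float(np.percentile(v, 97.5)),
                "p": tail_p(v),
            }
        )
    table = pd.DataFrame(rows).set_index("model")
    _, table["q"] = bh_fdr(table["p"].to_numpy(), q_level=q_level)
    table["significant"] = table["q"] < q_level
    for name in names:
        fits[name].ci = (table.at[name, "ci_lo"], table.at[name, "ci_hi"])
        fits[name].p = float(table.at[name, "p"])
        fits[name].q = float(table.at[name, "q"])

    diff_rows = []
    for a, b_ in itertools.combinations(names, 2):
        d = boot[a] - boot[b_]
        diff_rows.append(
            {
                "model_a": a,
                "model_b": b_,
                "delta_tau": fits[a].tau - fits[b_].tau,
                "ci_lo": float(np.percentile(d, 2.5)),
                "ci_hi": float(np.percentile(d, 97.5)),
                "p": tail_p(d),
            }
        )
    diffs = pd.DataFrame(diff_rows)
    if len(diffs):
        _, diffs["q"] = bh_fdr(diffs["p"].to_numpy(), q_level=q_level)
        diffs["significant"] = diffs["q"] < q_level
    return fits, table, diffs
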