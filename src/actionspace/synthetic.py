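"""Ground-truth study simulator.

Generates everything a desk run of the pipeline needs: a planted category
structure over ~100 actions, feature loadings per action, noisy binary and
1-7 raters, and arranging participants whose trials reflect a noisy
subject-specific RDM laid out in a circular arena.

Design of the action space: feature loadings are driven by a
low-dimensional latent space (categories are blobs of latent vectors)
mapped through per-feature logistic links, plus feature-specific unique
variance.  This emulates two salient properties of real feature-rating
data — features are strongly inter-correlated (redundant features exist
and get pruned), yet each carries some unique signal — and makes the true
RDM approximately low-rank, as behavioral RDMs that embed well in 2-D are.
A configurable number of planted near-duplicate features emulates the
redundancy removed by the pruning stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit

from .arrangement import ArrangementTrial, EvidenceState, default_subset_size, select_next_subset, update_estimate
from .features import FeatureSchema, RatingRecord, load_default_schema
from .rdm import RDM, embed_2d

# Rating-session design of the three collection waves (raters x actions each).
WAVE1_THEMES = (
    "Body parts", "Object-directedness", "Trajectory", "Type of limb movement",
    "Posture", "Location", "Keeping balance", "Duration", "Contact with others",
    "Pace", "Use of force", "Goal-directedness",
)
WAVE3_THEMES = (
    "Harm", "Water", "Season-dependence", "Change of location",
    "Concentration", "Noise", "Valence",
)
RATING_WAVES = (
    {"themes": WAVE1_THEMES, "n_raters": 17, "actions_per_rater": 25},
    {"themes": WAVE1_THEMES, "n_raters": 107, "actions_per_rater": 5},
    {"themes": WAVE3_THEMES, "n_raters": 149, "actions_per_rater": 5},
)


def wave_rating_counts() -> list:
    """Total ratings collected per wave (raters x actions per rater)."""
    return [w["n_raters"] * w["actions_per_rater"] for w in RATING_WAVES]


@dataclass(frozen=True)
class StudyConfig:
    """Generator settings; defaults mirror the emulated study's scale."""

    n_actions: int = 100
    n_categories: int = 11
    min_category_size: int = 3
    latent_dim: int = 4
    category_strength: float = 1.0   # scale of category centers in latent space
    within_sd: float = 0.2           # latent spread of actions around their center
    unique_sd: float = 0.4           # feature-specific (non-shared) signal sd
    binary_steepness: float = 4.0    # logistic link slope for binary features
    continuous_steepness: float = 1.2
    n_redundant: int = 15            # planted near-duplicate features (59 -> 44)
    redundancy_jitter: float = 0.02
    redundancy_flip_prob: float = 0.3
    delta: float = 0.8               # additive cross-category dissimilarity
    weight_density: float = 0.5      # fraction of features with true weight > 0
    weight_shape: float = 1.5        # gamma shape of nonzero true weights
    dominant_boost: float = 3.0      # one dominant feature (valence analogue)
    rater_flip: float = 0.05         # binary answer flip probability
    rater_sd: float = 0.1            # continuous rating noise sd (on [0,1] scale)
    raters_min: int = 7
    raters_max: int = 11
    participant_sd: float = 0.15     # lognormal sigma of subject RDM distortion
    arena_jitter: float = 0.02       # placement jitter sd (arena units)


def null_config(config: "StudyConfig | None" = None) -> StudyConfig:
    """No-effect variant: category membership carries no feature signal."""
    return replace(config or StudyConfig(), category_strength=0.0, delta=0.0)


@dataclass(frozen=True)
class GroundTruth:
    config: StudyConfig
    schema: FeatureSchema
    item_ids: tuple
    categories: tuple                # category labels
    assignment: dict                 # item -> category
    sizes: tuple
    F: pd.DataFrame                  # true loadings, actions x features, in [0,1]
    w: pd.Series                     # true non-negative feature weights
    redundant: tuple                 # (duplicate, base) feature-id pairs
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([self.assignment[i] for i in self.item_ids])


def _spread_centers(rng, K: int, L: int, scale: float, pool: int = 400) -> np.ndarray:
    """Well-separated category centers: greedy farthest-point pick from a pool.

    Emulates that the study's categories are mutually distinguishable;
    purely independent Gaussian centers occasionally collide in latent
    space, which no recoverable category structure would exhibit.
    """
    if scale == 0.0:
        return np.zeros((K, L))
    cand = rng.normal(0.0, scale, size=(pool, L))
    chosen = [int(rng.integers(pool))]
    for _ in range(K - 1):
        dmin = np.min(
            np.linalg.norm(cand[:, None, :] - cand[chosen][None, :, :], axis=2), axis=1
        )
        chosen.append(int(np.argmax(dmin)))
    return cand[chosen]


def _category_sizes(rng, n: int, k: int, min_size: int) -> np.ndarray:
    sizes = rng.multinomial(n, rng.dirichlet(np.full(k, 5.0)))
    while sizes.min() < min_size:
        sizes[np.argmax(sizes)] -= 1
        sizes[np.argmin(sizes)] += 1
    return sizes


def gen_ground_truth(seed: int, config: StudyConfig | None = None, schema: FeatureSchema | None = None) -> GroundTruth:
    """Draw a ground-truth study; bit-reproducible given (config, seed)."""
    cfg = config or StudyConfig()
    schema = schema or load_default_schema()
    if cfg.n_categories > cfg.n_actions:
        raise ValueError("more categories than actions")
    rng = np.random.default_rng(seed)
    n, K, L = cfg.n_actions, cfg.n_categories, cfg.latent_dim
    feats = schema.feature_ids
    nf = len(feats)

    sizes = _category_sizes(rng, n, K, min(cfg.min_category_size, n // K))
    labels = np.repeat(np.arange(K), sizes)
    item_ids = tuple(f"a{i:03d}" for i in range(n))
    cats = tuple(f"K{c + 1:02d}" for c in range(K))
    assignment = {item_ids[i]: cats[labels[i]] for i in range(n)}

    centers = _spread_centers(rng, K, L, cfg.category_strength)
    latents = centers[labels] + rng.normal(0.0, cfg.within_sd, size=(n, L))

    F = np.empty((n, nf))
    for j, fid in enumerate(feats):
        u = rng.normal(size=L)
        u /= np.linalg.norm(u)
        offset = rng.normal(0.0, 0.5)
        raw = latents @ u + offset + rng.normal(0.0, cfg.unique_sd, size=n)
        steep = cfg.binary_steepness if schema[fid].scale == "binary" else cfg.continuous_steepness
        F[:, j] = expit(steep * raw)

    # Planted near-duplicates: redundancy the pruning stage should remove.
    # Bases are drawn from the most bimodal (highest-variance) features, as
    # real redundant rating items are strongly action-discriminating ones.
    pairs = []
    if cfg.n_redundant > 0:
        by_var = np.argsort(F.var(axis=0))[::-1][: 2 * cfg.n_redundant]
        picked = rng.permutation(by_var)
        for k in range(cfg.n_redundant):
            dup, base = int(picked[2 * k]), int(picked[2 * k + 1])
            col = F[:, base]
            if rng.random() < cfg.redundancy_flip_prob:
                col = 1.0 - col
            F[:, dup] = np.clip(col + rng.normal(0.0, cfg.redundancy_jitter, size=n), 0.0, 1.0)
            pairs.append((feats[dup], feats[base]))

    w = np.where(rng.random(nf) < cfg.weight_density, rng.gamma(cfg.weight_shape, 1.0, size=nf), 0.0)
    for dup, _ in pairs:
        w[feats.index(dup)] = 0.0
    if not np.any(w > 0):
        w[int(rng.integers(nf))] = 1.0
    w[int(np.argmax(w))] *= cfg.dominant_boost

    return GroundTruth(
        config=cfg,
        schema=schema,
        item_ids=item_ids,
        categories=cats,
        assignment=assignment,
        sizes=tuple(int(s) for s in sizes),
        F=pd.DataFrame(F, index=list(item_ids), columns=list(feats)),
        w=pd.Series(w, index=list(feats)),
        redundant=tuple(pairs),
        seed=int(seed),
    )


def gen_true_rdm(gt: GroundTruth) -> RDM:
    """True RDM: weighted Euclidean feature distance plus the cross-category offset."""
    Xw = gt.F.to_numpy() * np.sqrt(gt.w.to_numpy())
    d = pdist(Xw)
    if gt.config.delta != 0:
        lab = gt.labels
        iu, ju = np.triu_indices(len(gt.item_ids), k=1)
        d = d + gt.config.delta * (lab[iu] != lab[ju])
    return RDM(gt.item_ids, d, {"source": "ground_truth", "seed": gt.seed})


def gen_feature_ratings(
    gt: GroundTruth, seed: int, raters_per_cell: int | None = None
) -> list:
    """Noisy rating records for every (action, feature) cell.

    Binary features answer Yes with probability (1-eps)*f + eps*(1-f);
    continuous features return round(1 + 6*clip(f + N(0, sigma_r), 0, 1)).
    Each simulated rater judges all features of its assigned action; the
    number of raters per action is drawn uniformly from the configured
    range unless ``raters_per_cell`` fixes it.
    """
    cfg = gt.config
    rng = np.random.default_rng(seed)
    records: list = []
    scales = {fid: gt.schema[fid].scale for fid in gt.schema.feature_ids}
    for item in gt.item_ids:
        r_n = raters_per_cell or int(rng.integers(cfg.raters_min, cfg.raters_max + 1))
        f_row = gt.F.loc[item]
        for r in range(r_n):
            rater = f"{item}_r{r:02d}"
            for fid in gt.schema.feature_ids:
                f = float(f_row[fid])
                if scales[fid] == "binary":
                    p_yes = (1 - cfg.rater_flip) * f + cfg.rater_flip * (1 - f)
                    ans = "Yes" if rng.random() < p_yes else "No"
                else:
                    x = float(np.clip(f + rng.normal(0.0, cfg.rater_sd), 0.0, 1.0))
                    ans = int(round(1 + 6 * x))
                records.append(RatingRecord(rater, item, fid, ans))
    return records


def gen_subject_rdms(gt: GroundTruth, n_participants: int, seed: int) -> list:
    """Per-participant RDMs: true RDM with multiplicative lognormal noise."""
    true = gen_true_rdm(gt)
    rng = np.random.default_rng(seed)
    out = []
    for p in range(n_participants):
        noise = np.exp(rng.normal(0.0, gt.config.participant_sd, size=true.d.size))
        out.append(RDM(gt.item_ids, true.d * noise, {"participant": f"s{p:02d}"}))
    return out


def effective_true_weights(gt: GroundTruth, fm_full, retained) -> pd.Series:
    """True generator weights re-expressed on a retained feature subset.

    Redundant features make weights identifiable only up to aliasing: when
    pruning removes a feature that carries true weight, an (almost)
    collinear retained feature absorbs it in any fit.  Each dropped
    feature's weight is therefore reassigned to the retained feature it
    correlates most strongly with in the full aggregated matrix
    ``fm_full``.
    """
    retained = list(retained)
    w_eff = gt.w[retained].copy()
    corr = fm_full.values.corr().abs()
    for f in gt.w.index:
        if f in retained or gt.w[f] == 0:
            continue
        target = corr.loc[f, retained].idxmax()
        w_eff[target] += gt.w[f]
    return w_eff


@dataclass(frozen=True)
class ProtocolConfig:
    """Adaptive multi-arrangement session settings (emulating a thorough session)."""

    max_trials: int = 24
    evidence_threshold: float = 0.5
    subset_floor: int = 3
    arena_fill: float = 0.92
    embed_restarts: int = 2
    embed_max_iter: int = 200
    embed_eps: float = 1e-7


def _sub_rdm(d_square: np.ndarray, idx: np.ndarray, ids: Sequence[str]) -> RDM:
    sub = d_square[np.ix_(idx, idx)]
    return RDM(tuple(ids), squareform(sub, checks=False))


def gen_participant_trials(
    gt: GroundTruth,
    n_participants: int,
    seed: int,
    protocol: ProtocolConfig | None = None,
) -> list:
    """Simulated arrangement trial logs for ``n_participants`` subjects.

    Each subject's RDM is the true RDM under multiplicative lognormal
    distortion.  The session mimics the adaptive design: a first full-arena
    trial, then subsets of the least-evidenced items, each laid out by 2-D
    non-metric MDS of the subject's sub-RDM, scaled into the arena and
    jittered; the session ends when all pairwise evidence reaches the
    threshold or the trial budget is spent.
    """
    proto = protocol or ProtocolConfig()
    cfg = gt.config
    true = gen_true_rdm(gt)
    rng = np.random.default_rng(seed)
    item_ids = gt.item_ids
    n = len(item_ids)
    pos = {it: k for k, it in enumerate(item_ids)}
    trials: list = []
    for p in range(n_participants):
        pid = f"s{p:02d}"
        noise = np.exp(rng.normal(0.0, cfg.participant_sd, size=true.d.size))
        subj_square = squareform(true.d * noise, checks=False)
        state = EvidenceState.empty(item_ids)
        for t in range(proto.max_trials):
            if t == 0:
                items = list(item_ids)
            else:
                k = max(proto.subset_floor, min(default_subset_size(state, proto.subset_floor), n))
                items = select_next_subset(state, max(3, k))
            idx = np.asarray([pos[it] for it in items])
            sub = _sub_rdm(subj_square, idx, items)
            if np.all(sub.d == 0):
                coords = np.zeros((len(items), 2))
            else:
                emb = embed_2d(
                    sub,
                    seed=int(rng.integers(2**31)),
                    restarts=proto.embed_restarts,
                    max_iter=proto.embed_max_iter,
                    eps=proto.embed_eps,
                )
                coords = emb.coords - emb.coords.mean(axis=0)
                rmax = np.max(np.linalg.norm(coords, axis=1))
                if rmax > 0:
                    coords = coords * (proto.arena_fill / rmax)
            if cfg.arena_jitter > 0:
                coords = coords + rng.normal(0.0, cfg.arena_jitter, size=coords.shape)
            norms = np.linalg.norm(coords, axis=1)
            over = norms > 1.0
            if over.any():
                coords[over] /= norms[over, None]
            trial = ArrangementTrial(pid, tuple(items), coords)
            trials.append(trial)
            state = update_estimate(state, trial)
            if state.seen.all() and state.e.min() >= proto.evidence_threshold:
                break
    return trials
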