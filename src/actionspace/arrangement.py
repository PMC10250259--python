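"""Multi-arrangement trials: evidence accumulation and RDM reconstruction.

In a multi-arrangement session a participant repeatedly drags a subset of
the stimuli inside a unit-radius circular arena so that on-screen distance
expresses dissimilarity.  Each trial yields partial pairwise distances on
an arbitrary per-trial scale.  The estimator aligns every trial to the
running estimate with a least-squares scalar, accumulates per-pair
evidence (squared aligned distance by default: well-separated pairs are
better resolved), and maintains an evidence-weighted mean distance
estimate.  Subsets for subsequent trials are chosen adaptively as the
items with the least total evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .rdm import RDM, condensed_index

log = logging.getLogger(__name__)


class TrialError(ValueError):
    pass


class CoverageError(ValueError):
    """Some item pair was never co-presented in any trial."""


@dataclass(frozen=True)
class ArrangementTrial:
    """One participant's placement of an item subset in the arena.

    Coordinates are in arena units (the arena is the unit disk).
    """

    participant_id: str
    items: tuple
    coords: np.ndarray  # (k, 2)

    def __post_init__(self):
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if len(items) < 2:
            raise TrialError("a trial needs at least two items")
        if len(set(items)) != len(items):
            raise TrialError(f"duplicate item in trial: {items}")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(items), 2):
            raise TrialError("coords must be (n_items, 2)")
        r2 = np.sum(coords**2, axis=1)
        if np.any(r2 > 1.0 + 1e-9):
            bad = items[int(np.argmax(r2))]
            raise TrialError(f"item {bad!r} placed outside the unit arena")
        object.__setattr__(self, "coords", coords)


def trial_distances(trial: ArrangementTrial) -> np.ndarray:
    """Condensed Euclidean screen distances over the trial's item pairs."""
    return pdist(trial.coords)


@dataclass
class EvidenceState:
    """Running pairwise evidence and distance estimate for one participant."""

    item_ids: tuple
    e: np.ndarray       # condensed evidence, >= 0
    d_hat: np.ndarray   # condensed estimate; meaningful only where seen
    seen: np.ndarray    # condensed bool: pair co-presented at least once

    @classmethod
    def empty(cls, item_ids: Sequence[str]) -> "EvidenceState":
        ids = tuple(item_ids)
        m = len(ids) * (len(ids) - 1) // 2
        return cls(ids, np.zeros(m), np.zeros(m), np.zeros(m, dtype=bool))

    def item_evidence(self) -> np.ndarray:
        """Total evidence per item (sum over pairs containing it)."""
        n = len(self.item_ids)
        totals = np.zeros(n)
        iu, ju = np.triu_indices(n, k=1)
        np.add.at(totals, iu, self.e)
        np.add.at(totals, ju, self.e)
        return totals


def _trial_pair_indices(state: EvidenceState, trial: ArrangementTrial) -> np.ndarray:
    pos = {item: k for k, item in enumerate(state.item_ids)}
    try:
        gidx = [pos[it] for it in trial.items]
    except KeyError as exc:
        raise TrialError(f"trial item {exc.args[0]!r} not in state item set") from None
    n = len(state.item_ids)
    k = len(gidx)
    out = []
    for a in range(k - 1):
        for b in range(a + 1, k):
            out.append(condensed_index(gidx[a], gidx[b], n))
    return np.asarray(out, dtype=int)


def update_estimate(
    state: EvidenceState, trial: ArrangementTrial, evidence_exponent: float = 2.0
) -> EvidenceState:
    """Fold one trial into the evidence state (returns a new state).

    The trial's screen distances are scale-aligned to the current estimate
    by a least-squares scalar over pairs that already carry evidence; the
    very first trial is normalized to unit root-mean-square.  Each observed
    pair then contributes the aligned distance with weight
    ``aligned**evidence_exponent``, and the estimate becomes the
    evidence-weighted mean of all aligned observations.
    """
    idx = _trial_pair_indices(state, trial)
    t = trial_distances(trial)
    if np.all(t == 0):
        log.warning(
            "trial for participant %s has all-zero distances; zero evidence contributed",
            trial.participant_id,
        )
        seen = state.seen.copy()
        seen[idx] = True
        return EvidenceState(state.item_ids, state.e.copy(), state.d_hat.copy(), seen)

    overlap = state.e[idx] > 0
    if overlap.any() and float(np.sum(t[overlap] ** 2)) > 0:
        scale = float(np.sum(t[overlap] * state.d_hat[idx][overlap]) / np.sum(t[overlap] ** 2))
        if scale <= 0:
            scale = 1.0 / np.sqrt(np.mean(t**2))
    else:
        scale = 1.0 / np.sqrt(np.mean(t**2))
    aligned = scale * t
    w = aligned**evidence_exponent

    e = state.e.copy()
    d_hat = state.d_hat.copy()
    seen = state.seen.copy()
    tot = e[idx] + w
    nz = tot > 0
    upd = idx[nz]
    d_hat[upd] = (e[upd] * d_hat[upd] + w[nz] * aligned[nz]) / tot[nz]
    e[idx] = tot
    seen[idx] = True
    return EvidenceState(state.item_ids, e, d_hat, seen)


def select_next_subset(state: EvidenceState, k: int) -> list:
    """The k items with least total pairwise evidence (ties by item order)."""
    n = len(state.item_ids)
    if not (2 <= k <= n):
        raise ValueError(f"subset size {k} out of range [2, {n}]")
    totals = state.item_evidence()
    chosen = np.sort(np.argsort(totals, kind="stable")[:k])
    return [state.item_ids[i] for i in chosen]


def aggregate_participant(
    trials: Sequence[ArrangementTrial],
    item_ids: Sequence[str] | None = None,
    evidence_exponent: float = 2.0,
) -> RDM:
    """Fold a participant's trials into an RDM estimate.

    Raises :class:`CoverageError` if any pair was never co-presented.
    """
    trials = list(trials)
    if not trials:
        raise TrialError("no trials")
    if item_ids is None:
        seen_ids: dict = {}
        for tr in trials:
            for it in tr.items:
                seen_ids.setdefault(it, None)
        item_ids = sorted(seen_ids)
    state = EvidenceState.empty(item_ids)
    for tr in trials:
        state = update_estimate(state, tr, evidence_exponent=evidence_exponent)
    if not state.seen.all():
        n = len(state.item_ids)
        iu, ju = np.triu_indices(n, k=1)
        missing = [
            (state.item_ids[i], state.item_ids[j])
            for i, j in zip(iu[~state.seen], ju[~state.seen])
        ]
        shown = ", ".join(f"{a}-{b}" for a, b in missing[:10])
        raise CoverageError(
            f"{len(missing)} item pair(s) never co-presented (e.g. {shown})"
        )
    pid = trials[0].participant_id
    return RDM(state.item_ids, state.d_hat, {"participant": pid, "n_trials": len(trials)})


def default_subset_size(state: EvidenceState, floor: int = 3) -> int:
    """Adaptive subset-size schedule: all items below the evidence median.

    Falls back to ``floor`` when fewer items qualify; capped at n.
    """
    totals = state.item_evidence()
    below = int(np.sum(totals < np.median(totals)))
    return min(len(state.item_ids), max(floor, below))
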