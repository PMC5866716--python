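"""Simple- and weighted-vote fusion of habitat maps.

Per pixel, every member map casts one vote for its label; the simple-vote
ensemble weights members equally, the weighted-vote ensemble weights each
member by its overall accuracy on the validation set (any non-negative
weights are accepted; a common rescaling cannot change the argmax).

Tie handling is deterministic, order-independent and auditable: among the
tied classes, prefer the one supported by the member with the highest
tie-break weight (for the simple vote, the supplied accuracies; absent
those, fall back directly to the lowest class id). Pixels decided by the
tie-break are counted and returned as a mask. A member whose pixel is
nodata abstains there; the fused pixel is nodata only if every member
abstains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .raster import HabitatMap, _require_same_grid


@dataclass
class EnsembleResult:
    member_ids: list[str]
    weights: np.ndarray
    voted_map: HabitatMap
    tie_count: int
    tie_mask: np.ndarray


def majority_vote(maps: Sequence[HabitatMap],
                  member_ids: Sequence[str] | None = None,
                  accuracies: Sequence[float] | None = None) -> EnsembleResult:
    """Equal-weight ("select all majority") vote across member maps.

    ``accuracies``, if given, are used only to break ties (highest-accuracy
    supporter wins); they do not weight the votes themselves.
    """
    n = _check_members(maps)
    weights = np.ones(n)
    tb = None if accuracies is None else np.asarray(accuracies, dtype=float)
    if tb is not None and len(tb) != n:
        raise ValueError("accuracies length does not match number of maps")
    return _vote(maps, weights, tb, member_ids)


def weighted_vote(maps: Sequence[HabitatMap], weights: Sequence[float],
                  member_ids: Sequence[str] | None = None) -> EnsembleResult:
    """Accuracy-weighted vote; invariant to common rescaling of weights."""
    n = _check_members(maps)
    w = np.asarray(weights, dtype=float)
    if len(w) != n:
        raise ValueError(f"{n} maps but {len(w)} weights")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if not (w > 0).any():
        raise ValueError("at least one weight must be positive")
    return _vote(maps, w, w, member_ids)


def _check_members(maps: Sequence[HabitatMap]) -> int:
    if len(maps) == 0:
        raise ValueError("need at least one member map")
    g0 = maps[0].grid
    legend0 = maps[0].legend
    for m in maps[1:]:
        _require_same_grid(g0, m.grid, "member maps")
        if m.legend != legend0:
            raise ValueError("member maps must share one legend")
    return len(maps)


def _vote(maps, weights, tiebreak_weights, member_ids) -> EnsembleResult:
    n = len(maps)
    if member_ids is None:
        member_ids = [f"m{i}" for i in range(n)]
    member_ids = list(member_ids)
    # canonical member order: by id, so input order cannot perturb float sums
    order = sorted(range(n), key=lambda i: member_ids[i])
    maps = [maps[i] for i in order]
    weights = np.asarray(weights, dtype=float)[order]
    tb = None if tiebreak_weights is None else \
        np.asarray(tiebreak_weights, dtype=float)[order]
    ids_sorted = [member_ids[i] for i in order]

    legend = dict(maps[0].legend)
    class_ids = np.array(sorted(legend), dtype=np.int64)
    k = len(class_ids)
    grid = maps[0].grid
    nodata = maps[0].nodata
    labels = np.stack([m.labels for m in maps])          # (n, R, C)
    votes = labels[:, None, :, :] == class_ids[None, :, None, None]
    scores = np.einsum("i,ikrc->krc", weights, votes)    # (k, R, C)
    voted_for = votes.any(axis=0)                        # (k, R, C)
    any_vote = voted_for.any(axis=0)                     # at least one member voted
    best = scores.max(axis=0)
    is_max = (scores == best[None]) & voted_for
    n_max = is_max.sum(axis=0)
    winner_idx = np.argmax(is_max, axis=0)               # lowest class id among tied

    tie_mask = (n_max > 1) & any_vote
    if tie_mask.any() and tb is not None:
        rr, cc = np.nonzero(tie_mask)
        for r, c in zip(rr.tolist(), cc.tolist()):
            cand = np.nonzero(is_max[:, r, c])[0]
            support = np.full(len(cand), -np.inf)
            for j, ci in enumerate(cand):
                voters = votes[:, ci, r, c]
                if voters.any():
                    support[j] = tb[voters].max()
            best_support = support.max()
            top = cand[support == best_support]
            winner_idx[r, c] = top.min()                 # lowest class id fallback

    out = np.where(any_vote, class_ids[winner_idx], nodata)
    voted = HabitatMap(out, legend, grid, nodata=nodata)
    return EnsembleResult(ids_sorted, weights, voted,
                          int(tie_mask.sum()), tie_mask)
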