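"""Choice-set reconstruction.

A choice set is the intersection of a spatial neighborhood and a single
restaurant category: the options a decider plausibly weighed against the
restaurant they picked.  Three steps build them from raw records:

1. :func:`infer_primary_category` — each restaurant carries several assigned
   category terms; the single primary category is the term occurring most
   often in the restaurant's review texts (whole-word, case-insensitive),
   so every restaurant lands in exactly one set.
2. :func:`dbscan` — neighborhoods come from density-based spatial clustering
   of review coordinates (one point per review, so popular restaurants carry
   multiplicity), with per-city parameters picked by
   :func:`tune_dbscan_params` from nearest-neighbor distances.
3. :func:`build_choice_sets` — partition non-noise restaurants by
   (city, cluster, category).

:func:`filter_events` then applies the eligibility rules: sets of >= 3
restaurants showing >= 3 unique ratings at decision time, users with >= 100
reviews analyzed in their most-reviewed city, and >= 5 restaurants for
delivery-order sets.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .rating_state import RatingState
from .synthetic_world import UMBRELLA_TERM, CheckInEvent, OrderEvent, ReviewEvent

logger = logging.getLogger(__name__)

NOISE = -1

__all__ = [
    "NOISE",
    "NoCategoryError",
    "CategoryAssignment",
    "ClusterLabeling",
    "ChoiceSetDefinition",
    "infer_primary_category",
    "dbscan",
    "tune_dbscan_params",
    "build_choice_sets",
    "filter_events",
]


class NoCategoryError(ValueError):
    """Raised when a business has no category terms besides the umbrella."""


@dataclass(frozen=True)
class CategoryAssignment:
    business_id: str | None
    primary_term: str
    term_counts: dict


@dataclass(frozen=True)
class ClusterLabeling:
    """Per-point cluster labels (>= 0) with NOISE = -1."""

    labels: np.ndarray
    eps: float
    min_pts: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if len(self.labels) else 0


@dataclass(frozen=True)
class ChoiceSetDefinition:
    set_id: tuple  # (city, cluster index, category term)
    member_ids: tuple

    @property
    def city(self) -> str:
        return self.set_id[0]

    @property
    def category(self) -> str:
        return self.set_id[2]


# --------------------------------------------------------------------------
# category inference
# --------------------------------------------------------------------------


def _term_pattern(term: str) -> re.Pattern:
    # whole-word match; multi-word terms matched as whitespace-separated phrases
    parts = [re.escape(p) for p in term.lower().split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(parts) + r"(?!\w)")


def infer_primary_category(
    assigned_terms: Sequence[str],
    review_texts: Sequence[str],
    business_id: str | None = None,
) -> CategoryAssignment:
    """Pick the assigned category term occurring most often in review text.

    The umbrella term "Restaurants" identifies the business as a restaurant
    but never competes as a category.  Ties (including the no-text fallback)
    go to the higher count, then the earlier position in ``assigned_terms``,
    then lexicographic order.

    Raises :class:`NoCategoryError` when no non-umbrella term exists — a
    condition distinct from empty review text, which falls back to the first
    assigned term with a logged warning.
    """
    candidates = [t for t in assigned_terms if t != UMBRELLA_TERM]
    if not candidates:
        raise NoCategoryError(
            f"business {business_id!r} has no category terms besides the umbrella"
        )
    text = "\n".join(t.lower() for t in review_texts)
    counts = {t: len(_term_pattern(t).findall(text)) for t in candidates}
    if not review_texts or all(c == 0 for c in counts.values()):
        if not review_texts:
            logger.warning(
                "business %r has no review text; falling back to first term %r",
                business_id,
                candidates[0],
            )
        primary = candidates[0]
    else:
        order = {t: i for i, t in enumerate(candidates)}
        primary = max(candidates, key=lambda t: (counts[t], -order[t], t))
    return CategoryAssignment(business_id=business_id, primary_term=primary, term_counts=counts)


# --------------------------------------------------------------------------
# DBSCAN
# --------------------------------------------------------------------------


def dbscan(
    points: Sequence,
    eps: float,
    min_pts: float,
    sample_weight: Sequence[float] | None = None,
) -> ClusterLabeling:
    """Density-based spatial clustering (classic DBSCAN semantics).

    Euclidean distance in the raw coordinate units (decimal degrees for GPS
    input).  A point is *core* when the total weight of points within
    ``eps`` — including itself — is at least ``min_pts`` (weights default
    to 1, so weight = point count; review-multiplicity input can instead be
    passed as unique coordinates with per-point weights, which is exactly
    equivalent).  Clusters grow from core points in index order; border
    points join the first cluster that discovers them, making the labeling
    deterministic for a fixed point order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return ClusterLabeling(labels=np.empty(0, dtype=int), eps=eps, min_pts=min_pts)
    if pts.ndim != 2:
        pts = pts.reshape(len(pts), -1)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    n = len(pts)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if len(w) != n:
        raise ValueError("sample_weight length mismatch")
    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, eps)
    core = np.array([w[idx].sum() >= min_pts for idx in neighborhoods])
    labels = np.full(n, NOISE, dtype=int)
    cid = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        labels[i] = cid
        queue = list(neighborhoods[i])
        qi = 0
        while qi < len(queue):
            j = queue[qi]
            qi += 1
            if labels[j] == NOISE:
                labels[j] = cid
                if core[j]:
                    queue.extend(neighborhoods[j])
        cid += 1
    return ClusterLabeling(labels=labels, eps=eps, min_pts=min_pts)


def tune_dbscan_params(
    points: Sequence,
    target_min_pts_fraction: float = 0.01,
    k: int = 4,
    quantile: float = 0.5,
    total_weight: float | None = None,
) -> tuple[float, float]:
    """Per-city DBSCAN parameters from nearest-neighbor analysis.

    ``eps`` is the ``quantile`` (default median) of the k-th
    nearest-neighbor distance over ``points`` (floored at 1e-6 degrees for
    degenerate all-identical input); ``min_pts`` is
    ``max(3, round(target_min_pts_fraction * n_points))`` where the point
    count is ``total_weight`` when given (review-weighted clustering) and
    ``len(points)`` otherwise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        pts = pts.reshape(len(pts), -1)
    if len(pts) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {len(pts)}")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k + 1)
    knn = dists[:, k]
    eps = max(float(np.quantile(knn, quantile)), 1e-6)
    n = total_weight if total_weight is not None else len(pts)
    min_pts = max(3, round(target_min_pts_fraction * n))
    logger.info(
        "tuned DBSCAN: eps=%.6g (q%.2f of %d-NN over %d points), min_pts=%s",
        eps,
        quantile,
        k,
        len(pts),
        min_pts,
    )
    return eps, min_pts


# --------------------------------------------------------------------------
# set assembly
# --------------------------------------------------------------------------


def build_choice_sets(
    businesses: Sequence,
    cluster_labels: Mapping[str, int],
    assignments: Mapping[str, CategoryAssignment],
) -> list[ChoiceSetDefinition]:
    """Partition non-noise businesses into (city, cluster, category) sets.

    ``businesses`` need ``id`` and ``city`` attributes; ``cluster_labels``
    maps business id -> cluster index or NOISE.  Noise businesses belong to
    no set, so sets plus noise partition the input; each business id appears
    in at most one set globally.
    """
    seen = set()
    groups: dict[tuple, list] = {}
    for b in businesses:
        if b.id in seen:
            raise ValueError(f"duplicate business id {b.id!r}")
        seen.add(b.id)
        label = cluster_labels.get(b.id, NOISE)
        if label == NOISE or b.id not in assignments:
            continue
        key = (b.city, int(label), assignments[b.id].primary_term)
        groups.setdefault(key, []).append(b.id)
    return [
        ChoiceSetDefinition(set_id=key, member_ids=tuple(sorted(ids)))
        for key, ids in sorted(groups.items())
    ]


# --------------------------------------------------------------------------
# event eligibility
# --------------------------------------------------------------------------


def _set_eligible_at(
    set_def: ChoiceSetDefinition,
    state: RatingState,
    t: float,
    exclude_review_id: str | None,
    min_set_size: int,
    min_unique_ratings: int,
) -> tuple[bool, str | None]:
    if len(set_def.member_ids) < min_set_size:
        return False, "set_too_small"
    snap = state.snapshot(set_def, t, exclude_review_id)
    if len({o.displayed_rating for o in snap.options}) < min_unique_ratings:
        return False, "too_few_unique_ratings"
    return True, None


def filter_events(
    events: Sequence,
    sets: Sequence[ChoiceSetDefinition],
    state: RatingState | None = None,
    min_set_size: int = 3,
    min_unique_ratings: int = 3,
    min_user_reviews: int = 100,
    min_orders_set_size: int = 5,
    order_sets: Mapping[tuple, int] | None = None,
) -> tuple[list, Counter]:
    """Apply the eligibility rules; returns (eligible events, exclusion tally).

    Review events are kept when the reviewing user has at least
    ``min_user_reviews`` reviews in the stream, the event lies in the user's
    most-frequently-reviewed city, the chosen restaurant belongs to a set of
    at least ``min_set_size`` members showing at least
    ``min_unique_ratings`` distinct displayed ratings just before the
    review.  Check-in events carry no user identity, so only the set-level
    rules apply.  Order events require their (city, cuisine) set to have at
    least ``min_orders_set_size`` restaurants (pass set sizes via
    ``order_sets``).

    Exclusions are tallied by reason; kept + excluded always equals the
    input count.
    """
    set_of: dict[str, ChoiceSetDefinition] = {}
    for s in sets:
        for bid in s.member_ids:
            set_of[bid] = s

    review_events = [e for e in events if isinstance(e, ReviewEvent)]
    user_total: Counter = Counter(e.user_id for e in review_events)
    user_city_counts: dict[str, Counter] = {}
    for e in review_events:
        s = set_of.get(e.business_id)
        if s is not None:
            user_city_counts.setdefault(e.user_id, Counter())[s.city] += 1
    user_home = {
        u: max(c.items(), key=lambda kv: (kv[1], kv[0]))[0]
        for u, c in user_city_counts.items()
    }

    eligible = []
    tally: Counter = Counter()
    for e in events:
        if isinstance(e, OrderEvent):
            size = (
                order_sets.get((e.city, e.cuisine), 0)
                if order_sets is not None
                else sum(
                    1
                    for s in sets
                    if s.city == e.city and s.category == e.cuisine
                    for _ in s.member_ids
                )
            )
            if size < min_orders_set_size:
                tally["order_set_too_small"] += 1
            else:
                eligible.append(e)
            continue

        s = set_of.get(e.business_id)
        if s is None:
            tally["business_not_in_any_set"] += 1
            continue
        if isinstance(e, ReviewEvent):
            if user_total[e.user_id] < min_user_reviews:
                tally["user_below_min_reviews"] += 1
                continue
            if user_home.get(e.user_id) != s.city:
                tally["outside_home_city"] += 1
                continue
            excl: str | None = e.review_id
        elif isinstance(e, CheckInEvent):
            excl = None
        else:
            raise TypeError(f"unsupported event type {type(e).__name__}")
        if state is None:
            raise ValueError("rating state required for review/check-in events")
        ok, reason = _set_eligible_at(
            s, state, e.timestamp, excl, min_set_size, min_unique_ratings
        )
        if not ok:
            tally[reason] += 1
            continue
        snap = state.snapshot(s, e.timestamp, excl)
        if all(o.business_id != e.business_id for o in snap.options):
            tally["chosen_not_displayed"] += 1
            continue
        eligible.append(e)
    tally["kept"] = len(eligible)
    return eligible, tally
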