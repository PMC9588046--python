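"""Time-indexed displayed ratings.

A restaurant's *displayed rating* at an instant ``t`` is the mean of all star
ratings posted strictly before ``t`` — excluding, when requested, one focal
review (the review being analyzed, so the snapshot captures the information
state of the user *before* they contributed) — rounded to the nearest half
star, as review platforms display it.

:class:`RatingState` indexes a whole review stream once and then answers
prefix-mean queries and set snapshots in O(log n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

HALF_STAR_LATTICE = tuple(x / 2 for x in range(2, 11))  # 1.0, 1.5, ..., 5.0


def round_half_star(x: float) -> float:
    """Round a star value in [1, 5] to the nearest half star.

    Exact midpoints (e.g. 3.25) round *up*; the function is idempotent on its
    own output.
    """
    if not (1.0 <= x <= 5.0):
        raise ValueError(f"star value {x!r} outside [1, 5]")
    # nearest multiple of 0.5, half-up: scale by 2, round half-up, unscale
    return math.floor(2.0 * x + 0.5) / 2.0


@dataclass(frozen=True)
class DisplayedOption:
    """One option as a user would see it at a given instant."""

    business_id: str
    displayed_rating: float  # half-star lattice (or raw mean if unrounded)
    raw_prior_mean: float
    n_reviews: int
    price: int


@dataclass(frozen=True)
class SetSnapshot:
    """The visible state of a choice set at one instant.

    Members with zero prior reviews carry no displayable rating and are
    omitted (``n_omitted`` counts them).
    """

    set_id: tuple
    timestamp: float
    options: tuple
    n_omitted: int = 0

    @property
    def displayed(self) -> np.ndarray:
        return np.array([o.displayed_rating for o in self.options])

    def option(self, business_id: str) -> DisplayedOption:
        for o in self.options:
            if o.business_id == business_id:
                return o
        raise KeyError(business_id)


class RatingState:
    """Prefix means and counts over a review stream, per business.

    Parameters
    ----------
    reviews
        Iterable of objects with ``business_id``, ``review_id``, ``timestamp``
        (orderable number) and ``stars`` attributes.  Timestamps need not be
        pre-sorted; ties within a business are broken by review id.
    prices
        Optional map business_id -> price (1-4) used to decorate snapshots.
    """

    def __init__(self, reviews: Iterable, prices: Mapping[str, int] | None = None):
        per_biz: dict[str, list] = {}
        for r in reviews:
            per_biz.setdefault(r.business_id, []).append(
                (float(r.timestamp), r.review_id, float(r.stars))
            )
        self._times: dict[str, np.ndarray] = {}
        self._cumsum: dict[str, np.ndarray] = {}
        self._ids: dict[str, dict[str, int]] = {}
        self._stars: dict[str, np.ndarray] = {}
        for bid, rows in per_biz.items():
            rows.sort(key=lambda x: (x[0], x[1]))
            t = np.array([x[0] for x in rows])
            s = np.array([x[2] for x in rows], dtype=float)
            self._times[bid] = t
            self._stars[bid] = s
            self._cumsum[bid] = np.concatenate([[0.0], np.cumsum(s)])
            self._ids[bid] = {x[1]: i for i, x in enumerate(rows)}
        self._prices = dict(prices) if prices else {}

    def businesses(self) -> list[str]:
        return list(self._times)

    def n_reviews_total(self, business_id: str) -> int:
        return len(self._times.get(business_id, ()))

    def prefix_mean(
        self, business_id: str, t: float, exclude_review_id: str | None = None
    ) -> tuple[float, int]:
        """Mean and count of reviews strictly before ``t``.

        ``exclude_review_id`` is removed from the prefix even if it is
        stamped earlier than ``t``.  Returns ``(nan, 0)`` for an empty prefix.
        """
        times = self._times.get(business_id)
        if times is None:
            if exclude_review_id is not None:
                raise KeyError(
                    f"review {exclude_review_id!r} does not belong to "
                    f"unknown business {business_id!r}"
                )
            return (math.nan, 0)
        k = int(np.searchsorted(times, t, side="left"))
        total = self._cumsum[business_id][k]
        n = k
        if exclude_review_id is not None:
            pos = self._ids[business_id].get(exclude_review_id)
            if pos is None:
                raise KeyError(
                    f"review {exclude_review_id!r} does not belong to "
                    f"business {business_id!r}"
                )
            if pos < k:
                total -= self._stars[business_id][pos]
                n -= 1
        if n == 0:
            return (math.nan, 0)
        return (total / n, n)

    def snapshot(
        self,
        set_def,
        t: float,
        exclude_review_id: str | None = None,
        rounded: bool = True,
    ) -> SetSnapshot:
        """Visible state of ``set_def`` at ``t``, excluding the focal review.

        ``set_def`` is anything with ``set_id`` and ``member_ids`` attributes.
        The focal review is only excluded from the business it belongs to.
        """
        options = []
        omitted = 0
        for bid in set_def.member_ids:
            excl = (
                exclude_review_id
                if exclude_review_id is not None
                and exclude_review_id in self._ids.get(bid, {})
                else None
            )
            mean, n = self.prefix_mean(bid, t, excl)
            if n == 0:
                omitted += 1
                continue
            shown = round_half_star(mean) if rounded else mean
            options.append(
                DisplayedOption(
                    business_id=bid,
                    displayed_rating=shown,
                    raw_prior_mean=mean,
                    n_reviews=n,
                    price=int(self._prices.get(bid, 0)),
                )
            )
        return SetSnapshot(
            set_id=getattr(set_def, "set_id", None),
            timestamp=t,
            options=tuple(options),
            n_omitted=omitted,
        )
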