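"""Context-effect statistics per analyzed decision.

Each eligible event becomes one :class:`ChoiceRecord` row holding the target
indicator (did the decider pick a top-rated option?), set statistics (mean,
population variance, top-two gap, distractor mean), covariates of the
top-rated and chosen options, and — for review-based decisions — the signed
rating deviation (user's stars minus the chosen option's unrounded prior
mean).

Set-level statistics are computed over *displayed* (half-star-rounded)
ratings, the information deciders actually saw; the rating deviation uses
the unrounded prior mean because it concerns the option's running value,
not its display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .rating_state import RatingState, SetSnapshot
from .synthetic_world import ReviewEvent

__all__ = [
    "CHOICE_TABLE_COLUMNS",
    "target_indicator",
    "set_statistics",
    "rating_deviation",
    "top_option",
    "build_choice_table",
    "build_order_table",
    "build_distractor_table",
    "build_experiment_tables",
    "binned_target_rates",
]

#: Stable column order of the analysis table.
CHOICE_TABLE_COLUMNS = [
    "event_id",
    "user_id",
    "set_id",
    "n_options",
    "chosen_id",
    "is_target",
    "mean_set",
    "var_set",
    "gap12",
    "distractor_mean",
    "in_top_two",
    "n_top_ties",
    "n_second_ties",
    "price_top",
    "n_reviews_top",
    "price_chosen",
    "n_reviews_chosen",
    "review_text_length",
    "mean_set_excl_chosen",
    "raw_prior_mean_chosen",
    "user_stars",
    "rating_deviation",
]


def target_indicator(snapshot: SetSnapshot, chosen_id: str) -> bool:
    """True iff the chosen option's displayed rating ties the set maximum.

    Ties count: with several options at the (possibly non-unique) highest
    rating, choosing any of them is a ratings-maximizing choice.
    """
    ratings = snapshot.displayed
    chosen = snapshot.option(chosen_id)  # KeyError if absent
    return bool(chosen.displayed_rating == ratings.max())


def set_statistics(
    displayed: Sequence[float],
) -> tuple[float, float, float, float]:
    """(mean, population variance, top-two gap, distractor mean).

    ``gap12`` removes one instance of the maximum and subtracts the next
    order statistic, so tied maxima give gap 0.  ``distractor_mean``
    averages everything below the top two order statistics (ties at the
    second-highest value beyond the first two instances count as
    distractors) and is NaN for fewer than 3 options.
    """
    r = np.sort(np.asarray(displayed, dtype=float))[::-1]
    if r.size < 2:
        raise ValueError("set statistics need at least 2 options")
    mean = float(r.mean())
    var = float(r.var())  # population variance: the set is the whole context
    gap12 = float(r[0] - r[1])
    distractor = float(r[2:].mean()) if r.size >= 3 else math.nan
    return mean, var, gap12, distractor


def rating_deviation(user_stars: float, raw_prior_mean_chosen: float) -> float:
    """Signed deviation: the user's rating minus the chosen option's prior mean."""
    if math.isnan(raw_prior_mean_chosen):
        raise ValueError("rating deviation undefined without prior reviews")
    return float(user_stars) - float(raw_prior_mean_chosen)


def top_option(snapshot: SetSnapshot):
    """The highest-rated option; ties broken by review count then id.

    The covariates of "the" top option need a deterministic representative
    when the maximum is non-unique; the most-reviewed (then lexicographically
    first) option is used.
    """
    best = max(
        snapshot.options,
        key=lambda o: (o.displayed_rating, o.n_reviews, [-ord(c) for c in o.business_id]),
    )
    return best


def build_choice_table(
    events: Sequence,
    state: RatingState,
    sets: Sequence,
) -> pd.DataFrame:
    """One :class:`ChoiceRecord` row per eligible review/check-in event.

    Events must already have passed :func:`~contextchoice.choice_sets.filter_events`;
    rows whose chosen option is not displayed raise, since eligibility
    guaranteed it.
    """
    set_of = {}
    for s in sets:
        for bid in s.member_ids:
            set_of[bid] = s
    rows = []
    for i, e in enumerate(events):
        s = set_of[e.business_id]
        is_review = isinstance(e, ReviewEvent)
        excl = e.review_id if is_review else None
        snap = state.snapshot(s, e.timestamp, excl)
        disp = snap.displayed
        mean, var, gap12, distractor = set_statistics(disp)
        chosen = snap.option(e.business_id)
        top = top_option(snap)
        second_value = np.sort(disp)[::-1][1]
        in_top_two = bool(chosen.displayed_rating >= second_value)
        n_top_ties = int((disp == disp.max()).sum())
        n_second_ties = int((disp == second_value).sum())
        others = disp[[o.business_id != e.business_id for o in snap.options]]
        rows.append(
            {
                "event_id": e.review_id if is_review else f"checkin{i:07d}",
                "user_id": e.user_id if is_review else None,
                "set_id": "|".join(str(x) for x in s.set_id),
                "n_options": len(snap.options),
                "chosen_id": e.business_id,
                "is_target": bool(chosen.displayed_rating == disp.max()),
                "mean_set": mean,
                "var_set": var,
                "gap12": gap12,
                "distractor_mean": distractor,
                "in_top_two": in_top_two,
                "n_top_ties": n_top_ties,
                "n_second_ties": n_second_ties,
                "price_top": top.price,
                "n_reviews_top": top.n_reviews,
                "price_chosen": chosen.price,
                "n_reviews_chosen": chosen.n_reviews,
                "review_text_length": len(e.text) if is_review else np.nan,
                "mean_set_excl_chosen": float(others.mean()) if others.size else np.nan,
                "raw_prior_mean_chosen": chosen.raw_prior_mean,
                "user_stars": e.stars if is_review else np.nan,
                "rating_deviation": (
                    rating_deviation(e.stars, chosen.raw_prior_mean) if is_review else np.nan
                ),
            }
        )
    return pd.DataFrame(rows, columns=CHOICE_TABLE_COLUMNS)


def build_order_table(
    orders: Sequence,
    options: pd.DataFrame,
) -> pd.DataFrame:
    """Choice table for delivery orders with static displayed ratings.

    ``options`` is the static per-restaurant table (restaurant_id, city,
    cuisine, stars, n_ratings, price); each order row gets the same set
    statistics for its (city, cuisine) set.
    """
    cols = {"restaurant_id", "city", "cuisine", "stars", "n_ratings", "price"}
    if not cols.issubset(options.columns):
        raise ValueError(f"options table missing columns {cols - set(options.columns)}")
    per_set = {}
    for key, grp in options.groupby(["city", "cuisine"], sort=True):
        disp = grp["stars"].to_numpy(dtype=float)
        if disp.size < 2:
            continue
        mean, var, gap12, distractor = set_statistics(disp)
        top_idx = grp.index[
            np.lexsort((grp["restaurant_id"], -grp["n_ratings"], -grp["stars"]))[0]
        ]
        srt = np.sort(disp)[::-1]
        per_set[key] = {
            "disp": dict(zip(grp["restaurant_id"], disp)),
            "n_options": int(disp.size),
            "max": float(disp.max()),
            "second": float(srt[1]),
            "n_top_ties": int((disp == disp.max()).sum()),
            "n_second_ties": int((disp == srt[1]).sum()),
            "mean_set": mean,
            "var_set": var,
            "gap12": gap12,
            "distractor_mean": distractor,
            "price_top": int(grp.loc[top_idx, "price"]),
            "n_reviews_top": int(grp.loc[top_idx, "n_ratings"]),
            "price": dict(zip(grp["restaurant_id"], grp["price"])),
            "n_ratings": dict(zip(grp["restaurant_id"], grp["n_ratings"])),
        }
    rows = []
    for i, o in enumerate(orders):
        info = per_set.get((o.city, o.cuisine))
        if info is None or o.restaurant_id not in info["disp"]:
            continue
        r = info["disp"][o.restaurant_id]
        rows.append(
            {
                "event_id": f"order{i:07d}",
                "user_id": o.user_id,
                "set_id": f"{o.city}|{o.cuisine}",
                "n_options": info["n_options"],
                "chosen_id": o.restaurant_id,
                "is_target": bool(r == info["max"]),
                "mean_set": info["mean_set"],
                "var_set": info["var_set"],
                "gap12": info["gap12"],
                "distractor_mean": info["distractor_mean"],
                "in_top_two": bool(r >= info["second"]),
                "n_top_ties": info["n_top_ties"],
                "n_second_ties": info["n_second_ties"],
                "price_top": info["price_top"],
                "n_reviews_top": info["n_reviews_top"],
                "price_chosen": int(info["price"][o.restaurant_id]),
                "n_reviews_chosen": int(info["n_ratings"][o.restaurant_id]),
                "review_text_length": np.nan,
                "mean_set_excl_chosen": np.nan,
                "raw_prior_mean_chosen": r,
                "user_stars": np.nan,
                "rating_deviation": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=CHOICE_TABLE_COLUMNS)


def build_distractor_table(choice_table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Top-two subset for the IIA/distractor analysis.

    Keeps records whose chosen rating is among the top two order statistics
    in sets of at least 3 options; the response stays ``is_target`` (choice
    of the top among the top two).  Records from sets with a *tied* maximum
    are dropped: any top-two choice there is ratings-maximizing by
    definition, so the top-vs-second response carries no information.
    Returns the subset and the retained top-two fraction of the input
    (before the tie exclusion), reported for comparison with large-scale
    choice data where roughly three quarters of choices land in the top two.
    """
    if len(choice_table) == 0:
        return choice_table.copy(), math.nan
    mask = choice_table["in_top_two"] & (choice_table["n_options"] >= 3)
    sub = choice_table.loc[mask & (choice_table["gap12"] > 0)].copy()
    return sub, float(mask.mean())


def build_experiment_tables(
    trials: Sequence,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analysis tables for experiment trials: (choice_table, rating_table).

    The choice table mirrors the field-data choice table (response
    ``is_target``, context statistics of the displayed set, covariates of
    the top option) with ``user_id`` = participant.  The rating table holds
    the 0-100 expected-satisfaction response with covariates of the
    highlighted option and the set mean excluding it.
    """
    choice_rows, rating_rows = [], []
    for i, t in enumerate(trials):
        snap = t.snapshot
        disp = snap.displayed
        if t.trial_type == "choice":
            mean, var, gap12, distractor = set_statistics(disp)
            chosen = snap.option(t.response_choice)
            top = top_option(snap)
            second = np.sort(disp)[::-1][1]
            choice_rows.append(
                {
                    "event_id": f"trial{i:06d}",
                    "user_id": t.participant_id,
                    "participant_id": t.participant_id,
                    "n_options": len(snap.options),
                    "chosen_id": t.response_choice,
                    "is_target": bool(chosen.displayed_rating == disp.max()),
                    "in_top_two": bool(chosen.displayed_rating >= second),
                    "n_top_ties": int((disp == disp.max()).sum()),
                    "n_second_ties": int((disp == second).sum()),
                    "mean_set": mean,
                    "var_set": var,
                    "gap12": gap12,
                    "distractor_mean": distractor,
                    "price_top": top.price,
                    "n_reviews_top": top.n_reviews,
                }
            )
        elif t.trial_type == "rating":
            h = snap.option(t.highlighted_id)
            others = disp[[o.business_id != t.highlighted_id for o in snap.options]]
            rating_rows.append(
                {
                    "event_id": f"trial{i:06d}",
                    "participant_id": t.participant_id,
                    "n_options": len(snap.options),
                    "r_highlighted": h.displayed_rating,
                    "n_reviews_highlighted": h.n_reviews,
                    "price_highlighted": h.price,
                    "mean_set_excl_highlighted": float(others.mean()),
                    "satisfaction": t.response_satisfaction,
                }
            )
    return pd.DataFrame(choice_rows), pd.DataFrame(rating_rows)


def binned_target_rates(
    choice_table: pd.DataFrame,
    edges: Sequence[float] = (3.0, 3.5, 4.0),
) -> pd.DataFrame:
    """Target-choice rate across set-mean bins (<=3, 3-3.5, 3.5-4, >4 by default)."""
    bins = [-np.inf, *edges, np.inf]
    labels = (
        [f"<= {edges[0]}"]
        + [f"{a}-{b}" for a, b in zip(edges[:-1], edges[1:])]
        + [f"> {edges[-1]}"]
    )
    cut = pd.cut(choice_table["mean_set"], bins=bins, labels=labels)
    g = choice_table.groupby(cut, observed=False)["is_target"]
    out = pd.DataFrame({"n": g.size(), "target_rate": g.mean()})
    out.index.name = "mean_set_bin"
    return out.reset_index()
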