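"""Synthetic world generator with controllable context dependence.

The generator builds Yelp-like cities: spatial clusters of restaurants, each
restaurant carrying a latent quality on the 1-5 star scale, category terms,
and a price tier.  Users then produce review / check-in / order streams from
a *divisive-normalization* choice model,

    v_i = r_i / (sigma + omega * sum_j r_j),

where ``r_i`` is option *i*'s displayed rating and the sum runs over the
displayed ratings of the whole choice set.  With ``omega = 0`` the model
collapses to a plain logit over ratings and satisfies independence of
irrelevant alternatives (IIA); with ``omega > 0`` high-valued contexts
compress value differences and produce IIA violations.  Choices are drawn
from a softmax with temperature ``tau``.

Post-choice star ratings follow a prediction-error rule: the emitted rating
is the experienced utility (a symmetric random draw centred on the option's
running mean) minus a contextually scaled expectation,

    rating = Normal(prior_mean, sigma_u) + kappa * (context_mean - 3),

so richer contexts lower the expectation and inflate the rating deviation in
proportion to ``kappa``.  The midpoint 3 anchors the neutral context on the
1-5 scale, making ``kappa`` directly the deviation slope.

Every ``simulate_*`` operation is a pure function of (world, config, seed).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .rating_state import round_half_star

logger = logging.getLogger(__name__)

UMBRELLA_TERM = "Restaurants"

__all__ = [
    "WorldConfig",
    "ExperimentHeterogeneity",
    "Restaurant",
    "ReviewEvent",
    "CheckInEvent",
    "OrderEvent",
    "ExperimentTrial",
    "World",
    "generate_world",
    "normalized_value",
    "normalized_values",
    "choice_probabilities",
    "simulate_rating",
    "simulate_choice_stream",
    "simulate_checkins",
    "simulate_orders",
    "simulate_experiment",
]


# --------------------------------------------------------------------------
# configuration and record types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WorldConfig:
    """Generative parameters of the synthetic world.

    Geometry: each city holds ``clusters_per_city`` Gaussian neighborhoods
    (centres spread by ``cluster_center_spread`` decimal degrees, members by
    ``within_cluster_sd``).  Each neighborhood holds
    ``restaurants_per_cluster`` restaurants *per category* (or a per-set
    count drawn uniformly from ``restaurants_per_cluster_range``, mirroring
    real 3-7 option sets).

    Value mechanism: ``sigma_norm`` (> 0) is the semi-saturation constant of
    divisive normalization, ``omega`` (>= 0) the context weight, ``tau``
    (> 0) the softmax temperature, ``kappa`` the expectation-context slope
    (stars of rating shift per star of context mean), ``sigma_u`` the
    experience-noise SD.  ``cluster_quality_sd`` shifts whole neighborhoods
    up or down in quality so set means span the 1-5 scale the way real
    neighborhoods do.

    ``discretize`` clamps-and-rounds emitted ratings to whole stars (the
    platform scale); continuous mode keeps the clamped real value.
    ``display_rounded`` controls whether deciders see half-star-rounded or
    exact running means.
    """

    n_cities: int = 1
    clusters_per_city: int = 300
    cluster_center_spread: float = 0.6
    within_cluster_sd: float = 0.004
    categories: tuple = ("Pizza", "Italian", "Burgers")
    restaurants_per_cluster: int = 4
    restaurants_per_cluster_range: tuple | None = (3, 7)
    n_users: int = 200
    events_per_user: int = 100
    init_reviews_per_restaurant: int = 20
    init_reviews_range: tuple | None = (5, 60)
    quality_mean: float = 3.6
    quality_sd: float = 0.6
    cluster_quality_sd: float = 0.6
    price_probs: tuple = (0.3, 0.4, 0.2, 0.1)
    sigma_norm: float = 1.0
    omega: float = 0.5
    tau: float = 0.05
    kappa: float = 0.4
    sigma_u: float = 0.5
    discretize: bool = True
    display_rounded: bool = True
    term_salience: float = 3.0
    n_checkins: int | None = None
    n_orders: int | None = None
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cities": self.n_cities,
            "clusters_per_city": self.clusters_per_city,
            "restaurants_per_cluster": self.restaurants_per_cluster,
            "n_users": self.n_users,
            "events_per_user": self.events_per_user,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.init_reviews_per_restaurant < 0:
            raise ValueError("init_reviews_per_restaurant must be >= 0")
        if abs(sum(self.price_probs) - 1.0) > 1e-12:
            raise ValueError("price_probs must sum to 1 within 1e-12")
        if len(self.price_probs) != 4:
            raise ValueError("price_probs must cover price tiers 1-4")
        if self.sigma_norm <= 0:
            raise ValueError("sigma_norm must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not self.categories:
            raise ValueError("at least one category term is required")
        if self.restaurants_per_cluster_range is not None:
            lo, hi = self.restaurants_per_cluster_range
            if not (1 <= lo <= hi):
                raise ValueError("invalid restaurants_per_cluster_range")
        if self.init_reviews_range is not None:
            lo, hi = self.init_reviews_range
            if not (0 <= lo <= hi):
                raise ValueError("invalid init_reviews_range")


@dataclass(frozen=True)
class ExperimentHeterogeneity:
    """Participant-level spread of the context mechanisms in the experiment.

    Each participant p draws (omega_p, c_p) from a bivariate normal with the
    given means, SDs and correlation; omega_p is clipped at 0.  ``c_p`` is
    the participant's expectation-context slope on the 0-100 satisfaction
    scale (the experiment-scale analogue of kappa).

    Experiment choices use their own value sensitivity (``choice_sigma``,
    ``choice_tau``) rather than the field-data parameters: the participant
    population is placed in the *unsaturated* normalization regime
    (omega_p * sum(r) < sigma), where a larger context weight strengthens
    the measured context effect — the comparative statics the contextual
    account describes.  In the saturated regime extra context weight mostly
    flattens choice overall instead.
    """

    omega_mean: float = 0.2
    omega_sd: float = 0.1
    c_mean: float = 5.0
    c_sd: float = 2.5
    correlation: float = 0.8
    choice_sigma: float = 6.0
    choice_tau: float = 0.025
    lapse_rate: float = 0.0
    rating_intercept: float = 10.0
    rating_slope: float = 15.0
    rating_noise_sd: float = 6.0


@dataclass(frozen=True)
class Restaurant:
    id: str
    city: str
    lat: float
    lon: float
    assigned_terms: tuple
    true_primary_term: str
    price: int
    latent_quality: float
    true_cluster: int  # generator ground truth, not visible to the pipeline


@dataclass(frozen=True)
class ReviewEvent:
    review_id: str
    user_id: str
    business_id: str
    timestamp: float
    stars: float
    text: str


@dataclass(frozen=True)
class CheckInEvent:
    business_id: str
    timestamp: float


@dataclass(frozen=True)
class OrderEvent:
    user_id: str
    restaurant_id: str
    city: str
    cuisine: str
    timestamp: float


@dataclass(frozen=True)
class ExperimentTrial:
    participant_id: str
    trial_type: str  # choice | rating | catch
    snapshot: object  # SetSnapshot
    highlighted_id: str | None = None
    response_choice: str | None = None
    response_satisfaction: float | None = None


@dataclass
class World:
    config: WorldConfig
    restaurants: list
    users: list  # user ids
    user_city: dict
    init_reviews: list
    _next_ts: int = 0

    @property
    def restaurants_by_id(self) -> dict:
        return {r.id: r for r in self.restaurants}

    def true_sets(self) -> dict:
        """Ground-truth (city, cluster, category) -> member ids."""
        out: dict[tuple, list] = {}
        for r in self.restaurants:
            out.setdefault((r.city, r.true_cluster, r.true_primary_term), []).append(
                r.id
            )
        return out


# --------------------------------------------------------------------------
# world generation
# --------------------------------------------------------------------------


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi)) if size else np.clip(mean, lo, hi)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _review_text(rng, restaurant: Restaurant, salience: float) -> str:
    """Bag of lowercase category-term tokens; the true term dominates."""
    pool = []
    weights = []
    for term in restaurant.assigned_terms:
        pool.append(term.lower())
        weights.append(salience if term == restaurant.true_primary_term else 1.0)
    w = np.asarray(weights) / sum(weights)
    n = int(rng.integers(3, 12))
    toks = rng.choice(len(pool), size=n, p=w)
    return " ".join(pool[i] for i in toks)


def _emit_whole_star(rng, mean: float, sd: float) -> int:
    """Noisy whole-star rating: round half-away-from-zero then clamp to 1-5."""
    x = rng.normal(mean, sd)
    return int(min(5, max(1, math.floor(x + 0.5))))


def _review_texts_batch(rng, restaurant: Restaurant, salience: float, n: int) -> list:
    """Vectorized batch of synthetic review texts for one restaurant."""
    pool = [t.lower() for t in restaurant.assigned_terms]
    w = np.array(
        [salience if t == restaurant.true_primary_term else 1.0 for t in restaurant.assigned_terms]
    )
    w = w / w.sum()
    lens = rng.integers(3, 12, size=n)
    toks = rng.choice(len(pool), size=int(lens.sum()), p=w)
    out = []
    pos = 0
    for ln in lens:
        out.append(" ".join(pool[i] for i in toks[pos : pos + ln]))
        pos += ln
    return out


def generate_world(config: WorldConfig) -> World:
    """Build restaurants, users and the seed review history.

    Deterministic given ``config.seed``.  Every cluster receives
    ``restaurants_per_cluster`` restaurants for each category (or a count
    drawn from ``restaurants_per_cluster_range`` per (cluster, category)
    set), and every restaurant receives ``init_reviews_per_restaurant``
    whole-star seed reviews whose mean converges on its latent quality.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    restaurants: list[Restaurant] = []
    bid = 0
    for ci in range(config.n_cities):
        city = f"city{ci:02d}"
        # cities live on well-separated patches of the plane
        city_lat, city_lon = 10.0 * ci, 0.0
        centers = rng.normal(
            [city_lat, city_lon], config.cluster_center_spread, size=(config.clusters_per_city, 2)
        )
        for k in range(config.clusters_per_city):
            for cat in config.categories:
                # quality offset per (neighborhood, category) scene: a
                # neighborhood's pizza places and burger joints need not be
                # equally good
                offset = rng.normal(0.0, config.cluster_quality_sd)
                if config.restaurants_per_cluster_range is not None:
                    lo, hi = config.restaurants_per_cluster_range
                    n_rest = int(rng.integers(lo, hi + 1))
                else:
                    n_rest = config.restaurants_per_cluster
                for _ in range(n_rest):
                    lat, lon = rng.normal(centers[k], config.within_cluster_sd)
                    q = float(
                        _truncnorm(rng, config.quality_mean + offset, config.quality_sd, 1.0, 5.0)
                    )
                    terms = [cat]
                    others = [c for c in config.categories if c != cat]
                    if others and rng.random() < 0.5:
                        terms.append(str(rng.choice(others)))
                    rng.shuffle(terms)
                    price = int(rng.choice(4, p=np.asarray(config.price_probs))) + 1
                    restaurants.append(
                        Restaurant(
                            id=f"b{bid:05d}",
                            city=city,
                            lat=float(lat),
                            lon=float(lon),
                            assigned_terms=tuple(terms),
                            true_primary_term=cat,
                            price=price,
                            latent_quality=q,
                            true_cluster=k,
                        )
                    )
                    bid += 1

    users = [f"u{idx:05d}" for idx in range(config.n_users)]
    cities = sorted({r.city for r in restaurants})
    user_city = {u: cities[i % len(cities)] for i, u in enumerate(users)}

    world = World(
        config=config,
        restaurants=restaurants,
        users=users,
        user_city=user_city,
        init_reviews=[],
        _next_ts=0,
    )
    # seed review history: background reviewers, no context mechanism
    ts = 0
    rid = 0
    init: list[ReviewEvent] = []
    for r in restaurants:
        if config.init_reviews_range is not None:
            lo, hi = config.init_reviews_range
            n_init = int(rng.integers(lo, hi + 1))
        else:
            n_init = config.init_reviews_per_restaurant
        if n_init == 0:
            continue
        stars = np.clip(
            np.floor(rng.normal(r.latent_quality, config.sigma_u, n_init) + 0.5), 1, 5
        ).astype(int)
        texts = _review_texts_batch(rng, r, config.term_salience, n_init)
        for s, txt in zip(stars, texts):
            init.append(
                ReviewEvent(
                    review_id=f"seed{rid:07d}",
                    user_id=f"bg{rid % 500:04d}",
                    business_id=r.id,
                    timestamp=float(ts),
                    stars=int(s),
                    text=txt,
                )
            )
            rid += 1
            ts += 1
    world.init_reviews = init
    world._next_ts = ts
    return world


# --------------------------------------------------------------------------
# the choice and rating mechanisms
# --------------------------------------------------------------------------


def normalized_values(
    ratings: Sequence[float], sigma: float, omega: float
) -> np.ndarray:
    """Divisive-normalization values v_i = r_i / (sigma + omega * sum_j r_j)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    r = np.asarray(ratings, dtype=float)
    return r / (sigma + omega * r.sum())


def normalized_value(
    r_i: float, set_ratings: Sequence[float], sigma: float, omega: float
) -> float:
    """Value of one option among ``set_ratings`` (which must contain it)."""
    rs = list(set_ratings)
    if not any(math.isclose(r_i, x) for x in rs):
        raise ValueError("r_i must be a member of set_ratings")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    return float(r_i / (sigma + omega * sum(rs)))


def choice_probabilities(values: Sequence[float], tau: float) -> np.ndarray:
    """Softmax p_i proportional to exp(v_i / tau), overflow-safe."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    z = (v - v.max()) / tau
    e = np.exp(z)
    return e / e.sum()


def simulate_rating(
    prior_mean_chosen: float,
    context_mean_excl_chosen: float,
    config: WorldConfig,
    rng: np.random.Generator,
) -> float:
    """Prediction-error rating rule.

    Experienced utility u ~ Normal(prior_mean, sigma_u^2); expectation
    E = prior_mean - kappa * (context_mean - 3); the emitted rating is
    u - (E - prior_mean) = u + kappa * (context_mean - 3), clamped to [1, 5]
    and rounded to whole stars when ``config.discretize``.
    """
    for name, v in (
        ("prior_mean_chosen", prior_mean_chosen),
        ("context_mean_excl_chosen", context_mean_excl_chosen),
    ):
        if not (1.0 <= v <= 5.0):
            raise ValueError(f"{name} must lie in [1, 5], got {v}")
    u = rng.normal(prior_mean_chosen, config.sigma_u) if config.sigma_u > 0 else prior_mean_chosen
    x = u + config.kappa * (context_mean_excl_chosen - 3.0)
    if config.discretize:
        return float(min(5, max(1, math.floor(x + 0.5))))
    return float(min(5.0, max(1.0, x)))


# --------------------------------------------------------------------------
# event streams
# --------------------------------------------------------------------------


class _RunningRatings:
    """O(1) running mean per business, fed in time order."""

    def __init__(self, reviews):
        self.sum: dict[str, float] = {}
        self.n: dict[str, int] = {}
        for r in reviews:
            self.add(r.business_id, r.stars)

    def add(self, bid: str, stars: float) -> None:
        self.sum[bid] = self.sum.get(bid, 0.0) + stars
        self.n[bid] = self.n.get(bid, 0) + 1

    def mean(self, bid: str) -> tuple[float, int]:
        n = self.n.get(bid, 0)
        return (self.sum[bid] / n if n else math.nan, n)


def _displayed(mean: float, rounded: bool) -> float:
    return round_half_star(mean) if rounded else mean


def _prepare_sets(world: World):
    """Ground-truth sets grouped by city, only sets with >= 2 members."""
    by_city: dict[str, list] = {}
    for key, members in world.true_sets().items():
        by_city.setdefault(key[0], []).append((key, sorted(members)))
    for city in by_city:
        by_city[city].sort(key=lambda x: x[0][1:])
    return by_city


def simulate_choice_stream(
    world: World, config: WorldConfig | None = None, seed: int | None = None
):
    """Simulate the review-generating choice stream.

    Returns ``(records, reviews)`` where ``records`` are ground-truth choice
    precursors (set key, displayed state, chosen option, probabilities used)
    and ``reviews`` are the emitted :class:`ReviewEvent` rows.  The displayed
    state used for each choice excludes the review being emitted.
    """
    config = config or world.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    running = _RunningRatings(world.init_reviews)
    sets_by_city = _prepare_sets(world)
    biz = world.restaurants_by_id
    records = []
    reviews = []
    ts = world._next_ts
    rid = 0
    n_skipped = 0
    total = config.n_users * config.events_per_user
    for e in range(total):
        user = world.users[e % config.n_users]
        city_sets = sets_by_city.get(world.user_city[user], [])
        if not city_sets:
            n_skipped += 1
            continue
        key, members = city_sets[int(rng.integers(len(city_sets)))]
        shown = [
            (bid,) + running.mean(bid)
            for bid in members
            if running.n.get(bid, 0) > 0
        ]
        if len(shown) < 2:
            n_skipped += 1
            logger.debug("event %d skipped: set %s has <2 rated options", e, key)
            continue
        disp = np.array([_displayed(m, config.display_rounded) for _, m, _ in shown])
        values = normalized_values(disp, config.sigma_norm, config.omega)
        probs = choice_probabilities(values, config.tau)
        j = int(rng.choice(len(shown), p=probs))
        chosen_id, prior_raw, _n = shown[j]
        others = np.delete(disp, j)
        ctx_mean = float(others.mean())
        stars = simulate_rating(
            min(5.0, max(1.0, prior_raw)), min(5.0, max(1.0, ctx_mean)), config, rng
        )
        review = ReviewEvent(
            review_id=f"r{rid:07d}",
            user_id=user,
            business_id=chosen_id,
            timestamp=float(ts),
            stars=stars,
            text=_review_text(rng, biz[chosen_id], config.term_salience),
        )
        records.append(
            {
                "set_key": key,
                "timestamp": float(ts),
                "user_id": user,
                "option_ids": [bid for bid, _, _ in shown],
                "displayed": disp,
                "prior_raw_chosen": prior_raw,
                "context_mean_excl_chosen": ctx_mean,
                "chosen_id": chosen_id,
                "is_target": bool(disp[j] == disp.max()),
            }
        )
        reviews.append(review)
        running.add(chosen_id, stars)
        ts += 1
        rid += 1
    if n_skipped:
        logger.info("simulate_choice_stream: skipped %d undersized events", n_skipped)
    return records, reviews


def simulate_checkins(
    world: World, config: WorldConfig | None = None, seed: int | None = None
):
    """Check-in stream: same choice mechanism, static ratings, no user ids."""
    config = config or world.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    running = _RunningRatings(world.init_reviews)
    sets_by_city = _prepare_sets(world)
    all_sets = [kv for city in sorted(sets_by_city) for kv in sets_by_city[city]]
    n_events = config.n_checkins or config.n_users * config.events_per_user
    events = []
    ts = 10_000_000  # disjoint from review timestamps
    for _ in range(n_events):
        key, members = all_sets[int(rng.integers(len(all_sets)))]
        shown = [(bid,) + running.mean(bid) for bid in members if running.n.get(bid, 0) > 0]
        if len(shown) < 2:
            continue
        disp = np.array([_displayed(m, config.display_rounded) for _, m, _ in shown])
        probs = choice_probabilities(
            normalized_values(disp, config.sigma_norm, config.omega), config.tau
        )
        j = int(rng.choice(len(shown), p=probs))
        events.append(CheckInEvent(business_id=shown[j][0], timestamp=float(ts)))
        ts += 1
    return events


def simulate_orders(
    world: World, config: WorldConfig | None = None, seed: int | None = None
):
    """Delivery-order stream over city-wide (city, cuisine) sets.

    Displayed ratings are static (the seed-review means), as delivery
    platforms show a fixed rating over a short observation window.  Returns
    ``(orders, options)`` where ``options`` is the static per-restaurant
    display table (restaurant_id, city, cuisine, stars, n_ratings, price).
    """
    config = config or world.config
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    running = _RunningRatings(world.init_reviews)
    by_key: dict[tuple, list] = {}
    for r in world.restaurants:
        by_key.setdefault((r.city, r.true_primary_term), []).append(r.id)
    options = []
    static: dict[tuple, list] = {}
    for key in sorted(by_key):
        rows = []
        for bid in sorted(by_key[key]):
            mean, n = running.mean(bid)
            if n == 0:
                continue
            stars = _displayed(mean, config.display_rounded)
            price = world.restaurants_by_id[bid].price
            options.append(
                {
                    "restaurant_id": bid,
                    "city": key[0],
                    "cuisine": key[1],
                    "stars": stars,
                    "n_ratings": n,
                    "price": price,
                }
            )
            rows.append((bid, stars))
        if len(rows) >= 2:
            static[key] = rows
    keys = sorted(static)
    n_events = config.n_orders or config.n_users * config.events_per_user
    orders = []
    ts = 20_000_000
    for i in range(n_events):
        key = keys[int(rng.integers(len(keys)))]
        rows = static[key]
        disp = np.array([s for _, s in rows])
        probs = choice_probabilities(
            normalized_values(disp, config.sigma_norm, config.omega), config.tau
        )
        j = int(rng.choice(len(rows), p=probs))
        orders.append(
            OrderEvent(
                user_id=f"du{i % config.n_users:05d}",
                restaurant_id=rows[j][0],
                city=key[0],
                cuisine=key[1],
                timestamp=float(ts),
            )
        )
        ts += 1
    return orders, options


# --------------------------------------------------------------------------
# laboratory experiment
# --------------------------------------------------------------------------

N_CHOICE_TRIALS = 135
N_RATING_TRIALS = 135
N_CATCH_TRIALS = 5
N_TRIALS = N_CHOICE_TRIALS + N_RATING_TRIALS + N_CATCH_TRIALS


def simulate_experiment(
    choice_set_pool: Sequence,
    n_participants: int,
    config: WorldConfig,
    heterogeneity: ExperimentHeterogeneity | None = None,
    seed: int | None = None,
):
    """Simulate a 275-trial choice/rating experiment.

    Each participant sees 135 choice trials, 135 rating trials and 5 catch
    trials drawn from ``choice_set_pool`` (snapshots re-used with a warning
    when the pool is smaller than 275).  Choice trials follow the
    divisive-normalization model with participant-specific omega_p; rating
    trials answer 0-100 expected satisfaction

        a + b * r_highlighted - c_p * mean(others) + noise,

    with (omega_p, c_p) drawn with the configured correlation.  Catch trials
    (pick the top-rated option) are answered correctly except with
    probability ``lapse_rate``.

    Returns ``(trials, truth)`` where ``truth`` maps participant id to the
    drawn (omega_p, c_p).
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    het = heterogeneity or ExperimentHeterogeneity()
    pool = list(choice_set_pool)
    if not pool:
        raise ValueError("empty choice set pool")
    if len(pool) < N_TRIALS:
        warnings.warn(
            f"snapshot pool has {len(pool)} < {N_TRIALS} sets; re-using sets",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    cov = np.array(
        [
            [het.omega_sd**2, het.correlation * het.omega_sd * het.c_sd],
            [het.correlation * het.omega_sd * het.c_sd, het.c_sd**2],
        ]
    )
    draws = rng.multivariate_normal([het.omega_mean, het.c_mean], cov, size=n_participants)
    trials: list[ExperimentTrial] = []
    truth: dict[str, tuple] = {}
    for p in range(n_participants):
        pid = f"p{p:04d}"
        omega_p = max(0.0, float(draws[p, 0]))
        c_p = float(draws[p, 1])
        truth[pid] = (omega_p, c_p)
        if len(pool) >= N_TRIALS:
            idx = rng.choice(len(pool), size=N_TRIALS, replace=False)
        else:
            idx = rng.choice(len(pool), size=N_TRIALS, replace=True)
        types = np.array(
            ["choice"] * N_CHOICE_TRIALS + ["rating"] * N_RATING_TRIALS + ["catch"] * N_CATCH_TRIALS
        )
        rng.shuffle(types)
        for snap_i, ttype in zip(idx, types):
            snap = pool[int(snap_i)]
            disp = snap.displayed
            ids = [o.business_id for o in snap.options]
            if ttype == "choice":
                probs = choice_probabilities(
                    normalized_values(disp, het.choice_sigma, omega_p), het.choice_tau
                )
                j = int(rng.choice(len(ids), p=probs))
                trials.append(
                    ExperimentTrial(pid, "choice", snap, response_choice=ids[j])
                )
            elif ttype == "rating":
                j = int(rng.integers(len(ids)))
                others = np.delete(disp, j)
                sat = (
                    het.rating_intercept
                    + het.rating_slope * disp[j]
                    - c_p * float(others.mean())
                    + rng.normal(0.0, het.rating_noise_sd)
                )
                trials.append(
                    ExperimentTrial(
                        pid,
                        "rating",
                        snap,
                        highlighted_id=ids[j],
                        response_satisfaction=float(min(100.0, max(0.0, sat))),
                    )
                )
            else:  # catch: pick the highest-rated option, unless lapsing
                top = int(np.argmax(disp))
                if het.lapse_rate > 0 and rng.random() < het.lapse_rate and len(ids) > 1:
                    wrong = [k for k in range(len(ids)) if disp[k] < disp.max()]
                    j = int(rng.choice(wrong)) if wrong else top
                else:
                    j = top
                trials.append(
                    ExperimentTrial(pid, "catch", snap, response_choice=ids[j])
                )
    return trials, truth
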