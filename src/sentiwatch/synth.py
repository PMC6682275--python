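"""Synthetic tweet-stream generator with known spatiotemporal sentiment structure.

Every downstream stage of the pipeline is tested against streams produced
here, because the ground truth -- which tweet was meant to be positive or
negative, and what each city-hour's true sentiment proportion is -- is
recorded at generation time.

The data-generating model is additive on the proportion scale.  For a tweet
posted in city *c* during local hour *h* on day-of-week *d* under weather
*w*, the probability that it carries positive sentiment is::

    p = clamp( base + city[c] + hour[h] + dow[d] + weather[w]
               + social_slope * 1{tweet is social} + event_delta, 0, 1 )

and symmetrically for negative sentiment with its own parameter set.  The
two labels are drawn independently, so a tweet can be positive, negative,
both, or neither.  Cell-level tweet counts are Poisson.  Localized events
are injected as additive shifts over a contiguous window of hours in one
city and recorded in the ground truth.

Two generation paths share this model:

``generate_tweets``
    the full record-level stream (text, profile location, follower counts,
    interaction markers) for exercising the end-to-end pipeline;
``generate_cells``
    direct city-hour cell sampling (Poisson volumes, binomial sentiment
    counts) for model-level studies where tweet text is irrelevant and
    hundreds of replicate datasets are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sentiment import NEGATIVE, POSITIVE, Lexicon, LexiconEntry

#: The seven-category weather schema used throughout the pipeline.
WEATHER_CATEGORIES = ("clear", "clouds", "fog", "haze", "rain", "snow", "storm")

_SYLLABLES = ("ba", "den", "kor", "mel", "sa", "tor", "vin", "lu", "gar", "pex")
_COUNTRY_POOL = ("Northland", "Southland", "Eastmark", "Westerra", "Midgard")


@dataclass(frozen=True)
class InjectedEvent:
    """A localized sentiment shift with known ground truth.

    ``start`` is a naive local datetime in the event city; the shift applies
    to ``duration_h`` contiguous local hours.  ``delta_pos``/``delta_neg``
    are signed additive shifts on the proportion scale.
    """

    city: str
    start: datetime
    duration_h: int
    delta_pos: float = 0.0
    delta_neg: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_h < 1:
            raise ValueError("event duration must be at least 1 hour")

    def active(self, city: str, local_time: datetime) -> bool:
        if city != self.city:
            return False
        return self.start <= local_time < self.start + timedelta(hours=self.duration_h)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic stream.

    Effect mappings left as ``None`` are filled deterministically from
    ``seed`` with magnitudes typical of population-level sentiment data:
    city offsets of a few percentage points, mild circadian and weekly
    cycles, small weather effects, and a positive association between the
    social share of a cell and its positive-sentiment proportion.
    """

    n_cities: int = 10
    city_names: Sequence[str] | None = None
    countries: Mapping[str, str] | None = None
    tz_offsets: Mapping[str, int] | None = None
    period_start: date = date(2017, 7, 13)
    period_end: date = date(2017, 7, 26)  # inclusive
    base_volume: float = 50.0
    base_prop_pos: float = 0.40
    base_prop_neg: float = 0.28
    city_effects_pos: Mapping[str, float] | None = None
    city_effects_neg: Mapping[str, float] | None = None
    hour_effects_pos: Sequence[float] | None = None
    hour_effects_neg: Sequence[float] | None = None
    dow_effects_pos: Sequence[float] | None = None
    dow_effects_neg: Sequence[float] | None = None
    weather_effects_pos: Mapping[str, float] | None = None
    weather_effects_neg: Mapping[str, float] | None = None
    social_effect_pos: float = 0.10
    social_effect_neg: float = -0.02
    social_base_rate: float = 0.25
    celebrity_rate: float = 0.01
    celebrity_threshold: int = 300_000
    junk_location_rate: float = 0.10
    other_lang_rate: float = 0.05
    weather_persistence: float = 0.8
    events: Sequence[InjectedEvent] = field(default_factory=tuple)
    seed: int = 0

    @property
    def n_days(self) -> int:
        return (self.period_end - self.period_start).days + 1

    @property
    def n_hours(self) -> int:
        return self.n_days * 24

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _city_names(config: GeneratorConfig) -> list[str]:
    if config.city_names is not None:
        names = list(config.city_names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate city names in configuration")
        if len(names) != config.n_cities:
            raise ValueError("city_names length does not match n_cities")
        return names
    names = []
    for i in range(config.n_cities):
        a, b = divmod(i, len(_SYLLABLES))
        stem = _SYLLABLES[a % len(_SYLLABLES)].title() + _SYLLABLES[b]
        names.append(f"{stem}ton{i:03d}")
    return names


def _resolved_effects(config: GeneratorConfig, cities: Sequence[str]):
    """Concretize all effect structures, drawing unspecified ones from the seed."""
    rng = np.random.default_rng([config.seed, 101])
    hours = np.arange(24)
    city_pos = (
        dict(config.city_effects_pos)
        if config.city_effects_pos is not None
        else {c: round(v, 4) for c, v in zip(cities, rng.uniform(-0.06, 0.06, len(cities)))}
    )
    city_neg = (
        dict(config.city_effects_neg)
        if config.city_effects_neg is not None
        else {c: round(v, 4) for c, v in zip(cities, rng.uniform(-0.05, 0.05, len(cities)))}
    )
    # Default circadian cycles: positive sentiment peaks in the evening,
    # negative sentiment around midnight.
    hour_pos = (
        np.asarray(config.hour_effects_pos, dtype=float)
        if config.hour_effects_pos is not None
        else np.round(0.04 * np.cos(2 * np.pi * (hours - 21) / 24), 4)
    )
    hour_neg = (
        np.asarray(config.hour_effects_neg, dtype=float)
        if config.hour_effects_neg is not None
        else np.round(0.03 * np.cos(2 * np.pi * (hours - 0) / 24), 4)
    )
    dow_pos = (
        np.asarray(config.dow_effects_pos, dtype=float)
        if config.dow_effects_pos is not None
        else np.array([-0.005, -0.005, 0.0, 0.0, 0.01, 0.008, 0.0])  # Friday high
    )
    dow_neg = (
        np.asarray(config.dow_effects_neg, dtype=float)
        if config.dow_effects_neg is not None
        else np.array([0.006, 0.003, 0.0, 0.0, -0.008, -0.004, 0.0])
    )
    if len(hour_pos) != 24 or len(hour_neg) != 24:
        raise ValueError("hour effect vectors must have length 24")
    if len(dow_pos) != 7 or len(dow_neg) != 7:
        raise ValueError("day-of-week effect vectors must have length 7")
    wx_pos = (
        dict(config.weather_effects_pos)
        if config.weather_effects_pos is not None
        else {"clear": 0.0, "clouds": -0.005, "fog": -0.01, "haze": -0.008,
              "rain": -0.015, "snow": 0.005, "storm": -0.02}
    )
    wx_neg = (
        dict(config.weather_effects_neg)
        if config.weather_effects_neg is not None
        else {"clear": 0.0, "clouds": 0.004, "fog": 0.008, "haze": 0.006,
              "rain": 0.012, "snow": -0.002, "storm": 0.018}
    )
    for table in (wx_pos, wx_neg):
        missing = set(WEATHER_CATEGORIES) - set(table)
        if missing:
            raise ValueError(f"weather effects missing categories: {sorted(missing)}")
    return city_pos, city_neg, hour_pos, hour_neg, dow_pos, dow_neg, wx_pos, wx_neg


def generate_gazetteer(config: GeneratorConfig) -> pd.DataFrame:
    """Build the city table: canonical name, aliases, country, tz offset, population.

    Aliases are pipe-separated lowercase strings, unique across cities.
    """
    if config.n_cities < 1:
        raise ValueError("n_cities must be at least 1")
    cities = _city_names(config)
    rng = np.random.default_rng([config.seed, 11])
    countries = (
        dict(config.countries)
        if config.countries is not None
        else {c: _COUNTRY_POOL[i % len(_COUNTRY_POOL)] for i, c in enumerate(cities)}
    )
    offsets = (
        dict(config.tz_offsets)
        if config.tz_offsets is not None
        else {c: int(o) for c, o in zip(cities, rng.integers(-8, 10, len(cities)))}
    )
    rows = []
    for c in cities:
        aliases = [c.lower(), f"{c.lower()} city", f"{c[:4].lower()}{len(c)}"]
        rows.append(
            {
                "city": c,
                "aliases": "|".join(aliases),
                "country": countries[c],
                "tz_offset": offsets[c],
                "population": int(rng.integers(2, 150) * 100_000),
            }
        )
    frame = pd.DataFrame(rows)
    all_aliases = [a for row in frame["aliases"] for a in row.split("|")]
    if len(set(all_aliases)) != len(all_aliases):
        raise ValueError("generated aliases collide across cities")
    return frame


def generate_weather(config: GeneratorConfig, gazetteer: pd.DataFrame | None = None) -> pd.DataFrame:
    """One weather category per (city, UTC hour) via a sticky Markov draw.

    With probability ``weather_persistence`` the previous hour's category is
    kept; otherwise a fresh category is drawn uniformly from the seven-value
    schema.  Persistence 1.0 therefore freezes each city's weather and
    persistence 0.0 gives i.i.d. uniform categories.
    """
    if config.n_hours <= 0:
        raise ValueError("period must contain at least one day")
    cities = list(gazetteer["city"]) if gazetteer is not None else _city_names(config)
    rng = np.random.default_rng([config.seed, 23])
    start = datetime.combine(config.period_start, datetime.min.time())
    hours = [start + timedelta(hours=h) for h in range(config.n_hours)]
    cats = np.asarray(WEATHER_CATEGORIES)
    rows = []
    for city in cities:
        state = rng.integers(len(cats))
        fresh = rng.integers(len(cats), size=len(hours))
        keep = rng.random(len(hours)) < config.weather_persistence
        for t, k, f in zip(hours, keep, fresh):
            if not k:
                state = f
            rows.append({"city": city, "utc_time": t.isoformat(), "category": cats[state]})
    return pd.DataFrame(rows)


def generate_lexicon(n_pos: int = 20, n_neg: int = 20, seed: int = 0) -> pd.DataFrame:
    """A toy sentiment lexicon of synthetic tokens.

    Positive and negative term sets are disjoint by construction and share no
    tokens with the filler vocabulary used for tweet text, so scoring a
    generated tweet recovers its intended labels exactly.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("lexicon needs at least one term of each polarity")
    rng = np.random.default_rng([seed, 37])
    rows = [
        {"term": f"posterm{i:03d}", "polarity": POSITIVE, "strength": int(rng.integers(2, 6))}
        for i in range(n_pos)
    ] + [
        {"term": f"negterm{i:03d}", "polarity": NEGATIVE, "strength": int(rng.integers(2, 6))}
        for i in range(n_neg)
    ]
    return pd.DataFrame(rows)


def _clamp(x):
    return np.clip(x, 0.0, 1.0)


def _cell_base_probs(config, effects, city, local_time, weather_cat):
    """Linear predictor for one cell, before the social term."""
    city_pos, city_neg, hour_pos, hour_neg, dow_pos, dow_neg, wx_pos, wx_neg = effects
    h, d = local_time.hour, local_time.weekday()
    ev_pos = ev_neg = 0.0
    for ev in config.events:
        if ev.active(city, local_time):
            ev_pos += ev.delta_pos
            ev_neg += ev.delta_neg
    p = config.base_prop_pos + city_pos[city] + hour_pos[h] + dow_pos[d] + wx_pos[weather_cat] + ev_pos
    q = config.base_prop_neg + city_neg[city] + hour_neg[h] + dow_neg[d] + wx_neg[weather_cat] + ev_neg
    return p, q, ev_pos, ev_neg


def generate_cells(config: GeneratorConfig, noiseless: bool = False) -> pd.DataFrame:
    """Sample the city-hour cell table directly from the generating model.

    Weather is drawn i.i.d. per cell from the seven categories.  With
    ``noiseless=True`` the tweet count is fixed at ``base_volume`` and the
    observed proportions equal the true ones exactly (no Poisson or binomial
    sampling), which makes regression parameter recovery exactly identified.

    Returns a frame with the observed cell columns used by the modelling
    stage plus ground-truth columns ``p_pos_true``, ``p_neg_true`` and
    ``event_active``.
    """
    gaz = generate_gazetteer(config)
    effects = _resolved_effects(config, list(gaz["city"]))
    rng = np.random.default_rng([config.seed, 53])
    start = datetime.combine(config.period_start, datetime.min.time())
    rows = []
    for city, country, off in zip(gaz["city"], gaz["country"], gaz["tz_offset"]):
        for h in range(config.n_hours):
            local_time = start + timedelta(hours=h + int(off))
            wx = WEATHER_CATEGORIES[rng.integers(len(WEATHER_CATEGORIES))]
            if noiseless:
                n = max(int(round(config.base_volume)), 1)
            else:
                n = int(rng.poisson(config.base_volume))
            if n == 0:
                continue
            n_social = int(rng.binomial(n, config.social_base_rate))
            p_social = n_social / n
            p0, q0, ev_pos, ev_neg = _cell_base_probs(config, effects, city, local_time, wx)
            ev = ev_pos != 0.0 or ev_neg != 0.0
            p_true = float(_clamp(p0 + config.social_effect_pos * p_social))
            q_true = float(_clamp(q0 + config.social_effect_neg * p_social))
            p_base = float(_clamp(p0 - ev_pos + config.social_effect_pos * p_social))
            q_base = float(_clamp(q0 - ev_neg + config.social_effect_neg * p_social))
            if noiseless:
                n_pos, n_neg = p_true * n, q_true * n
            else:
                n_pos = int(rng.binomial(n, p_true))
                n_neg = int(rng.binomial(n, q_true))
            rows.append(
                {
                    "city": city,
                    "country": country,
                    "local_date": local_time.date().isoformat(),
                    "local_hour": local_time.hour,
                    "dow": local_time.weekday(),
                    "n": n,
                    "n_pos": n_pos,
                    "n_neg": n_neg,
                    "n_social": n_social,
                    "p_pos": n_pos / n,
                    "p_neg": n_neg / n,
                    "p_social": p_social,
                    "weather": wx,
                    "p_pos_true": p_true,
                    "p_neg_true": q_true,
                    "p_pos_base": p_base,
                    "p_neg_base": q_base,
                    "event_active": ev,
                }
            )
    return pd.DataFrame(rows)


def generate_tweets(
    config: GeneratorConfig,
    gazetteer: pd.DataFrame,
    weather: pd.DataFrame,
    lexicon: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Generate the record-level tweet stream plus ground truth.

    Returns ``(tweets, truth)`` where ``truth`` holds two frames:
    ``"tweets"`` with each record's intended labels and ``"cells"`` with each
    city-hour's true proportions under the generating model.

    Per city-UTC-hour the tweet count is Poisson(``base_volume``).  Each
    tweet gets interaction markers, a follower count (celebrities receive at
    least ``celebrity_threshold``), a profile location that is an alias of
    its city (or a junk string for the unresolvable fraction), a language
    tag, a UTC timestamp inside the hour, and text assembled from filler
    tokens plus lexicon terms matching its intended sentiment labels.
    """
    if gazetteer.empty:
        raise ValueError("gazetteer is empty")
    if config.n_hours <= 0:
        raise ValueError("period contains no hours")
    wx_lookup = {
        (r.city, r.utc_time): r.category for r in weather.itertuples(index=False)
    }
    lex = Lexicon.from_frame(lexicon)
    pos_terms = sorted(lex.positive_terms)
    neg_terms = sorted(lex.negative_terms)
    effects = _resolved_effects(config, list(gazetteer["city"]))
    rng = np.random.default_rng([config.seed, 71])
    start = datetime.combine(config.period_start, datetime.min.time())
    other_langs = ("es", "fr", "pt", "ja")

    tweet_rows: list[dict] = []
    truth_tweet_rows: list[dict] = []
    truth_cell_rows: list[dict] = []
    seq = 0
    for city, alias_str, country, off in zip(
        gazetteer["city"], gazetteer["aliases"], gazetteer["country"], gazetteer["tz_offset"]
    ):
        aliases = alias_str.split("|")
        for h in range(config.n_hours):
            utc_hour = start + timedelta(hours=h)
            local_time = utc_hour + timedelta(hours=int(off))
            wx = wx_lookup.get((city, utc_hour.isoformat()), "clear")
            n = int(rng.poisson(config.base_volume))
            if n == 0:
                continue
            p0, q0, ev_pos, ev_neg = _cell_base_probs(config, effects, city, local_time, wx)
            ev = ev_pos != 0.0 or ev_neg != 0.0
            social = rng.random(n) < config.social_base_rate
            p_t = _clamp(p0 + config.social_effect_pos * social)
            q_t = _clamp(q0 + config.social_effect_neg * social)
            is_pos = rng.random(n) < p_t
            is_neg = rng.random(n) < q_t
            celeb = rng.random(n) < config.celebrity_rate
            junk = rng.random(n) < config.junk_location_rate
            foreign = rng.random(n) < config.other_lang_rate
            offsets_s = rng.integers(0, 3600, n)
            for i in range(n):
                seq += 1
                tid = f"t{seq:09d}"
                # interaction markers: social = reply or direct mention;
                # broadcast = plain tweet, retweet or quote (a retweet may
                # still carry a mention of the original author)
                is_reply = is_quote = is_retweet = False
                mentions = 0
                if social[i]:
                    if rng.random() < 0.5:
                        is_reply = True
                    else:
                        mentions = int(rng.integers(1, 4))
                else:
                    u = rng.random()
                    if u < 0.2:
                        is_retweet = True
                        mentions = int(rng.integers(0, 2))
                    elif u < 0.3:
                        is_quote = True
                followers = (
                    int(config.celebrity_threshold + rng.integers(0, 5_000_000))
                    if celeb[i]
                    else int(min(rng.lognormal(5.0, 1.8), config.celebrity_threshold - 1))
                )
                loc = (
                    f"zz-junk-{rng.integers(1_000_000)}"
                    if junk[i]
                    else str(rng.choice(aliases))
                )
                toks = [f"filler{rng.integers(500):03d}" for _ in range(int(rng.integers(4, 9)))]
                if is_pos[i]:
                    toks.insert(int(rng.integers(len(toks) + 1)), str(rng.choice(pos_terms)))
                if is_neg[i]:
                    toks.insert(int(rng.integers(len(toks) + 1)), str(rng.choice(neg_terms)))
                tweet_rows.append(
                    {
                        "id": tid,
                        "text": " ".join(toks),
                        "utc_time": (utc_hour + timedelta(seconds=int(offsets_s[i]))).isoformat(),
                        "lang": str(rng.choice(other_langs)) if foreign[i] else "en",
                        "profile_location": loc,
                        "followers": followers,
                        "is_retweet": is_retweet,
                        "is_quote": is_quote,
                        "is_reply": is_reply,
                        "mentions": mentions,
                    }
                )
                truth_tweet_rows.append(
                    {
                        "id": tid,
                        "city": city,
                        "intended_pos": bool(is_pos[i]),
                        "intended_neg": bool(is_neg[i]),
                        "intended_social": bool(social[i]),
                        "is_celebrity": bool(celeb[i]),
                        "is_junk_location": bool(junk[i]),
                        "is_english": not bool(foreign[i]),
                    }
                )
            p_social = float(social.mean())
            truth_cell_rows.append(
                {
                    "city": city,
                    "country": country,
                    "local_date": local_time.date().isoformat(),
                    "local_hour": local_time.hour,
                    "dow": local_time.weekday(),
                    "weather": wx,
                    "n": n,
                    "p_social": p_social,
                    "p_pos_true": float(_clamp(p0 + config.social_effect_pos * p_social)),
                    "p_neg_true": float(_clamp(q0 + config.social_effect_neg * p_social)),
                    "event_active": ev,
                }
            )
    tweets = pd.DataFrame(tweet_rows)
    truth = {
        "tweets": pd.DataFrame(truth_tweet_rows),
        "cells": pd.DataFrame(truth_cell_rows),
    }
    return tweets, truth


def default_lexicon() -> pd.DataFrame:
    """The packaged toy lexicon used by examples and fixtures."""
    return generate_lexicon(n_pos=25, n_neg=25, seed=2017)
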