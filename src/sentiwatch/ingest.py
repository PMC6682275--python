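"""Filtering and annotation of raw tweet records.

The fixed pipeline order is: language filter -> celebrity filter -> city
resolution -> local-time conversion.  Each stage only removes or annotates
records, never duplicates them, and logs its retention count.

City resolution replaces a geocoding web service with a deterministic local
alias table: the user's free-text profile location is normalized and matched
case-insensitively against the gazetteer's aliases, first as a whole and
then by its leading comma-separated segment ("Sydney, Australia" matches the
alias "sydney").  Accounts with at least 300,000 followers are removed as
likely brands or bots; the bound is inclusive.
"""

from __future__ import annotations

import logging
from datetime import datetime, timedelta

import pandas as pd

logger = logging.getLogger(__name__)

SOCIAL = "social"
BROADCAST = "broadcast"

#: Follower-count bound above which an account is treated as a celebrity/brand.
CELEBRITY_THRESHOLD = 300_000


def filter_language(tweets: pd.DataFrame, lang_tag: str = "en") -> pd.DataFrame:
    """Keep only records whose platform language tag matches ``lang_tag``."""
    out = tweets[tweets["lang"] == lang_tag].copy()
    logger.info("filter_language: kept %d of %d records", len(out), len(tweets))
    return out


def label_interaction(is_retweet: bool, is_quote: bool, is_reply: bool, mentions: int) -> str:
    """Classify one tweet as social or broadcast.

    Retweets and quotes are broadcast regardless of any mentions they carry
    (the retweeted text's mentions are not the poster's conversation);
    otherwise replies and tweets that mention other users are social, and
    plain tweets are broadcast.
    """
    if is_retweet or is_quote:
        return BROADCAST
    if is_reply or mentions > 0:
        return SOCIAL
    return BROADCAST


def filter_celebrities(tweets: pd.DataFrame, threshold: int = CELEBRITY_THRESHOLD) -> pd.DataFrame:
    """Drop records from accounts with at least ``threshold`` followers."""
    if threshold < 0:
        raise ValueError("celebrity threshold must be non-negative")
    out = tweets[tweets["followers"] < threshold].copy()
    logger.info("filter_celebrities: kept %d of %d records", len(out), len(tweets))
    return out


class AliasIndex:
    """Case-insensitive alias -> city lookup built from a gazetteer table."""

    def __init__(self, gazetteer: pd.DataFrame):
        self._index: dict[str, str] = {}
        self.gazetteer = gazetteer
        for row in gazetteer.itertuples(index=False):
            for alias in str(row.aliases).split("|"):
                key = _normalize(alias)
                if key in self._index and self._index[key] != row.city:
                    raise ValueError(f"alias {alias!r} maps to multiple cities")
                self._index[key] = row.city
        self.tz_offsets = dict(zip(gazetteer["city"], gazetteer["tz_offset"]))
        self.countries = dict(zip(gazetteer["city"], gazetteer["country"]))

    def lookup(self, key: str) -> str | None:
        return self._index.get(key)


def _normalize(s: str) -> str:
    return " ".join(str(s).lower().split())


def resolve_city(profile_location: str, index: AliasIndex) -> str | None:
    """Match a free-text profile location against the alias table.

    Tries the whole normalized string first, then its leading
    comma-separated segment.  Returns the canonical city name or ``None``.
    """
    if profile_location is None or (isinstance(profile_location, float) and pd.isna(profile_location)):
        return None
    key = _normalize(profile_location)
    if not key:
        return None
    hit = index.lookup(key)
    if hit is not None:
        return hit
    head = _normalize(key.split(",")[0])
    if head and head != key:
        return index.lookup(head)
    return None


def localize(utc_time: datetime, tz_offset: int) -> dict:
    """Convert a UTC timestamp to local fields under a fixed-hour offset.

    Fixed offsets (no DST) keep the conversion bit-stable; a DST-aware
    offset table can be supplied upstream by editing the gazetteer.
    """
    local = utc_time + timedelta(hours=int(tz_offset))
    return {
        "local_time": local,
        "local_date": local.date(),
        "local_hour": local.hour,
        "local_dow": local.weekday(),
    }


def resolve_tweets(tweets: pd.DataFrame, index: AliasIndex) -> pd.DataFrame:
    """Annotate each record with city, country, local time fields and
    interaction label, dropping records whose location cannot be resolved."""
    if tweets.empty:
        cols = list(tweets.columns) + [
            "city", "country", "local_time", "local_date", "local_hour",
            "local_dow", "interaction",
        ]
        return pd.DataFrame(columns=cols)
    cities = tweets["profile_location"].map(lambda s: resolve_city(s, index))
    resolved = tweets[cities.notna()].copy()
    resolved["city"] = cities[cities.notna()]
    logger.info("resolve_tweets: resolved %d of %d records", len(resolved), len(tweets))
    resolved["country"] = resolved["city"].map(index.countries)
    utc = pd.to_datetime(resolved["utc_time"])
    offs = resolved["city"].map(index.tz_offsets).astype(int)
    local = utc + pd.to_timedelta(offs, unit="h")
    resolved["local_time"] = local
    resolved["local_date"] = local.dt.date.astype(str)
    resolved["local_hour"] = local.dt.hour
    resolved["local_dow"] = local.dt.weekday
    resolved["interaction"] = [
        label_interaction(r.is_retweet, r.is_quote, r.is_reply, r.mentions)
        for r in resolved.itertuples(index=False)
    ]
    return resolved


def select_top_cities(resolved: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep only records from the ``k`` cities with the most resolved tweets.

    Ties are broken alphabetically for determinism.
    """
    counts = resolved.groupby("city").size().sort_index()
    top = counts.sort_values(ascending=False, kind="stable").head(k).index
    return resolved[resolved["city"].isin(top)].copy()


def run_ingest(
    tweets: pd.DataFrame,
    gazetteer: pd.DataFrame,
    lang_tag: str = "en",
    celebrity_threshold: int = CELEBRITY_THRESHOLD,
    top_k: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full ingest pipeline; returns the resolved table and per-stage counts."""
    counts = {"input": len(tweets)}
    t = filter_language(tweets, lang_tag)
    counts["after_language"] = len(t)
    t = filter_celebrities(t, celebrity_threshold)
    counts["after_celebrity"] = len(t)
    index = AliasIndex(gazetteer)
    t = resolve_tweets(t, index)
    counts["after_resolution"] = len(t)
    if top_k is not None:
        t = select_top_cities(t, top_k)
        counts["after_top_cities"] = len(t)
    return t, counts
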