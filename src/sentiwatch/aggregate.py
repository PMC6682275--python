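"""City-hour aggregation: the ecological analysis table.

The analysis unit is the city-hour cell: all scored, resolved tweets from
one city in one local-time hour.  Each cell carries the tweet count, the
counts and proportions of positive-flagged, negative-flagged and social
tweets, and the hour's weather category.  Because positive and negative
labels are independent, ``p_pos + p_neg`` may exceed 1.

Zero-tweet city-hours are omitted rather than imputed: a proportion is
undefined at n = 0 and only observed cells are modelled.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

CELL_COLUMNS = [
    "city", "country", "local_date", "local_hour", "dow",
    "n", "n_pos", "n_neg", "n_social",
    "p_pos", "p_neg", "p_social", "weather",
]


def aggregate_cells(
    scored: pd.DataFrame,
    weather: pd.DataFrame,
    tz_offsets: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Aggregate scored, resolved tweets into the city-hour cell table.

    Weather is keyed by (city, UTC hour); the cell's local hour is translated
    back to UTC through ``tz_offsets`` before the join.  Cells with no
    weather row default to "clear" with a logged warning.  Duplicate weather
    rows for one (city, hour) are an input error.
    """
    if scored.empty:
        return pd.DataFrame(columns=CELL_COLUMNS)
    required = {"city", "country", "local_date", "local_hour", "local_dow",
                "is_positive", "is_negative", "interaction"}
    missing = required - set(scored.columns)
    if missing:
        raise KeyError(f"scored tweet table is missing columns: {sorted(missing)}")

    if weather.duplicated(subset=["city", "utc_time"]).any():
        raise ValueError("duplicate weather rows for a (city, utc hour) key")
    wx = {(r.city, r.utc_time): r.category for r in weather.itertuples(index=False)}

    g = scored.groupby(["city", "country", "local_date", "local_hour", "local_dow"], sort=True)
    cells = g.agg(
        n=("is_positive", "size"),
        n_pos=("is_positive", "sum"),
        n_neg=("is_negative", "sum"),
    ).reset_index()
    cells["n_social"] = (
        g["interaction"].agg(lambda s: int((s == "social").sum())).to_numpy()
    )
    cells = cells.rename(columns={"local_dow": "dow"})
    cells["p_pos"] = cells["n_pos"] / cells["n"]
    cells["p_neg"] = cells["n_neg"] / cells["n"]
    cells["p_social"] = cells["n_social"] / cells["n"]

    offsets = tz_offsets or {}
    n_missing_wx = 0
    categories = []
    for r in cells.itertuples(index=False):
        local = pd.Timestamp(f"{r.local_date} {r.local_hour:02d}:00:00")
        utc = local - pd.Timedelta(hours=int(offsets.get(r.city, 0)))
        cat = wx.get((r.city, utc.isoformat()))
        if cat is None:
            n_missing_wx += 1
            cat = "clear"
        categories.append(cat)
    if n_missing_wx:
        logger.warning("aggregate_cells: %d cells had no weather row; defaulted to 'clear'",
                       n_missing_wx)
    cells["weather"] = categories
    return cells[CELL_COLUMNS]


def filter_cells(cells: pd.DataFrame, min_n: int = 1) -> pd.DataFrame:
    """Drop cells with fewer than ``min_n`` tweets.

    Exposed because the chi-square deviation test is fragile at tiny counts.
    """
    if min_n < 1:
        raise ValueError("min_n must be at least 1")
    out = cells[cells["n"] >= min_n].copy()
    logger.info("filter_cells: kept %d of %d cells (min_n=%d)", len(out), len(cells), min_n)
    return out
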