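"""Detection and ranking of localized sentiment deviations.

Given a fitted baseline model and a table of held-out city-hour cells, each
cell's observed count of positive (or negative) flagged tweets is compared
with the count expected under the model using a one-sample chi-square
goodness-of-fit test over the two categories {flagged, not flagged}::

    chi2 = (O - E)^2 / E + ((n - O) - (n - E))^2 / (n - E),   df = 1

The predicted proportion is clamped to [eps, 1 - eps] before computing the
expected count so the statistic stays finite under extreme extrapolation.

Rather than thresholding, cells are ranked by descending chi-square within
each outcome (positive and negative sentiment are never combined into one
scale).  Rarity is expressed as a recurrence interval: the number of
observation days divided by how many deviations across all cities exceeded
that magnitude; the top-ranked deviation, exceeded by none, is reported with
a ">D" sentinel.  Significant same-direction deviations are merged across
contiguous hours, days and same-country cities into events labelled by
their most extreme member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Clamp bound for predicted proportions when forming expected counts.
EPS = 1e-6

EXCESS = "excess"
DEFICIT = "deficit"

_OUTCOME_COUNT = {"positive": "n_pos", "negative": "n_neg"}
_SPEC_OUTCOME = {"p_pos": "positive", "p_neg": "negative"}


def expected_counts(model, cells: pd.DataFrame, eps: float = EPS) -> np.ndarray:
    """Expected flagged-tweet count per cell under the baseline model."""
    p = np.clip(model.predict(cells), eps, 1.0 - eps)
    return p * cells["n"].to_numpy(dtype=float)


def chi2_deviation(observed: float, expected: float, n: float) -> tuple[float, float, str]:
    """One-cell chi-square deviation: returns (chi2, p_value, direction)."""
    if not (0.0 < expected < n):
        raise ValueError(f"expected count must lie strictly inside (0, n), got {expected} of {n}")
    d = observed - expected
    chi2 = d * d / expected + d * d / (n - expected)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, (EXCESS if observed > expected else DEFICIT)


def compute_deviations(model, cells: pd.DataFrame, eps: float = EPS) -> pd.DataFrame:
    """Chi-square deviation of every cell from the model's expectation.

    The tested outcome (positive or negative) follows the model's own
    outcome.  Returns one row per cell with observed and expected counts,
    the statistic, its p-value and the direction of the deviation.
    """
    outcome = _SPEC_OUTCOME[model.spec.outcome]
    p = np.clip(model.predict(cells), eps, 1.0 - eps)
    return deviations_from_expected(cells, p, outcome)


def deviations_from_expected(
    cells: pd.DataFrame, p_expected: np.ndarray, outcome: str
) -> pd.DataFrame:
    """Chi-square deviations of cells from given expected proportions.

    Lower-level entry used both by :func:`compute_deviations` and by
    calibration studies where the expectation is the generating model itself.
    """
    n = cells["n"].to_numpy(dtype=float)
    if (n <= 0).any():
        raise ValueError("all cells must have n > 0")
    O = cells[_OUTCOME_COUNT[outcome]].to_numpy(dtype=float)
    E = np.asarray(p_expected, dtype=float) * n
    if ((E <= 0) | (E >= n)).any():
        raise ValueError("expected counts must lie strictly inside (0, n)")
    d = O - E
    chi2 = d * d / E + d * d / (n - E)
    out = cells[["city", "country", "local_date", "local_hour"]].copy()
    out["outcome"] = outcome
    out["n"] = cells["n"].to_numpy()
    out["observed"] = O
    out["expected"] = E
    out["chi2"] = chi2
    out["p_value"] = stats.chi2.sf(chi2, df=1)
    out["direction"] = np.where(O > E, EXCESS, DEFICIT)
    return out


def rank_deviations(deviations: pd.DataFrame) -> pd.DataFrame:
    """Rank deviations by descending chi-square, separately per outcome.

    Ties break by earlier (local_date, local_hour), then city label, so the
    ranking is invariant to input order.
    """
    dev = deviations.copy()
    dev["_negchi2"] = -dev["chi2"]
    dev = dev.sort_values(
        ["outcome", "_negchi2", "local_date", "local_hour", "city"], kind="stable"
    ).drop(columns="_negchi2")
    dev["rank"] = dev.groupby("outcome").cumcount() + 1
    return dev.reset_index(drop=True)


def recurrence_interval(chi2: float, ranked: pd.DataFrame, observation_days: int) -> float | str:
    """Recurrence interval in days for a deviation of the given magnitude.

    The frequency is the number of ranked deviations with a strictly larger
    statistic; a magnitude exceeded by none returns the sentinel ">D".
    """
    exceeded = int((ranked["chi2"] > chi2).sum())
    if exceeded == 0:
        return f">{observation_days}"
    return observation_days / exceeded


def add_recurrence_intervals(ranked: pd.DataFrame, observation_days: int) -> pd.DataFrame:
    """Annotate a ranked table with each row's recurrence interval (per outcome)."""
    out = ranked.copy()
    values: list[float | str] = []
    for _, grp in out.groupby("outcome", sort=False):
        chi2s = grp["chi2"].to_numpy()
        for c in chi2s:
            values.append(recurrence_interval(c, grp, observation_days))
    out["recurrence_interval"] = values
    return out


@dataclass(frozen=True)
class EventReport:
    """Merged significant deviations labelled by their most extreme member."""

    scope: str  # hour-city, day-city, day-country, multi-day-country
    label: str  # city for single-city events, else country
    country: str
    outcome: str
    direction: str
    date_start: str
    date_end: str
    hour_start: int
    hour_end: int
    n_members: int
    max_chi2: float
    p_value: float
    peak_city: str
    peak_date: str
    peak_hour: int
    observed_pct: float
    expected_pct: float
    recurrence_interval: float | str | None = None


def _contiguous_runs(dates: list[str]) -> list[list[str]]:
    """Partition sorted ISO dates into runs of consecutive calendar days."""
    runs: list[list[str]] = []
    prev = None
    for d in dates:
        ts = pd.Timestamp(d)
        if prev is not None and (ts - prev).days == 1:
            runs[-1].append(d)
        else:
            runs.append([d])
        prev = ts
    return runs


def merge_events(
    ranked: pd.DataFrame,
    alpha: float = 0.05,
    observation_days: int | None = None,
) -> pd.DataFrame:
    """Merge significant deviations into events.

    Within each (outcome, direction): same-city deviations on one local date
    merge into a day-city event; same-country deviations on one date merge
    into a day-country event; runs of consecutive dates merge into
    multi-day-country events.  A significant deviation with no partner
    remains an hour-city event.  Each event is labelled by its maximum
    chi-square member, whose observed and expected percentages are reported.
    """
    sig = ranked[ranked["p_value"] < alpha]
    events: list[EventReport] = []
    for (outcome, direction, country), grp in sig.groupby(
        ["outcome", "direction", "country"], sort=True
    ):
        for run in _contiguous_runs(sorted(grp["local_date"].unique())):
            members = grp[grp["local_date"].isin(run)]
            n_dates = members["local_date"].nunique()
            n_cities = members["city"].nunique()
            if len(members) == 1:
                scope = "hour-city"
            elif n_dates == 1 and n_cities == 1:
                scope = "day-city"
            elif n_dates == 1:
                scope = "day-country"
            else:
                scope = "multi-day-country"
            peak = members.loc[members["chi2"].idxmax()]
            label = peak["city"] if n_cities == 1 else country
            ri = (
                recurrence_interval(
                    float(peak["chi2"]), ranked[ranked["outcome"] == outcome], observation_days
                )
                if observation_days is not None
                else None
            )
            events.append(
                EventReport(
                    scope=scope,
                    label=str(label),
                    country=str(country),
                    outcome=str(outcome),
                    direction=str(direction),
                    date_start=min(run),
                    date_end=max(run),
                    hour_start=int(members["local_hour"].min()),
                    hour_end=int(members["local_hour"].max()),
                    n_members=len(members),
                    max_chi2=float(peak["chi2"]),
                    p_value=float(peak["p_value"]),
                    peak_city=str(peak["city"]),
                    peak_date=str(peak["local_date"]),
                    peak_hour=int(peak["local_hour"]),
                    observed_pct=100.0 * float(peak["observed"]) / float(peak["n"]),
                    expected_pct=100.0 * float(peak["expected"]) / float(peak["n"]),
                    recurrence_interval=ri,
                )
            )
    frame = pd.DataFrame([e.__dict__ for e in events])
    if frame.empty:
        return frame
    frame = frame.sort_values(
        ["max_chi2", "date_start", "label"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def _event_key(row) -> tuple:
    return (row.peak_city, row.peak_date, row.peak_hour, row.outcome, row.direction)


def compare_event_lists(
    events_a: pd.DataFrame, events_b: pd.DataFrame, top_k: int
) -> dict[str, pd.DataFrame]:
    """Compare two ranked event lists (e.g. full vs degenerate model).

    Returns per-country counts within the top ``top_k`` of each list, rank
    shifts of events shared between the lists (matched on their peak cell),
    and the events unique to each list.
    """
    a = events_a.head(top_k)
    b = events_b.head(top_k)
    counts = (
        pd.DataFrame(
            {
                "count_a": a.groupby("country").size(),
                "count_b": b.groupby("country").size(),
            }
        )
        .fillna(0)
        .astype(int)
        .rename_axis("country")
        .reset_index()
    )
    ka = {_event_key(r): int(r.rank) for r in a.itertuples(index=False)}
    kb = {_event_key(r): int(r.rank) for r in b.itertuples(index=False)}
    shared = sorted(set(ka) & set(kb), key=lambda k: ka[k])
    shifts = pd.DataFrame(
        {
            "peak_city": [k[0] for k in shared],
            "peak_date": [k[1] for k in shared],
            "peak_hour": [k[2] for k in shared],
            "outcome": [k[3] for k in shared],
            "direction": [k[4] for k in shared],
            "rank_a": [ka[k] for k in shared],
            "rank_b": [kb[k] for k in shared],
        }
    )
    if not shifts.empty:
        shifts["shift"] = shifts["rank_b"] - shifts["rank_a"]
    only_a = a[[_event_key(r) not in kb for r in a.itertuples(index=False)]]
    only_b = b[[_event_key(r) not in ka for r in b.itertuples(index=False)]]
    return {
        "country_counts": counts,
        "rank_shifts": shifts,
        "only_a": only_a.reset_index(drop=True),
        "only_b": only_b.reset_index(drop=True),
    }
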