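"""End-to-end orchestration: simulate, run, compare.

These functions are the library face of the command-line interface.  Every
run writes a ``manifest.json`` (configuration hash, seed, per-stage row
counts) sufficient to reproduce its outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import aggregate as agg
from . import baseline, deviations, ingest, synth
from .config import DataError, PipelineConfig
from .sentiment import Lexicon, classify_batch

logger = logging.getLogger(__name__)


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(outdir: Path, payload: dict, counts: dict) -> None:
    manifest = {
        "config_hash": _config_hash(payload),
        "config": payload,
        "row_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def simulate(config: synth.GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the five synthetic input files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gaz = synth.generate_gazetteer(config)
    weather = synth.generate_weather(config, gaz)
    lexicon = synth.default_lexicon()
    tweets, truth = synth.generate_tweets(config, gaz, weather, lexicon)
    paths = {
        "gazetteer": out / "gazetteer.csv",
        "weather": out / "weather.csv",
        "lexicon": out / "lexicon.csv",
        "tweets": out / "tweets.jsonl",
        "truth_tweets": out / "truth_tweets.csv",
        "truth_cells": out / "truth_cells.csv",
    }
    gaz.to_csv(paths["gazetteer"], index=False)
    weather.to_csv(paths["weather"], index=False)
    lexicon.to_csv(paths["lexicon"], index=False)
    with open(paths["tweets"], "w") as fh:
        for rec in tweets.to_dict(orient="records"):
            fh.write(json.dumps(rec) + "\n")
    truth["tweets"].to_csv(paths["truth_tweets"], index=False)
    truth["cells"].to_csv(paths["truth_cells"], index=False)
    counts = {"tweets": len(tweets), "cities": len(gaz), "weather_rows": len(weather)}
    _write_manifest(out, {"generator": config.__dict__}, counts)
    return paths


def read_tweets(path: str | Path) -> pd.DataFrame:
    """Read a tweet table from JSONL or CSV by file extension."""
    p = Path(path)
    if p.suffix == ".jsonl":
        return pd.read_json(p, lines=True, dtype={"id": str})
    if p.suffix == ".csv":
        return pd.read_csv(p, dtype={"id": str})
    raise DataError(f"unsupported tweet file format: {p.suffix}")


def run(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis: ingest, score, aggregate, model, detect.

    Writes scored tweets, the cell table, per-outcome model comparison
    tables and fitted-model JSON, ranked deviations with recurrence
    intervals, and merged event reports.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tweets = read_tweets(cfg.tweets_path)
    gazetteer = pd.read_csv(cfg.gazetteer_path)
    weather = pd.read_csv(cfg.weather_path)
    lexicon = Lexicon.from_csv(cfg.lexicon_path)

    counts: dict[str, int] = {}
    if tweets.empty:
        logger.warning("run: empty tweet file; writing empty outputs")
        for name in ("cells.csv", "deviations.csv", "events.csv"):
            pd.DataFrame().to_csv(out / name, index=False)
        _write_manifest(out, cfg.to_dict(), {"input": 0})
        return {"output_dir": out}

    resolved, counts = ingest.run_ingest(
        tweets, gazetteer, lang_tag=cfg.lang,
        celebrity_threshold=cfg.celebrity_threshold, top_k=cfg.top_cities,
    )
    scored = classify_batch(resolved, lexicon)
    scored.to_csv(out / "scored_tweets.csv", index=False)

    tz = dict(zip(gazetteer["city"], gazetteer["tz_offset"]))
    cells = agg.aggregate_cells(scored, weather, tz_offsets=tz)
    cells = agg.filter_cells(cells, cfg.min_n)
    counts["cells"] = len(cells)
    cells.to_csv(out / "cells.csv", index=False)

    train = cells[cells["local_date"] < cfg.split_date]
    test = cells[cells["local_date"] >= cfg.split_date]
    counts["cells_train"], counts["cells_test"] = len(train), len(test)
    if train.empty:
        raise DataError("no training cells before the split date")
    if test.empty:
        raise DataError("no test data: no cells on or after the split date")
    observation_days = int(test["local_date"].nunique())

    dev_frames, event_frames = [], []
    for outcome in cfg.outcomes:
        table, models = baseline.model_family(
            train, test, outcome, weight_by_n=cfg.weight_by_n
        )
        table.to_csv(out / f"model_comparison_{outcome}.csv", index=False)
        full = models["All factors"]
        (out / f"model_{outcome}.json").write_text(json.dumps(full.to_dict(), indent=2))
        devs = deviations.compute_deviations(full, test)
        ranked = deviations.rank_deviations(devs)
        ranked = deviations.add_recurrence_intervals(ranked, observation_days)
        dev_frames.append(ranked)
        events = deviations.merge_events(
            ranked, alpha=cfg.alpha, observation_days=observation_days
        )
        event_frames.append(events)

    all_devs = pd.concat(dev_frames, ignore_index=True)
    all_devs.to_csv(out / "deviations.csv", index=False)
    all_events = pd.concat([f for f in event_frames if not f.empty], ignore_index=True) \
        if any(not f.empty for f in event_frames) else pd.DataFrame()
    all_events.to_csv(out / "events.csv", index=False)
    counts["deviations"] = len(all_devs)
    counts["events"] = len(all_events)
    _write_manifest(out, cfg.to_dict(), counts)
    return {"output_dir": out, "cells": out / "cells.csv",
            "deviations": out / "deviations.csv", "events": out / "events.csv"}


def compare(events_a_path: str | Path, events_b_path: str | Path,
            top_k: int, out_path: str | Path) -> dict:
    """Compare two event lists and write a JSON comparison report."""
    a = pd.read_csv(events_a_path)
    b = pd.read_csv(events_b_path)
    for frame, name in ((a, events_a_path), (b, events_b_path)):
        if frame.empty:
            raise DataError(f"event list {name} is empty")
    if set(a["outcome"].unique()) != set(b["outcome"].unique()):
        raise DataError("event lists cover different outcomes")
    k = top_k
    if k > max(len(a), len(b)):
        logger.warning("compare: top_k=%d exceeds list length; using full lists", k)
        k = max(len(a), len(b))
    report = deviations.compare_event_lists(a, b, k)
    payload = {
        "top_k": k,
        "country_counts": report["country_counts"].to_dict(orient="records"),
        "rank_shifts": report["rank_shifts"].to_dict(orient="records"),
        "only_a": report["only_a"].to_dict(orient="records"),
        "only_b": report["only_b"].to_dict(orient="records"),
    }
    Path(out_path).write_text(json.dumps(payload, indent=2, default=str))
    return payload
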