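"""Ingest, score and aggregate a stream into city-hour cells.

The ingest pipeline filters by language tag, removes celebrity accounts
(>= 300,000 followers), resolves free-text profile locations against the
gazetteer's alias table and converts timestamps to local time.  Scored
tweets are then aggregated into the ecological analysis unit: the city-hour
cell with its positive, negative and social proportions.
"""

from datetime import date

import sentiwatch as sw

cfg = sw.GeneratorConfig(n_cities=5, period_start=date(2017, 7, 13),
                         period_end=date(2017, 7, 26), base_volume=40, seed=1)
gazetteer = sw.generate_gazetteer(cfg)
weather = sw.generate_weather(cfg, gazetteer)
lexicon_frame = sw.default_lexicon()
tweets, _ = sw.generate_tweets(cfg, gazetteer, weather, lexicon_frame)

resolved, counts = sw.run_ingest(tweets, gazetteer)
print("per-stage record counts:", counts)

scored = sw.classify_batch(resolved, sw.Lexicon.from_frame(lexicon_frame))
tz = dict(zip(gazetteer["city"], gazetteer["tz_offset"]))
cells = sw.aggregate_cells(scored, weather, tz_offsets=tz)

print(f"\ncells: {len(cells)}")
print(cells.head(5)[["city", "local_date", "local_hour", "n", "p_pos", "p_neg",
                     "p_social", "weather"]].to_string(index=False))
print("\np_pos and p_neg are independent proportions; a cell can be high on both.")
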