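"""Generate a synthetic tweet stream with known sentiment structure.

The generator emulates a city-targeted social-media sample: Poisson tweet
volumes per city-hour, additive city/hour/day/weather/social effects on the
probability that a tweet carries positive or negative sentiment, and full
ground truth for every tweet and cell.
"""

from datetime import date

import sentiwatch as sw

cfg = sw.GeneratorConfig(
    n_cities=5,
    period_start=date(2017, 7, 13),
    period_end=date(2017, 7, 26),
    base_volume=40,
    seed=1,
)
gazetteer = sw.generate_gazetteer(cfg)
weather = sw.generate_weather(cfg, gazetteer)
lexicon = sw.default_lexicon()
tweets, truth = sw.generate_tweets(cfg, gazetteer, weather, lexicon)

print(f"cities: {', '.join(gazetteer['city'])}")
print(f"tweets generated: {len(tweets)}")
print(f"intended positive fraction: {truth['tweets']['intended_pos'].mean():.3f}")
print(f"intended negative fraction: {truth['tweets']['intended_neg'].mean():.3f}")
print(tweets.head(3)[["id", "text", "utc_time", "profile_location"]].to_string(index=False))
print("\nEach tweet's text embeds lexicon terms matching its intended labels,")
print("so dictionary scoring recovers the ground truth exactly.")
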