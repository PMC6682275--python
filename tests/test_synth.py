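"""The generator's contract: determinism, schemas, and statistical fidelity."""

from datetime import date, datetime

import numpy as np
import pandas as pd
import pytest

import sentiwatch as sw
from sentiwatch.synth import WEATHER_CATEGORIES, GeneratorConfig


class TestGazetteer:
    def test_minimal_single_city(self):
        gaz = sw.generate_gazetteer(GeneratorConfig(n_cities=1))
        assert len(gaz) == 1
        assert len(gaz.loc[0, "aliases"].split("|")) >= 1

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig(n_cities=5, seed=7)
        pd.testing.assert_frame_equal(sw.generate_gazetteer(cfg), sw.generate_gazetteer(cfg))

    def test_hundred_cities_unique_names_and_aliases(self):
        gaz = sw.generate_gazetteer(GeneratorConfig(n_cities=100))
        assert gaz["city"].nunique() == 100
        aliases = [a for row in gaz["aliases"] for a in row.split("|")]
        assert len(set(aliases)) == len(aliases)

    def test_duplicate_city_names_rejected(self):
        cfg = GeneratorConfig(n_cities=2, city_names=["A", "A"])
        with pytest.raises(ValueError, match="duplicate"):
            sw.generate_gazetteer(cfg)


class TestWeather:
    def test_one_row_per_city_hour_in_schema(self):
        cfg = GeneratorConfig(n_cities=1, period_start=date(2017, 7, 13),
                              period_end=date(2017, 7, 13))
        wx = sw.generate_weather(cfg)
        assert len(wx) == 24
        assert set(wx["category"]) <= set(WEATHER_CATEGORIES)
        assert wx["utc_time"].nunique() == 24

    def test_full_persistence_freezes_category(self):
        cfg = GeneratorConfig(n_cities=3, weather_persistence=1.0)
        wx = sw.generate_weather(cfg)
        assert (wx.groupby("city")["category"].nunique() == 1).all()

    def test_zero_persistence_is_uniform(self):
        # ~1e5 draws; each category frequency within 3 multinomial SEs of 1/7
        cfg = GeneratorConfig(
            n_cities=30, period_start=date(2017, 7, 13), period_end=date(2017, 11, 30),
            weather_persistence=0.0, seed=5,
        )
        wx = sw.generate_weather(cfg)
        n = len(wx)
        assert n >= 100_000
        se = np.sqrt((1 / 7) * (6 / 7) / n)
        freqs = wx["category"].value_counts(normalize=True)
        assert len(freqs) == 7
        assert (np.abs(freqs - 1 / 7) < 3 * se).all()


class TestLexiconGeneration:
    def test_minimal_pair(self):
        lex = sw.generate_lexicon(n_pos=1, n_neg=1, seed=0)
        assert len(lex) == 2
        assert set(lex["polarity"]) == {"positive", "negative"}

    def test_polarities_disjoint_and_strengths_in_range(self, lexicon_frame):
        pos = set(lexicon_frame.loc[lexicon_frame["polarity"] == "positive", "term"])
        neg = set(lexicon_frame.loc[lexicon_frame["polarity"] == "negative", "term"])
        assert not pos & neg
        assert lexicon_frame["strength"].between(2, 5).all()


class TestTweetStream:
    def test_degenerate_probability_zero(self, gazetteer, weather, lexicon_frame):
        cfg = GeneratorConfig(
            n_cities=4, period_start=date(2017, 7, 13), period_end=date(2017, 7, 13),
            base_volume=20, base_prop_pos=0.0, base_prop_neg=0.0,
            city_effects_pos={c: 0 for c in gazetteer["city"]},
            city_effects_neg={c: 0 for c in gazetteer["city"]},
            hour_effects_pos=[0] * 24, hour_effects_neg=[0] * 24,
            dow_effects_pos=[0] * 7, dow_effects_neg=[0] * 7,
            weather_effects_pos={w: 0 for w in WEATHER_CATEGORIES},
            weather_effects_neg={w: 0 for w in WEATHER_CATEGORIES},
            social_effect_pos=0.0, social_effect_neg=0.0, seed=1,
        )
        tweets, truth = sw.generate_tweets(cfg, gazetteer, weather, lexicon_frame)
        assert not tweets["text"].str.contains("posterm").any()
        assert not truth["tweets"]["intended_pos"].any()

    def test_degenerate_probability_one(self, gazetteer, weather, lexicon_frame):
        cfg = GeneratorConfig(
            n_cities=4, period_start=date(2017, 7, 13), period_end=date(2017, 7, 13),
            base_volume=20, base_prop_pos=1.0, social_effect_pos=0.0,
            city_effects_pos={c: 0 for c in gazetteer["city"]},
            hour_effects_pos=[0] * 24, dow_effects_pos=[0] * 7,
            weather_effects_pos={w: 0 for w in WEATHER_CATEGORIES}, seed=1,
        )
        tweets, _ = sw.generate_tweets(cfg, gazetteer, weather, lexicon_frame)
        lex = sw.Lexicon.from_frame(lexicon_frame)
        scored = sw.classify_batch(tweets, lex)
        assert scored["is_positive"].all()

    def test_positive_fraction_matches_binomial_oracle(self, gazetteer, lexicon_frame):
        # ~1e5 tweets with flat p=0.4: observed fraction within 3 binomial SEs
        cfg = GeneratorConfig(
            n_cities=4, period_start=date(2017, 7, 13), period_end=date(2017, 7, 26),
            base_volume=75, base_prop_pos=0.4,
            city_effects_pos={c: 0 for c in gazetteer["city"]},
            hour_effects_pos=[0] * 24, dow_effects_pos=[0] * 7,
            weather_effects_pos={w: 0 for w in WEATHER_CATEGORIES},
            social_effect_pos=0.0, seed=9,
        )
        wx = sw.generate_weather(cfg, gazetteer)
        _, truth = sw.generate_tweets(cfg, gazetteer, wx, lexicon_frame)
        frac = truth["tweets"]["intended_pos"].mean()
        n = len(truth["tweets"])
        assert n > 90_000
        assert abs(frac - 0.4) < 3 * np.sqrt(0.4 * 0.6 / n)

    def test_roundtrip_scoring_recovers_intended_labels(self, stream, lexicon):
        tweets, truth = stream
        scored = sw.classify_batch(tweets, lexicon)
        merged = scored.merge(truth["tweets"], on="id")
        assert (merged["is_positive"] == merged["intended_pos"]).all()
        assert (merged["is_negative"] == merged["intended_neg"]).all()

    def test_same_seed_byte_identical(self, small_config, gazetteer, weather, lexicon_frame):
        a, _ = sw.generate_tweets(small_config, gazetteer, weather, lexicon_frame)
        b, _ = sw.generate_tweets(small_config, gazetteer, weather, lexicon_frame)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_gazetteer_rejected(self, weather, lexicon_frame):
        with pytest.raises(ValueError, match="gazetteer"):
            sw.generate_tweets(GeneratorConfig(), pd.DataFrame(), weather, lexicon_frame)


class TestCellGeneration:
    @pytest.mark.parametrize("volume", [50, 200, 800])
    def test_empirical_proportions_converge_to_truth(self, volume):
        cfg = GeneratorConfig(
            n_cities=3, period_start=date(2017, 7, 13), period_end=date(2017, 7, 19),
            base_volume=volume, seed=3,
        )
        cells = sw.generate_cells(cfg)
        # pooled z-score of observed counts vs cell-level truth, within 4 SE
        resid = cells["n_pos"] - cells["n"] * cells["p_pos_true"]
        var = (cells["n"] * cells["p_pos_true"] * (1 - cells["p_pos_true"])).sum()
        assert abs(resid.sum()) < 4 * np.sqrt(var)

    def test_event_injection_is_local(self):
        ev = sw.InjectedEvent(
            city=None, start=datetime(2017, 7, 15, 10), duration_h=4, delta_neg=0.3
        )
        base = GeneratorConfig(n_cities=3, period_start=date(2017, 7, 13),
                               period_end=date(2017, 7, 18), seed=4, base_volume=40)
        gaz = sw.generate_gazetteer(base)
        target = gaz.loc[1, "city"]
        ev = sw.InjectedEvent(city=target, start=ev.start, duration_h=4, delta_neg=0.3)
        with_ev = sw.generate_cells(base.with_(events=(ev,)))
        without = sw.generate_cells(base)
        merged = with_ev.merge(
            without, on=["city", "local_date", "local_hour"], suffixes=("_ev", "_0")
        )
        changed = merged["p_neg_true_ev"] != merged["p_neg_true_0"]
        flagged = merged["event_active_ev"]
        assert (changed == flagged).all()
        assert flagged.sum() == 4
        assert set(merged.loc[flagged, "city"]) == {target}

    def test_noiseless_cells_match_linear_predictor_exactly(self):
        cfg = GeneratorConfig(n_cities=3, period_start=date(2017, 7, 13),
                              period_end=date(2017, 7, 16), seed=6)
        cells = sw.generate_cells(cfg, noiseless=True)
        assert np.allclose(cells["p_pos"], cells["p_pos_true"])
        assert np.allclose(cells["p_neg"], cells["p_neg_true"])

    def test_true_proportions_clamped(self):
        cfg = GeneratorConfig(n_cities=2, period_start=date(2017, 7, 13),
                              period_end=date(2017, 7, 14), base_prop_pos=0.95,
                              social_effect_pos=0.5, seed=8)
        cells = sw.generate_cells(cfg)
        assert cells["p_pos_true"].between(0, 1).all()
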