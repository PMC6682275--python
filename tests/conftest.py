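from datetime import date, datetime

import pytest

import sentiwatch as sw


@pytest.fixture(scope="session")
def small_config() -> sw.GeneratorConfig:
    """A 4-city, 6-day stream: small but exercises every factor."""
    return sw.GeneratorConfig(
        n_cities=4,
        period_start=date(2017, 7, 13),
        period_end=date(2017, 7, 18),
        base_volume=30.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def gazetteer(small_config):
    return sw.generate_gazetteer(small_config)


@pytest.fixture(scope="session")
def weather(small_config, gazetteer):
    return sw.generate_weather(small_config, gazetteer)


@pytest.fixture(scope="session")
def lexicon_frame():
    return sw.generate_lexicon(n_pos=12, n_neg=12, seed=7)


@pytest.fixture(scope="session")
def lexicon(lexicon_frame):
    return sw.Lexicon.from_frame(lexicon_frame)


@pytest.fixture(scope="session")
def stream(small_config, gazetteer, weather, lexicon_frame):
    """(tweets, truth) for the small config."""
    return sw.generate_tweets(small_config, gazetteer, weather, lexicon_frame)


@pytest.fixture(scope="session")
def event_config(small_config):
    """Same stream with one strong injected negative event."""
    ev = sw.InjectedEvent(
        city="Babaton000",
        start=datetime(2017, 7, 16, 12),
        duration_h=6,
        delta_neg=0.35,
        delta_pos=-0.15,
    )
    return small_config.with_(events=(ev,), base_volume=120.0, seed=11)
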