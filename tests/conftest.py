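from datetime import datetime, timezone

import pytest

from xldiff import RetweetEvent, SyntheticConfig, generate_corpus


def ev(eid, ts, retweeter, source, lang="en", text="", urls=()):
    """Terse event constructor for hand-built fixtures."""
    if isinstance(ts, str):
        ts = datetime.fromisoformat(ts)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return RetweetEvent(eid, ts, retweeter, source, lang, text, tuple(urls))


@pytest.fixture(scope="session")
def small_corpus():
    """A small but fully featured bilingual corpus with ground truth."""
    cfg = SyntheticConfig(
        n_users_en=300, n_users_ja=200, n_months=6, n_urls=150,
        crosslingual_share_prob=0.7, rng_seed=11,
    )
    events, truth = generate_corpus(cfg)
    return events, truth
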