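from __future__ import annotations

from datetime import date

import pytest

from pulsecube import pipeline, synthgen
from pulsecube.stream_io import Post, Stream, UserAccount


@pytest.fixture(scope="session")
def fixture_stream():
    """The deterministic small synthetic stream plus its ground truth."""
    return synthgen.small_fixture()


@pytest.fixture(scope="session")
def study_stream():
    """The default-condition synthetic study stream (90 days, 50 users,
    10 events, 20 topics, 100 noise bigrams), seed 1."""
    return synthgen.generate_stream(synthgen.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def study_result(study_stream):
    stream, _ = study_stream
    return pipeline.run_analysis(stream, seed=1)


@pytest.fixture()
def tiny_stream():
    """Hand-built 3-post / 2-user stream with known metric values:
    author A has Yule's I 4/3, author B 8/3; one reply, one first-person
    post."""
    users = {
        "uA": UserAccount(user_id="uA", screen_name="a", verified=True),
        "uB": UserAccount(user_id="uB", screen_name="b"),
    }
    d = date(2019, 6, 1)
    posts = [
        Post(post_id="p1", text="alpha alpha beta", day=d, lang="en", user_id="uA"),
        Post(post_id="p2", text="gamma delta epsilon", day=d, lang="en", user_id="uB"),
        Post(post_id="p3", text="gamma delta my", day=d, lang="en", user_id="uB",
             in_reply_to="p2"),
    ]
    return Stream(posts=posts, users=users, window=(d, d))
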