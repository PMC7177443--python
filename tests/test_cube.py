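from collections import Counter
from datetime import date

import pytest

from pulsecube import pipeline, textmetrics
from pulsecube.cube import (
    GroupReport,
    UserFact,
    assign_quality_bands,
    audience_profile_histogram,
    build_post_facts,
    build_user_facts,
    classify_user_quality,
    controversial_screen,
    filter_stream,
    group_report,
)
from pulsecube.eventtopic import TermGroup
from pulsecube.stream_io import Post, Stream, UserAccount


def _fact(n, yule, coh, uid="u", **kw):
    return UserFact(user_id=uid, n_posts_in_stream=n, yules_i=yule,
                    coherence=coh, verified=False, followers=0, **kw)


class TestBuildUserFacts:
    def test_pooled_yule_matches_text_metric_oracle(self, tiny_stream):
        facts = build_user_facts(tiny_stream, pipeline.default_domain_model())
        assert facts["uA"].yules_i == pytest.approx(4 / 3)
        assert facts["uB"].yules_i == pytest.approx(8 / 3)
        assert len(facts) == 2

    def test_retweet_only_user_has_undefined_metrics(self):
        d = date(2019, 6, 1)
        users = {"u1": UserAccount(user_id="u1"), "u2": UserAccount(user_id="u2")}
        posts = [
            Post(post_id="p1", text="skin cancer", day=d, lang="en", user_id="u1"),
            Post(post_id="p2", text="skin cancer", day=d, lang="en", user_id="u2",
                 retweet_of="p1"),
        ]
        s = Stream(posts=posts, users=users, window=(d, d))
        facts = build_user_facts(s, pipeline.default_domain_model())
        assert not facts["u2"].metrics_defined
        assert facts["u2"].n_posts_in_stream == 1
        with pytest.raises(ValueError):
            classify_user_quality(facts["u2"])

    def test_band_assignment_skips_undefined(self):
        facts = {"u": UserFact(user_id="u", n_posts_in_stream=0, yules_i=None,
                               coherence=None, verified=False, followers=0)}
        assign_quality_bands(facts)
        assert facts["u"].quality_band is None


class TestClassifyUserQuality:
    def test_low_diversity_high_volume_is_filtered(self):
        # weather-bot-like account: 963 posts, Yule's I 29.8
        assert classify_user_quality(_fact(963, 29.8, 0.32e-4)) == "filtered"

    def test_offdomain_high_volume_is_filtered(self):
        # prolific comics bot: high diversity but coherence 0.21e-4
        assert classify_user_quality(_fact(2556, 94.3, 0.21e-4)) == "filtered"

    def test_small_clean_account_is_good(self):
        assert classify_user_quality(_fact(2, 200.0, 3e-4)) == "good"

    def test_boundary_neighbourhood_is_inspect(self):
        # volume just under the cutoff with bot-like diversity
        assert classify_user_quality(_fact(90, 25.0, 3e-4)) == "inspect"
        # coherence just above the off-domain cutoff
        assert classify_user_quality(_fact(500, 120.0, 0.55e-4)) == "inspect"

    def test_low_volume_never_filtered(self):
        assert classify_user_quality(_fact(50, 1.0, 0.0)) == "good"


class TestFilterStream:
    def _stream(self, n_bad=15, n_good=85):
        d = date(2019, 6, 1)
        users = {"bad": UserAccount(user_id="bad"),
                 "good": UserAccount(user_id="good")}
        posts = [Post(post_id=f"b{i}", text="x", day=d, lang="en", user_id="bad")
                 for i in range(n_bad)]
        posts += [Post(post_id=f"g{i}", text="y", day=d, lang="en", user_id="good")
                  for i in range(n_good)]
        return Stream(posts=posts, users=users, window=(d, d))

    def test_removed_fraction(self):
        s = self._stream()
        facts = {
            "bad": _fact(15, 5.0, 0.0, uid="bad", quality_band="filtered"),
            "good": _fact(85, 80.0, 1e-3, uid="good", quality_band="good"),
        }
        clean, removed = filter_stream(s, facts)
        assert len(clean) == 85
        assert removed == pytest.approx(0.15)

    def test_no_filtered_users_is_identity(self):
        s = self._stream()
        facts = {u: _fact(1, 80.0, 1e-3, uid=u, quality_band="good")
                 for u in s.users}
        clean, removed = filter_stream(s, facts)
        assert clean.posts == s.posts and removed == 0.0

    def test_all_filtered_warns_and_empties(self, caplog):
        s = self._stream()
        facts = {u: _fact(1, 1.0, 0.0, uid=u, quality_band="filtered")
                 for u in s.users}
        with caplog.at_level("WARNING"):
            clean, removed = filter_stream(s, facts)
        assert len(clean) == 0 and removed == 1.0
        assert "all posts removed" in caplog.text

    def test_fraction_conservation(self, fixture_stream):
        stream, _ = fixture_stream
        facts = build_user_facts(stream, pipeline.default_domain_model())
        assign_quality_bands(facts)
        clean, removed = filter_stream(stream, facts)
        assert removed + len(clean) / len(stream) == pytest.approx(1.0)


class TestGroupReport:
    def test_hand_computed_row(self, tiny_stream):
        facts = build_user_facts(tiny_stream, pipeline.default_domain_model())
        group = TermGroup(group_id="g", kind="topic",
                          terms=frozenset({("gamma", "delta")}),
                          post_ids={"p1", "p2", "p3"})
        empty = Stream(users=dict(tiny_stream.users), window=tiny_stream.window)
        r = group_report(group, tiny_stream, empty, facts)
        assert r.n_tweets == 3
        assert r.avg_yule == pytest.approx(2.0)  # mean of 4/3 and 8/3
        assert r.pct_verified == pytest.approx(50.0)
        assert r.n_users_tweeting == 2
        assert r.n_users_retweeting == 0
        assert r.pct_replies == pytest.approx(100 / 3)
        assert r.pct_first_person == pytest.approx(100 / 3)

    def test_on_dom_is_mean_author_volume(self):
        d = date(2019, 6, 1)
        users = {f"u{i}": UserAccount(user_id=f"u{i}") for i in (1, 2)}
        posts = [Post(post_id=f"a{j}", text="skin cancer", day=d, lang="en",
                      user_id="u1") for j in range(4)]
        posts += [Post(post_id=f"b{j}", text="skin cancer", day=d, lang="en",
                       user_id="u2") for j in range(8)]
        s = Stream(posts=posts, users=users, window=(d, d))
        facts = build_user_facts(s, pipeline.default_domain_model())
        group = TermGroup(group_id="g", kind="topic",
                          terms=frozenset({("skin", "cancer")}),
                          post_ids={"a0", "b0"})
        r = group_report(group, s, Stream(users=users, window=(d, d)), facts)
        assert r.on_dom == pytest.approx(6.0)

    def test_empty_group_rejected(self, tiny_stream):
        facts = build_user_facts(tiny_stream, pipeline.default_domain_model())
        group = TermGroup(group_id="g", kind="topic",
                          terms=frozenset({("x", "y")}), post_ids=set())
        with pytest.raises(ValueError):
            group_report(group, tiny_stream,
                         Stream(users=dict(tiny_stream.users)), facts)

    def test_matches_flat_scan_oracle_on_fixture(self, fixture_stream):
        """Every report column recomputed by a flat scan over raw posts."""
        stream, _ = fixture_stream
        res = pipeline.run_analysis(stream, seed=0)
        originals, retweets, facts = res.originals, res.retweets, res.facts
        by_id = {p.post_id: p for p in originals.posts}
        for g in res.event_groups + res.topic_groups:
            if not g.post_ids:
                continue
            r = group_report(g, originals, retweets, facts)
            posts = [by_id[pid] for pid in g.post_ids]
            authors = {p.user_id for p in posts}
            assert r.n_tweets == len(posts)
            assert r.n_users_tweeting == len(authors)
            assert r.avg_yule == pytest.approx(
                sum(facts[u].yules_i for u in authors) / len(authors))
            assert r.pct_verified == pytest.approx(
                100 * sum(stream.users[u].verified for u in authors) / len(authors))
            assert r.on_dom == pytest.approx(
                sum(facts[u].n_posts_in_stream for u in authors) / len(authors))
            assert r.n_users_retweeting == len(
                {p.user_id for p in retweets.posts if p.retweet_of in g.post_ids})
            assert r.pct_replies == pytest.approx(
                100 * sum(p.is_reply for p in posts) / len(posts))
            assert r.pct_first_person == pytest.approx(
                100 * sum(
                    textmetrics.is_first_person(textmetrics.tokenize(p.text, p.lang))
                    for p in posts) / len(posts))


class TestAudienceHistogram:
    def _setup(self):
        d = date(2019, 6, 1)
        users = {
            "j1": UserAccount(user_id="j1"), "j2": UserAccount(user_id="j2"),
            **{f"c{i}": UserAccount(user_id=f"c{i}") for i in range(5)},
        }
        posts = [
            Post(post_id="p1", text="skin cancer", day=d, lang="en", user_id="j1"),
            Post(post_id="p2", text="skin cancer now", day=d, lang="en",
                 user_id="j2"),
        ]
        rts = [Post(post_id=f"r{i}", text="skin cancer", day=d, lang="en",
                    user_id=f"c{i}", retweet_of="p1") for i in range(5)]
        originals = Stream(posts=posts, users=users, window=(d, d))
        retweets = Stream(posts=rts, users=users, window=(d, d))
        facts = {}
        for u in users:
            facts[u] = _fact(1, 50.0, 1e-3, uid=u)
            facts[u].profile = "journalist" if u.startswith("j") else "concerned"
        group = TermGroup(group_id="g", kind="event",
                          terms=frozenset({("skin", "cancer")}),
                          post_ids={"p1", "p2"})
        return group, originals, retweets, facts

    def test_author_and_audience_split_by_profile(self):
        group, originals, retweets, facts = self._setup()
        hist = audience_profile_histogram(group, originals, retweets, facts)
        assert hist == {"journalist": (2, 0), "concerned": (0, 5)}

    def test_self_retweeter_counts_in_both_roles(self):
        group, originals, retweets, facts = self._setup()
        d = date(2019, 6, 1)
        retweets.posts.append(
            Post(post_id="rself", text="skin cancer", day=d, lang="en",
                 user_id="j1", retweet_of="p1"))
        hist = audience_profile_histogram(group, originals, retweets, facts)
        assert hist["journalist"] == (2, 1)

    def test_no_retweets_means_empty_audience(self):
        group, originals, _, facts = self._setup()
        empty = Stream(users=dict(originals.users), window=originals.window)
        hist = audience_profile_histogram(group, originals, empty, facts)
        assert all(aud == 0 for _, aud in hist.values())


def _report(gid="g", yule=80.0, ver=10.0, ondom=5.0, replies=0.0, retw=5,
            fp=0.0):
    return GroupReport(group_id=gid, kind="topic", label=gid, n_tweets=100,
                       avg_yule=yule, pct_verified=ver, on_dom=ondom,
                       n_users_tweeting=50, n_users_retweeting=retw,
                       pct_replies=replies, pct_first_person=fp)


class TestControversialScreen:
    def test_spam_like_pattern(self):
        flags = controversial_screen(
            [_report(gid="spam", yule=24.0, ver=0.0, ondom=282.0, retw=0)])
        assert flags["spam"] == ["spam-like"]

    def test_active_discussion_pattern(self):
        flags = controversial_screen([_report(gid="disc", replies=43.0)])
        assert "discussion" in flags["disc"]

    def test_discussion_only_for_high_quality_group(self):
        flags = controversial_screen(
            [_report(gid="g", yule=85.0, ver=5.0, ondom=2.0, replies=43.0)])
        assert flags["g"] == ["discussion"]

    def test_unverified_viral_pattern(self):
        flags = controversial_screen(
            [_report(gid="v", ver=0.0, retw=10)])
        assert flags["v"] == ["unverified-viral"]

    def test_unflagged_groups_absent(self):
        assert controversial_screen([_report()]) == {}


class TestConservation:
    def test_complete_dimension_partitions_sum_to_total(self, fixture_stream):
        stream, _ = fixture_stream
        facts = build_user_facts(stream, pipeline.default_domain_model())
        assign_quality_bands(facts)
        pfacts = build_post_facts(stream)
        total = len(stream)
        for dim in (
            lambda p: p.lang,
            lambda p: p.day,
            lambda p: facts[p.user_id].quality_band,
            lambda p: p.is_reply,
        ):
            cells = Counter(dim(pf) for pf in pfacts.values())
            assert sum(cells.values()) == total
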