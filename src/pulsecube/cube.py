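"""The star-schema analysis cube: post facts and user facts with topic,
temporality, quality and profile dimensions.

Post facts carry per-post measures (day, language, group membership,
reply/first-person flags, engagement counts); user facts carry per-account
aggregates (volume in the stream, Yule's I vocabulary diversity, domain
coherence, verified flag, predicted profile) and the quality band derived
from them.  The band rules encode the two noise patterns visible in a
keyword-collected stream: automated accounts (high volume, Yule's I below
30) and prolific out-of-domain accounts (high volume, domain coherence
near zero).  Users inside a configurable margin of either decision
boundary are sent to manual inspection rather than silently kept or
dropped.

Group reports aggregate a term group (an event or a topic) into one table
row: tweet count, mean author Yule's I (Y), percentage of verified
authors (%Ver.), mean author volume in the stream (OnDom.), distinct
authors and retweeting users, and the percentage of replies and of
first-person posts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping

import pandas as pd

from . import textmetrics
from .eventtopic import TermGroup
from .profiling import ProfileModel, predict_profile
from .stream_io import Stream
from .textmetrics import LanguageModel, YULE_CAP

logger = logging.getLogger(__name__)

__all__ = [
    "UserFact",
    "PostFact",
    "QualityThresholds",
    "GroupReport",
    "build_user_facts",
    "classify_user_quality",
    "assign_quality_bands",
    "filter_stream",
    "build_post_facts",
    "group_report",
    "audience_profile_histogram",
    "controversial_screen",
    "reports_to_frame",
    "user_facts_to_frame",
]


@dataclass
class UserFact:
    """Per-account aggregate over the user's original posts."""

    user_id: str
    n_posts_in_stream: int
    yules_i: float | None
    coherence: float | None
    verified: bool
    followers: int
    profile: str = "others"
    quality_band: str | None = None

    @property
    def metrics_defined(self) -> bool:
        return self.yules_i is not None and self.coherence is not None


@dataclass(frozen=True)
class PostFact:
    post_id: str
    user_id: str
    day: date
    lang: str
    group_ids: frozenset[str]
    is_reply: bool
    is_first_person: bool
    reply_count: int
    retweet_count: int
    like_count: int


@dataclass(frozen=True)
class QualityThresholds:
    """Band boundaries.  ``inspect_margin`` widens each rule
    multiplicatively: a user caught only by the widened rule needs manual
    inspection instead of filtering."""

    bot_max_yule: float = 30.0
    bot_min_posts: int = 100
    offdomain_max_coherence: float = 0.5e-4
    offdomain_min_posts: int = 100
    inspect_margin: float = 0.20

    def __post_init__(self) -> None:
        if min(self.bot_max_yule, self.bot_min_posts,
               self.offdomain_max_coherence, self.offdomain_min_posts) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 <= self.inspect_margin < 1.0:
            raise ValueError("inspect_margin must be in [0, 1)")


@dataclass(frozen=True)
class GroupReport:
    """One report-table row for an event or topic group."""

    group_id: str
    kind: str
    label: str
    n_tweets: int
    avg_yule: float
    pct_verified: float
    on_dom: float
    n_users_tweeting: int
    n_users_retweeting: int
    pct_replies: float
    pct_first_person: float


def build_user_facts(
    stream: Stream,
    domain_lm: LanguageModel,
    profile_model: ProfileModel | None = None,
) -> dict[str, UserFact]:
    """Compute per-user facts from the pooled original posts of each user.

    Retweets are excluded from the text metrics; a user with only retweets
    (or no posts) gets undefined metrics and no band.  Yule's I for users
    whose every word is a hapax is reported at the standard cap.
    """
    by_user: dict[str, list] = {u: [] for u in stream.users}
    for p in stream.posts:
        if not p.is_retweet:
            by_user[p.user_id].append(p)
    n_posts = {u: 0 for u in stream.users}
    for p in stream.posts:
        n_posts[p.user_id] += 1
    facts: dict[str, UserFact] = {}
    for uid, acct in stream.users.items():
        originals = by_user[uid]
        if not originals:
            facts[uid] = UserFact(
                user_id=uid, n_posts_in_stream=n_posts[uid],
                yules_i=None, coherence=None,
                verified=acct.verified, followers=acct.followers,
            )
            continue
        seqs = [textmetrics.tokenize(p.text, p.lang) for p in originals]
        pooled = [t for s in seqs for t in s.tokens]
        if pooled:
            spec = textmetrics.frequency_spectrum(pooled)
            yi = textmetrics.yules_i(spec, cap=YULE_CAP)
        else:
            yi = None
        user_lm = textmetrics.build_language_model(seqs)
        coh = textmetrics.domain_coherence(user_lm, domain_lm) if user_lm.probs else None
        profile = "others"
        if profile_model is not None:
            profile, _ = predict_profile(profile_model, acct.description)
        facts[uid] = UserFact(
            user_id=uid, n_posts_in_stream=n_posts[uid],
            yules_i=yi, coherence=coh,
            verified=acct.verified, followers=acct.followers, profile=profile,
        )
    return facts


def classify_user_quality(
    fact: UserFact, th: QualityThresholds = QualityThresholds()
) -> str:
    """Assign good / inspect / filtered from a user's metrics.

    Filtered: high volume with bot-like diversity (Yule's I below the bot
    cutoff) or with near-zero domain coherence.  Inspect: caught only when
    every boundary of either rule is relaxed by the inspect margin.
    """
    if not fact.metrics_defined:
        raise ValueError(f"user {fact.user_id}: metrics undefined, cannot band")
    n, yi, coh = fact.n_posts_in_stream, fact.yules_i, fact.coherence
    m = th.inspect_margin

    def rule(min_posts: float, yule_cap: float | None, coh_cap: float | None) -> bool:
        if n < min_posts:
            return False
        if yule_cap is not None and yi < yule_cap:
            return True
        if coh_cap is not None and coh < coh_cap:
            return True
        return False

    strict = rule(th.bot_min_posts, th.bot_max_yule, None) or rule(
        th.offdomain_min_posts, None, th.offdomain_max_coherence
    )
    if strict:
        return "filtered"
    relaxed = rule(th.bot_min_posts * (1 - m), th.bot_max_yule * (1 + m), None) or rule(
        th.offdomain_min_posts * (1 - m), None, th.offdomain_max_coherence * (1 + m)
    )
    return "inspect" if relaxed else "good"


def assign_quality_bands(
    facts: Mapping[str, UserFact], th: QualityThresholds = QualityThresholds()
) -> None:
    """Band every fact in place; users without metrics keep band None."""
    for fact in facts.values():
        if fact.metrics_defined:
            fact.quality_band = classify_user_quality(fact, th)


def filter_stream(
    stream: Stream, facts: Mapping[str, UserFact]
) -> tuple[Stream, float]:
    """Drop every post (originals and retweets) authored by a filtered
    user; returns the cleaned stream and the removed-tweet fraction."""
    bad = {u for u, f in facts.items() if f.quality_band == "filtered"}
    kept = [p for p in stream.posts if p.user_id not in bad]
    removed_fraction = 1.0 - len(kept) / len(stream.posts) if stream.posts else 0.0
    if not kept:
        logger.warning("filter_stream: all posts removed")
    return (
        Stream(posts=kept, users=dict(stream.users), window=stream.window),
        removed_fraction,
    )


def build_post_facts(
    stream: Stream, assignment: Mapping[str, set[str]] | None = None
) -> dict[str, PostFact]:
    """One fact per post; ``assignment`` maps group_id -> post_ids."""
    groups_of: dict[str, set[str]] = {}
    if assignment:
        for gid, pids in assignment.items():
            for pid in pids:
                groups_of.setdefault(pid, set()).add(gid)
    out = {}
    for p in stream.posts:
        toks = textmetrics.tokenize(p.text, p.lang)
        out[p.post_id] = PostFact(
            post_id=p.post_id, user_id=p.user_id, day=p.day, lang=p.lang,
            group_ids=frozenset(groups_of.get(p.post_id, ())),
            is_reply=p.is_reply,
            is_first_person=textmetrics.is_first_person(toks),
            reply_count=p.reply_count, retweet_count=p.retweet_count,
            like_count=p.like_count,
        )
    return out


def _group_label(group: TermGroup) -> str:
    return " / ".join(" ".join(t) for t in sorted(group.terms)[:3])


def group_report(
    group: TermGroup,
    originals: Stream,
    retweets: Stream,
    facts: Mapping[str, UserFact],
) -> GroupReport:
    """Aggregate one term group into a report row.

    Author metrics (Y, %Ver., OnDom.) average over *distinct authors*, not
    posts.  %replies and %first-person are over the group's original
    posts.  The audience is resolved through retweet links only.
    """
    posts = [p for p in originals.posts if p.post_id in group.post_ids]
    if not posts:
        raise ValueError(f"group {group.group_id} has no posts in this stream")
    authors = sorted({p.user_id for p in posts})
    yules = [facts[u].yules_i for u in authors if facts[u].yules_i is not None]
    avg_yule = sum(yules) / len(yules) if yules else float("nan")
    pct_verified = 100.0 * sum(facts[u].verified for u in authors) / len(authors)
    on_dom = sum(facts[u].n_posts_in_stream for u in authors) / len(authors)
    retweeters = {
        p.user_id for p in retweets.posts if p.retweet_of in group.post_ids
    }
    n_replies = sum(p.is_reply for p in posts)
    n_fp = sum(
        textmetrics.is_first_person(textmetrics.tokenize(p.text, p.lang))
        for p in posts
    )
    return GroupReport(
        group_id=group.group_id,
        kind=group.kind,
        label=_group_label(group),
        n_tweets=len(posts),
        avg_yule=avg_yule,
        pct_verified=pct_verified,
        on_dom=on_dom,
        n_users_tweeting=len(authors),
        n_users_retweeting=len(retweeters),
        pct_replies=100.0 * n_replies / len(posts),
        pct_first_person=100.0 * n_fp / len(posts),
    )


def audience_profile_histogram(
    group: TermGroup,
    originals: Stream,
    retweets: Stream,
    facts: Mapping[str, UserFact],
) -> dict[str, tuple[int, int]]:
    """Histogram the group's authors and audience by profile.

    Authors are distinct posters of the group's posts; the audience is the
    distinct users retweeting them.  A user retweeting their own group
    post appears in both roles.  Returns profile -> (n_authors, n_audience)
    for every profile present in either role.
    """
    authors = {p.user_id for p in originals.posts if p.post_id in group.post_ids}
    audience = {
        p.user_id for p in retweets.posts if p.retweet_of in group.post_ids
    }
    hist: dict[str, list[int]] = {}
    for uid in authors:
        prof = facts[uid].profile
        hist.setdefault(prof, [0, 0])[0] += 1
    for uid in audience:
        prof = facts[uid].profile
        hist.setdefault(prof, [0, 0])[1] += 1
    return {k: (v[0], v[1]) for k, v in hist.items()}


@dataclass(frozen=True)
class ScreenThresholds:
    """Flags for candidate controversial / monitorable groups."""

    spam_max_yule: float = 30.0
    spam_min_on_dom: float = 100.0
    discussion_min_pct_replies: float = 40.0


def controversial_screen(
    reports: Iterable[GroupReport],
    th: ScreenThresholds = ScreenThresholds(),
) -> dict[str, list[str]]:
    """Flag groups worth monitoring.

    * ``spam-like``: very low author diversity with huge per-author volume
      (claim-style spam campaigns);
    * ``discussion``: a high reply share marks an active discussion;
    * ``unverified-viral``: retweeted audience but not a single verified
      author.
    Returns group_id -> list of flags (flagged groups only).
    """
    out: dict[str, list[str]] = {}
    for r in reports:
        flags = []
        if r.avg_yule < th.spam_max_yule and r.on_dom > th.spam_min_on_dom:
            flags.append("spam-like")
        if r.pct_replies >= th.discussion_min_pct_replies:
            flags.append("discussion")
        if r.pct_verified == 0.0 and r.n_users_retweeting > 0:
            flags.append("unverified-viral")
        if flags:
            out[r.group_id] = flags
    return out


def reports_to_frame(reports: Iterable[GroupReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


def user_facts_to_frame(facts: Mapping[str, UserFact]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in facts.values()])
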