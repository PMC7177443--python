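"""Reading, validating and partitioning micro-blog post streams.

The on-disk format is JSON Lines in a minimal subset of the Twitter v1.1
field vocabulary (``id_str``, ``full_text``, ``created_at`` as an ISO date,
``user`` with ``id_str``/``screen_name``/``description``/``verified``/
``followers_count``, ``retweeted_status.id_str``,
``in_reply_to_status_id_str``, ``lang``), so that real platform exports can
be adapted with a thin field mapping.  Timestamps are kept at day
resolution: that is the canonical time grain of all temporal analysis in
this package.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

SUPPORTED_LANGS = frozenset({"en", "es"})

__all__ = [
    "Post",
    "UserAccount",
    "Stream",
    "StreamFormatError",
    "read_stream",
    "write_stream",
    "dedup_texts",
    "split_retweets",
    "keyword_filter",
    "normalize_text",
]


class StreamFormatError(ValueError):
    """A stream file violates the JSONL dialect or a record invariant."""


@dataclass(frozen=True)
class Post:
    """One micro-blog message at day resolution."""

    post_id: str
    text: str
    day: date
    lang: str
    user_id: str
    retweet_of: str | None = None
    in_reply_to: str | None = None
    reply_count: int = 0
    retweet_count: int = 0
    like_count: int = 0

    def __post_init__(self) -> None:
        if self.retweet_of == self.post_id:
            raise StreamFormatError(f"post {self.post_id} retweets itself")
        if self.in_reply_to == self.post_id:
            raise StreamFormatError(f"post {self.post_id} replies to itself")
        for name in ("reply_count", "retweet_count", "like_count"):
            if getattr(self, name) < 0:
                raise StreamFormatError(f"post {self.post_id}: negative {name}")
        if self.lang not in SUPPORTED_LANGS:
            raise StreamFormatError(
                f"post {self.post_id}: unsupported lang {self.lang!r}"
            )

    @property
    def is_retweet(self) -> bool:
        return self.retweet_of is not None

    @property
    def is_reply(self) -> bool:
        return self.in_reply_to is not None


@dataclass(frozen=True)
class UserAccount:
    """A poster account; ``description`` feeds the profile dimension."""

    user_id: str
    screen_name: str = ""
    description: str = ""
    verified: bool = False
    followers: int = 0

    def __post_init__(self) -> None:
        if self.followers < 0:
            raise StreamFormatError(f"user {self.user_id}: negative followers")


@dataclass
class Stream:
    """An ordered collection of posts plus the accounts that wrote them.

    ``window`` is the inclusive ``[start_day, end_day]`` analysis window;
    it is ``None`` only for an empty stream.
    """

    posts: list[Post] = field(default_factory=list)
    users: dict[str, UserAccount] = field(default_factory=dict)
    window: tuple[date, date] | None = None

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self):
        return iter(self.posts)

    def post_by_id(self, post_id: str) -> Post | None:
        if not hasattr(self, "_index") or len(self._index) != len(self.posts):
            self._index = {p.post_id: p for p in self.posts}
        return self._index.get(post_id)

    def validate(self) -> None:
        """Check stream-level invariants; raise StreamFormatError on failure."""
        seen: set[str] = set()
        for p in self.posts:
            if p.post_id in seen:
                raise StreamFormatError(f"duplicate post_id {p.post_id}")
            seen.add(p.post_id)
            if p.user_id not in self.users:
                raise StreamFormatError(
                    f"post {p.post_id} references unknown user {p.user_id}"
                )
            if self.window is not None and not (
                self.window[0] <= p.day <= self.window[1]
            ):
                raise StreamFormatError(
                    f"post {p.post_id} day {p.day} outside window {self.window}"
                )


def _post_from_record(rec: Mapping, lineno: int) -> tuple[Post, UserAccount | None]:
    try:
        post_id = rec["id_str"]
        text = rec["full_text"]
        day = date.fromisoformat(rec["created_at"][:10])
        lang = rec.get("lang", "en")
    except (KeyError, ValueError, TypeError) as exc:
        raise StreamFormatError(f"line {lineno}: bad or missing field ({exc})") from exc
    user = None
    if "user" in rec:
        u = rec["user"]
        try:
            user = UserAccount(
                user_id=u["id_str"],
                screen_name=u.get("screen_name", ""),
                description=u.get("description", "") or "",
                verified=bool(u.get("verified", False)),
                followers=int(u.get("followers_count", 0)),
            )
        except (KeyError, TypeError) as exc:
            raise StreamFormatError(f"line {lineno}: bad user object ({exc})") from exc
        user_id = user.user_id
    else:
        user_id = rec.get("user_id_str")
        if user_id is None:
            raise StreamFormatError(f"line {lineno}: no user object or user_id_str")
    rt = rec.get("retweeted_status")
    retweet_of = rt["id_str"] if isinstance(rt, Mapping) else rt
    try:
        post = Post(
            post_id=post_id,
            text=text,
            day=day,
            lang=lang,
            user_id=user_id,
            retweet_of=retweet_of,
            in_reply_to=rec.get("in_reply_to_status_id_str"),
            reply_count=int(rec.get("reply_count", 0)),
            retweet_count=int(rec.get("retweet_count", 0)),
            like_count=int(rec.get("favorite_count", 0)),
        )
    except StreamFormatError as exc:
        raise StreamFormatError(f"line {lineno}: {exc}") from exc
    return post, user


def read_stream(path: str | Path, window: tuple[date, date] | None = None) -> Stream:
    """Read a JSONL stream file.

    Users are deduplicated by ``user_id`` with the last record winning.
    The window defaults to ``[min day, max day]`` of the posts; an empty
    file yields an empty stream with an undefined (``None``) window.
    A malformed line, or a post with neither an embedded user object nor a
    previously seen ``user_id_str``, is a hard error naming the line.
    """
    path = Path(path)
    posts: list[Post] = []
    users: dict[str, UserAccount] = {}
    seen_ids: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamFormatError(f"line {lineno}: malformed JSON ({exc})") from exc
            if not isinstance(rec, Mapping):
                raise StreamFormatError(f"line {lineno}: not a JSON object")
            post, user = _post_from_record(rec, lineno)
            if user is not None:
                users[user.user_id] = user
            elif post.user_id not in users:
                raise StreamFormatError(
                    f"line {lineno}: post {post.post_id} references unknown "
                    f"user {post.user_id} and embeds no user object"
                )
            if post.post_id in seen_ids:
                raise StreamFormatError(
                    f"line {lineno}: duplicate post_id {post.post_id}"
                )
            seen_ids.add(post.post_id)
            posts.append(post)
    if not posts:
        logger.warning("empty stream %s: window undefined", path)
        return Stream(posts=[], users=users, window=None)
    if window is None:
        days = [p.day for p in posts]
        window = (min(days), max(days))
    stream = Stream(posts=posts, users=users, window=window)
    stream.validate()
    return stream


def write_stream(stream: Stream, path: str | Path) -> None:
    """Write a stream back to the JSONL dialect (round-trips read_stream)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in stream.posts:
            u = stream.users[p.user_id]
            rec: dict = {
                "id_str": p.post_id,
                "full_text": p.text,
                "created_at": p.day.isoformat(),
                "lang": p.lang,
                "user": {
                    "id_str": u.user_id,
                    "screen_name": u.screen_name,
                    "description": u.description,
                    "verified": u.verified,
                    "followers_count": u.followers,
                },
                "reply_count": p.reply_count,
                "retweet_count": p.retweet_count,
                "favorite_count": p.like_count,
            }
            if p.retweet_of is not None:
                rec["retweeted_status"] = {"id_str": p.retweet_of}
            if p.in_reply_to is not None:
                rec["in_reply_to_status_id_str"] = p.in_reply_to
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Normalization used for duplicate detection: lowercase, strip URLs,
    collapse whitespace."""
    text = _URL_RE.sub(" ", text.lower())
    return _WS_RE.sub(" ", text).strip()


def dedup_texts(stream: Stream) -> tuple[Stream, dict[str, str]]:
    """Collapse posts with identical normalized text.

    The canonical post for each text is the earliest by ``(day, post_id)``.
    Returns the deduplicated stream (original order preserved) and a map
    from every removed post_id to its canonical post_id, so that
    ``|unique| + |dup_map| == |posts|``.
    """
    if not stream.posts:
        raise ValueError("dedup_texts: empty stream")
    canonical: dict[str, Post] = {}
    for p in sorted(stream.posts, key=lambda p: (p.day, p.post_id)):
        key = normalize_text(p.text)
        if key not in canonical:
            canonical[key] = p
    keep_ids = {p.post_id for p in canonical.values()}
    dup_map = {
        p.post_id: canonical[normalize_text(p.text)].post_id
        for p in stream.posts
        if p.post_id not in keep_ids
    }
    unique = Stream(
        posts=[p for p in stream.posts if p.post_id in keep_ids],
        users=dict(stream.users),
        window=stream.window,
    )
    return unique, dup_map


def split_retweets(stream: Stream) -> tuple[Stream, Stream]:
    """Partition a stream into original posts and retweets.

    A post is a retweet iff ``retweet_of`` is set.  Retweets pointing at a
    post outside the stream are kept and logged as dangling, never dropped.
    """
    originals = [p for p in stream.posts if not p.is_retweet]
    retweets = [p for p in stream.posts if p.is_retweet]
    known = {p.post_id for p in stream.posts}
    dangling = [p.post_id for p in retweets if p.retweet_of not in known]
    if dangling:
        logger.warning(
            "%d retweets reference posts outside the stream (e.g. %s)",
            len(dangling), dangling[:3],
        )
    mk = lambda posts: Stream(posts=posts, users=dict(stream.users), window=stream.window)
    return mk(originals), mk(retweets)


def keyword_filter(stream: Stream, keywords: Iterable[str]) -> Stream:
    """Keep posts whose tokens match at least one keyword.

    Single-word keywords match any token; multiword keywords (e.g. a
    two-word condition name) match as contiguous token n-grams.
    """
    from . import textmetrics  # local import to avoid a cycle

    keywords = {k.lower() for k in keywords}
    if not keywords:
        raise ValueError("keyword_filter: empty keyword set")
    unigrams = {k for k in keywords if " " not in k}
    ngrams = [tuple(k.split()) for k in keywords if " " in k]

    def matches(post: Post) -> bool:
        toks = textmetrics.tokenize(post.text, post.lang).tokens
        if unigrams.intersection(toks):
            return True
        for ng in ngrams:
            n = len(ng)
            for i in range(len(toks) - n + 1):
                if tuple(toks[i : i + n]) == ng:
                    return True
        return False

    kept = [p for p in stream.posts if matches(p)]
    return Stream(posts=kept, users=dict(stream.users), window=stream.window)


def write_dup_map(dup_map: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("post_id\tcanonical_post_id\n")
        for k in sorted(dup_map):
            fh.write(f"{k}\t{dup_map[k]}\n")
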