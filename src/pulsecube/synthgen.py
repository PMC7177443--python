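"""Ground-truthed synthetic micro-blog streams.

Real keyword-collected health streams are not redistributable, so every
analysis module in this package is exercised against synthetic streams
whose structure is known exactly.  The generator emulates the salient
statistical features of such a stream:

* users of several archetypes — lay users, concerned people, health
  professionals, organizations, journalists, alternative-therapy accounts,
  plus the noise archetypes (bots with tiny vocabularies, spammers posting
  one template text at scale, prolific out-of-domain accounts);
* planted **events**: short near-Gaussian daily bursts (width <= the
  event span threshold) of a few co-occurring name bigrams, each burst
  tall enough to clear the peak threshold;
* planted **topics**: bigrams (and two single-word themes) emitted at a
  sustained uniform daily rate across the window;
* noise bigrams too rare to qualify as either;
* heavy text duplication (copies of earlier posts, mirroring the high
  redundancy of keyword streams), retweets, replies, and first-person
  markers in two languages (en/es).

Human token streams are a mixture of one domain keyword per post, common
words drawn from a Zipf-weighted pool, and a long uniform tail of rare
words; the rare tail keeps the hapax mass high so that genuine users get
realistically high Yule's I while bots (10-word vocabulary) stay far
below the bot threshold.  All randomness flows from the mandatory config
seed, so identical configs produce byte-identical streams.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .profiling import PROFILE_SEED_VOCAB, LabelledUser
from .stream_io import Post, Stream, UserAccount

Term = tuple[str, ...]

__all__ = [
    "EventSpec",
    "TopicSpec",
    "SynthConfig",
    "GroundTruth",
    "generate_stream",
    "small_fixture",
    "generate_profile_descriptions",
    "make_planted_cooccurrence_graph",
    "DEFAULT_UNIGRAM_WHITELIST",
    "DOMAIN_KEYWORDS",
    "write_domain_lexicon",
]

# ---------------------------------------------------------------- vocabularies

#: Stream collection keywords (conditions, treatments, observations).
DOMAIN_KEYWORDS: tuple[str, ...] = (
    "cancer", "tumor", "carcinoma", "leukemia", "lymphoma", "metastasis",
    "sarcoma", "melanoma", "chemotherapy", "homeopathy", "uv", "cholesterol",
    "ldl", "mri",
)

#: Broader medical vocabulary used as post filler and as the domain lexicon.
DOMAIN_VOCAB: tuple[str, ...] = DOMAIN_KEYWORDS + (
    "diagnosis", "therapy", "oncology", "patient", "treatment", "screening",
    "biopsy", "relapse", "remission", "prevention", "awareness", "symptoms",
    "hospital", "clinic", "trial", "drug", "vaccine", "surgery", "radiation",
    "immunotherapy", "survival", "tumour", "cells", "research", "doctors",
    "nurses", "risk", "diet", "sunscreen", "checkup",
)

_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu ka ke ki ko "
    "ku la le li lo lu ma mo mu na ne nu pa pe pi po pu ra re ri ro ru sa se "
    "si so su ta te ti to tu va ve vi vo vu za ze zi zo zu"
).split()


def _pseudo_words(n: int, rng: np.random.Generator, n_syllables: int = 3) -> list[str]:
    """Deterministic pronounceable pseudo-words, unique, >= 3 syllables so
    they can never collide with stopwords or markers."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        w = "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


# Module-level pools, fixed independently of any stream seed.
_POOL_RNG = np.random.default_rng(190_206)
#: Common conversational background (Zipf-weighted).
BACKGROUND_COMMON: list[str] = _pseudo_words(4000, _POOL_RNG)
#: Long uniform tail of rare words (drives hapax mass / Yule's I).
RARE_POOL: list[str] = _pseudo_words(20000, _POOL_RNG, n_syllables=4)
#: Out-of-domain conversational pool (disjoint from the above).
OFFDOMAIN_COMMON: list[str] = _pseudo_words(3000, _POOL_RNG)
#: Name-like words for event bigrams.
NAME_POOL: list[str] = [w.capitalize().lower() for w in _pseudo_words(200, _POOL_RNG)]

_ZIPF_S = 0.8
_BG_WEIGHTS = 1.0 / np.arange(1, len(BACKGROUND_COMMON) + 1) ** _ZIPF_S
_BG_WEIGHTS /= _BG_WEIGHTS.sum()
_OD_WEIGHTS = 1.0 / np.arange(1, len(OFFDOMAIN_COMMON) + 1) ** _ZIPF_S
_OD_WEIGHTS /= _OD_WEIGHTS.sum()

#: Sustained discussion themes planted by the default config.
DEFAULT_TOPIC_TERMS: tuple[Term, ...] = (
    ("skin", "cancer"), ("brain", "tumor"), ("lung", "cancer"),
    ("breast", "cancer"), ("prostate", "cancer"), ("bone", "marrow"),
    ("stem", "cell"), ("clinical", "trial"), ("early", "detection"),
    ("sun", "protection"), ("tumor", "cerebral"), ("cancer", "mama"),
    ("cancer", "pancreas"), ("gene", "therapy"), ("immune", "system"),
    ("cervical", "cancer"), ("ovarian", "cancer"), ("childhood", "leukemia"),
    ("leukemia",), ("melanoma",),
)

#: Single-word themes tracked as degenerate unigram terms.
DEFAULT_UNIGRAM_WHITELIST: frozenset[str] = frozenset({"leukemia", "melanoma"})

_SPAM_PHRASES: tuple[tuple[str, ...], ...] = (
    ("miracle", "cure", "stops", "metastasis", "buy", "drops", "today"),
    ("secreto", "natural", "evita", "metastasis", "compra", "ahora"),
)

_FIRST_PERSON_PREFIX = {"en": ("i", "have"), "es": ("tengo",)}

_ARCHETYPE_PROFILE = {
    "lay": "others", "concerned": "concerned", "professional": "professional",
    "organization": "h.services", "journalist": "journalist", "pseudo": "pseudo",
    "student": "student", "bot": "others", "spammer": "others",
    "offdomain": "others",
}

_HUMAN_ARCHETYPES = ("lay", "concerned", "professional", "organization",
                     "journalist", "pseudo", "student")
_AUTHOR_WEIGHT = {"lay": 1.0, "concerned": 1.0, "professional": 1.2,
                  "organization": 2.0, "journalist": 2.0, "pseudo": 0.8,
                  "student": 0.8}


# ------------------------------------------------------------------- config

@dataclass(frozen=True)
class EventSpec:
    """One planted burst: all ``terms`` appear in every event post."""

    terms: tuple[Term, ...]
    peak_day: int  # offset from window start
    width: int = 5
    volume: int = 31  # unique posts in the burst
    topic: Term | None = None  # associated sustained theme
    topic_prob: float = 0.6  # fraction of event posts also carrying the topic
    min_peak: int = 20  # construction guarantee: peak-day count >= this


@dataclass(frozen=True)
class TopicSpec:
    """One sustained theme emitted at a uniform daily rate."""

    term: Term
    daily_rate: float = 1.1
    reply_prob: float | None = None  # override the stream-wide reply probability


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; the defaults define the standard synthetic
    study stream (90 days, 50 users, 10 events, 20 topics, 100 noise
    bigrams, ~60% duplicated texts, ~15% of posts from low-quality
    accounts)."""

    seed: int
    n_days: int = 90
    start_day: date = date(2019, 6, 1)
    users_per_archetype: Mapping[str, int] = field(
        default_factory=lambda: {
            "lay": 18, "concerned": 6, "professional": 4, "organization": 5,
            "journalist": 5, "pseudo": 3, "student": 2,
            "bot": 2, "spammer": 2, "offdomain": 3,
        }
    )
    n_events: int = 10
    events: tuple[EventSpec, ...] | None = None  # None -> auto-built
    topics: tuple[TopicSpec, ...] | None = None  # None -> default 20 themes
    n_noise_bigrams: int = 100
    noise_max_posts: int = 10
    background_posts: int = 1700
    duplicate_factor: float = 1.5  # mean copies per unique human post
    retweet_rate: float = 0.35  # mean retweets per human original
    reply_prob: float = 0.15
    first_person_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "lay": 0.30, "concerned": 0.50, "professional": 0.05,
            "organization": 0.02, "journalist": 0.02, "pseudo": 0.10,
            "student": 0.20,
        }
    )
    lang_mix: Mapping[str, float] = field(
        default_factory=lambda: {"en": 0.75, "es": 0.25}
    )
    bot_posts: int = 350
    spammer_posts: int = 250
    offdomain_posts: int = 200
    rare_word_frac: float = 0.3  # share of human filler tokens from RARE_POOL

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SynthConfig.seed is mandatory")
        for p in (self.reply_prob, self.rare_word_frac, *self.lang_mix.values(),
                  *self.first_person_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.events:
            for ev in self.events:
                if ev.width > 10:
                    raise ValueError("event width must be <= the 10-day span cap")


@dataclass
class GroundTruth:
    """Planted structure of a generated stream."""

    event_terms: dict[Term, int]  # term -> event index
    topic_terms: dict[Term, int]
    noise_terms: set[Term]
    user_archetype: dict[str, str]
    intended_band: dict[str, str]  # user_id -> good|filtered
    intended_profile: dict[str, str]
    post_flags: dict[str, dict]  # post_id -> {first_person, duplicate_of, ...}

    def to_json_dict(self) -> dict:
        return {
            "event_terms": {" ".join(t): i for t, i in self.event_terms.items()},
            "topic_terms": {" ".join(t): i for t, i in self.topic_terms.items()},
            "noise_terms": sorted(" ".join(t) for t in self.noise_terms),
            "user_archetype": self.user_archetype,
            "intended_band": self.intended_band,
            "intended_profile": self.intended_profile,
            "post_flags": self.post_flags,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))


# ---------------------------------------------------------------- generation

def _default_events(rng: np.random.Generator, cfg: SynthConfig) -> tuple[EventSpec, ...]:
    names = list(NAME_POOL)
    rng.shuffle(names)
    it = iter(names)
    topics = [t.term for t in (cfg.topics or ())] or list(DEFAULT_TOPIC_TERMS)
    events = []
    lo, hi = 8, cfg.n_days - 8
    peak_days = sorted(rng.choice(np.arange(lo, hi), size=cfg.n_events, replace=False))
    for i in range(cfg.n_events):
        terms = tuple(
            (next(it), next(it)) for _ in range(3)
        )
        events.append(
            EventSpec(
                terms=terms,
                peak_day=int(peak_days[i]),
                width=5,
                volume=31,
                topic=tuple(topics[i % len(topics)]),
            )
        )
    return tuple(events)


def _human_filler(rng: np.random.Generator, cfg: SynthConfig, n: int) -> list[str]:
    """Filler tokens for in-domain human posts: one collection keyword plus
    a Zipf common / uniform rare mixture."""
    toks = [str(rng.choice(DOMAIN_KEYWORDS))]
    for _ in range(n):
        if rng.random() < cfg.rare_word_frac:
            toks.append(RARE_POOL[int(rng.integers(len(RARE_POOL)))])
        else:
            toks.append(BACKGROUND_COMMON[int(rng.choice(len(_BG_WEIGHTS), p=_BG_WEIGHTS))])
    rng.shuffle(toks)
    return toks


def _insert_units(rng: np.random.Generator, filler: list[str],
                  units: Sequence[Sequence[str]]) -> list[str]:
    """Insert multi-word units into random gaps of the filler, keeping
    every unit contiguous (units never split each other; co-inserted units
    at the same gap are merely adjacent, which is rare)."""
    gaps = rng.integers(0, len(filler) + 1, size=len(units))
    out: list[str] = []
    for gap in range(len(filler) + 1):
        for unit, g in zip(units, gaps):
            if g == gap:
                out.extend(unit)
        if gap < len(filler):
            out.append(filler[gap])
    return out


def generate_stream(config: SynthConfig) -> tuple[Stream, GroundTruth]:
    """Generate a stream and its ground truth; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    topics = cfg.topics
    if topics is None:
        topics = tuple(
            TopicSpec(term=t, daily_rate=1.1,
                      reply_prob=0.45 if t == ("skin", "cancer") else None)
            for t in DEFAULT_TOPIC_TERMS
        )
    events = cfg.events if cfg.events is not None else _default_events(rng, cfg)

    # ---- users
    users: dict[str, UserAccount] = {}
    archetype: dict[str, str] = {}
    intended_band: dict[str, str] = {}
    intended_profile: dict[str, str] = {}
    user_lang: dict[str, str] = {}
    langs = list(cfg.lang_mix)
    lang_p = np.array([cfg.lang_mix[l] for l in langs], dtype=float)
    lang_p /= lang_p.sum()
    uid_counter = itertools.count(1)
    org_split = itertools.cycle(["h.services", "p.services"])
    for arch, n in cfg.users_per_archetype.items():
        for _ in range(n):
            uid = f"u{next(uid_counter):04d}"
            profile = _ARCHETYPE_PROFILE.get(arch, "others")
            if arch == "organization":
                profile = next(org_split)
            vocab = PROFILE_SEED_VOCAB[profile]
            if arch in ("bot", "spammer"):
                desc = ""
            else:
                k = min(4, len(vocab))
                words = list(rng.choice(vocab, size=k, replace=False))
                words += [BACKGROUND_COMMON[int(rng.integers(300))] for _ in range(2)]
                desc = " ".join(words)
            verified = bool(
                rng.random() < (0.7 if arch in ("organization", "journalist") else 0.02)
            )
            users[uid] = UserAccount(
                user_id=uid,
                screen_name=f"{arch}_{uid}",
                description=desc,
                verified=verified,
                followers=int(rng.lognormal(6.0, 1.5)),
            )
            archetype[uid] = arch
            intended_profile[uid] = profile if desc else "others"
            noise_volume = {"bot": cfg.bot_posts, "spammer": cfg.spammer_posts,
                            "offdomain": cfg.offdomain_posts}.get(arch, 0)
            # noise accounts are only *intended* to be caught once their
            # volume clears the high-volume prong of the band rules
            intended_band[uid] = "filtered" if noise_volume >= 100 else "good"
            user_lang[uid] = "en" if arch in ("bot", "spammer") else (
                langs[int(rng.choice(len(langs), p=lang_p))]
            )

    humans = [u for u, a in archetype.items() if a in _HUMAN_ARCHETYPES]
    if not humans:
        raise ValueError("config implies zero human users")
    hw = np.array([_AUTHOR_WEIGHT[archetype[u]] for u in humans], dtype=float)
    hw /= hw.sum()

    def pick_author() -> str:
        return humans[int(rng.choice(len(humans), p=hw))]

    # ---- plan unique human posts as (author, day, tokens, planted tag)
    drafts: list[dict] = []

    def add_draft(author: str, day_off: int, tokens: list[str], planted: str,
                  reply_prob: float | None = None) -> None:
        drafts.append(
            dict(author=author, day=day_off, tokens=tokens, planted=planted,
                 reply_prob=reply_prob)
        )

    # events: truncated discrete Gaussian bursts
    event_terms: dict[Term, int] = {}
    for i, ev in enumerate(events):
        for t in ev.terms:
            event_terms[t] = i
        half = ev.width // 2
        offsets = np.arange(-half, ev.width - half)
        shape = np.exp(-(offsets.astype(float) ** 2) / (2 * max(ev.width / 4.0, 0.8) ** 2))
        shape /= shape.sum()
        day_counts = rng.multinomial(ev.volume, shape)
        top = int(np.argmax(day_counts))
        if day_counts[top] < ev.min_peak:  # honour the burst-height guarantee
            day_counts[top] = ev.min_peak
        for off, k in zip(offsets, day_counts):
            d = min(max(ev.peak_day + int(off), 0), cfg.n_days - 1)
            for _ in range(int(k)):
                units: list[Sequence[str]] = [list(t) for t in ev.terms]
                if ev.topic is not None and rng.random() < ev.topic_prob:
                    units.append(list(ev.topic))
                toks = _insert_units(rng, _human_filler(rng, cfg, 7), units)
                add_draft(pick_author(), d, toks, f"event:{i}")

    # topics: uniform daily rates
    topic_terms: dict[Term, int] = {}
    for j, tp in enumerate(topics):
        topic_terms[tp.term] = j
        counts = rng.poisson(tp.daily_rate, size=cfg.n_days)
        for d in range(cfg.n_days):
            for _ in range(int(counts[d])):
                toks = _insert_units(rng, _human_filler(rng, cfg, 7), [list(tp.term)])
                add_draft(pick_author(), d, toks, f"topic:{j}",
                          reply_prob=tp.reply_prob)

    # background chatter, carrying the planted noise bigrams
    noise_pool = BACKGROUND_COMMON[500:500 + 4 * cfg.n_noise_bigrams]
    noise_terms: set[Term] = set()
    while len(noise_terms) < cfg.n_noise_bigrams:
        a, b = rng.choice(noise_pool, size=2, replace=False)
        noise_terms.add((str(a), str(b)))
    noise_slots: list[Term | None] = []
    for t in sorted(noise_terms):
        noise_slots.extend([t] * int(rng.integers(2, cfg.noise_max_posts + 1)))
    noise_slots.extend([None] * max(cfg.background_posts - len(noise_slots), 0))
    rng.shuffle(noise_slots)  # type: ignore[arg-type]
    for slot in noise_slots:
        d = int(rng.integers(cfg.n_days))
        filler = _human_filler(rng, cfg, 7)
        toks = _insert_units(rng, filler, [list(slot)]) if slot else filler
        add_draft(pick_author(), d, toks, "noise" if slot else "background")

    # ---- low-quality archetypes
    bot_vocabs = {
        u: _pseudo_words(10, np.random.default_rng(cfg.seed + 7919 + i))
        for i, u in enumerate(u for u, a in archetype.items() if a == "bot")
    }
    for u, vocab in bot_vocabs.items():
        for _ in range(cfg.bot_posts):
            toks = [vocab[int(rng.integers(10))] for _ in range(8)]
            add_draft(u, int(rng.integers(cfg.n_days)), toks, "bot")
    for i, u in enumerate(u for u, a in archetype.items() if a == "spammer"):
        phrase = list(_SPAM_PHRASES[i % len(_SPAM_PHRASES)])
        for _ in range(cfg.spammer_posts):
            add_draft(u, int(rng.integers(cfg.n_days)), list(phrase), "spam")
    for u in (u for u, a in archetype.items() if a == "offdomain"):
        for _ in range(cfg.offdomain_posts):
            toks = []
            for _ in range(8):
                if rng.random() < cfg.rare_word_frac:
                    toks.append(RARE_POOL[int(rng.integers(len(RARE_POOL)))])
                else:
                    toks.append(
                        OFFDOMAIN_COMMON[int(rng.choice(len(_OD_WEIGHTS), p=_OD_WEIGHTS))]
                    )
            add_draft(u, int(rng.integers(cfg.n_days)), toks, "offdomain")

    if not drafts:
        raise ValueError("config implies zero posts")

    # ---- duplicates: copies of unique human posts (same text, same day)
    human_idx = [k for k, dr in enumerate(drafts)
                 if archetype[dr["author"]] in _HUMAN_ARCHETYPES]
    copies: list[tuple[int, str]] = []  # (source draft index, copying author)
    for k in human_idx:
        for _ in range(int(rng.poisson(cfg.duplicate_factor))):
            copies.append((k, pick_author()))

    # ---- materialize posts
    posts: list[Post] = []
    post_flags: dict[str, dict] = {}
    pid_counter = itertools.count(1)
    window = (cfg.start_day, cfg.start_day + timedelta(days=cfg.n_days - 1))

    def emit(author: str, day_off: int, tokens: list[str], planted: str,
             reply_to: str | None, duplicate_of: str | None,
             first_person: bool) -> Post:
        lang = user_lang[author]
        toks = list(tokens)
        if first_person:
            toks = list(_FIRST_PERSON_PREFIX[lang]) + toks
        pid = f"p{next(pid_counter):06d}"
        post = Post(
            post_id=pid,
            text=" ".join(toks),
            day=cfg.start_day + timedelta(days=day_off),
            lang=lang,
            user_id=author,
            in_reply_to=reply_to,
        )
        posts.append(post)
        post_flags[pid] = {
            "planted": planted,
            "first_person": first_person,
            "duplicate_of": duplicate_of,
            "reply": reply_to is not None,
        }
        return post

    draft_posts: list[Post] = []
    order = sorted(range(len(drafts)), key=lambda k: drafts[k]["day"])
    emitted_ids: list[str] = []
    for k in order:
        dr = drafts[k]
        arch = archetype[dr["author"]]
        fp = (arch in cfg.first_person_prob
              and rng.random() < cfg.first_person_prob[arch])
        rp = dr["reply_prob"] if dr["reply_prob"] is not None else cfg.reply_prob
        reply_to = None
        if arch in _HUMAN_ARCHETYPES and emitted_ids and rng.random() < rp:
            reply_to = emitted_ids[int(rng.integers(len(emitted_ids)))]
        post = emit(dr["author"], dr["day"], dr["tokens"], dr["planted"],
                    reply_to, None, fp)
        emitted_ids.append(post.post_id)
        dr["post_id"] = post.post_id
        dr["first_person"] = fp
        draft_posts.append(post)

    by_draft_pid = {dr["post_id"]: p for dr, p in zip(
        (drafts[k] for k in order), draft_posts)}
    for k, author in copies:
        dr = drafts[k]
        src = by_draft_pid[dr["post_id"]]
        pid = f"p{next(pid_counter):06d}"
        # verbatim text copy: same text, language and day as the source
        posts.append(Post(post_id=pid, text=src.text, day=src.day,
                          lang=src.lang, user_id=author))
        post_flags[pid] = {
            "planted": dr["planted"] + ":copy",
            "first_person": dr.get("first_person", False),
            "duplicate_of": src.post_id,
            "reply": False,
        }

    # ---- retweets of human originals
    human_posts = [p for p in posts
                   if archetype[p.user_id] in _HUMAN_ARCHETYPES]
    all_uids = list(users)
    retweet_counts: dict[str, int] = {}
    for src in human_posts:
        n_rt = int(rng.poisson(cfg.retweet_rate))
        for _ in range(n_rt):
            rt_author = all_uids[int(rng.integers(len(all_uids)))]
            pid = f"p{next(pid_counter):06d}"
            posts.append(
                Post(
                    post_id=pid,
                    text=src.text,
                    day=min(src.day + timedelta(days=int(rng.integers(0, 3))),
                            window[1]),
                    lang=src.lang,
                    user_id=rt_author,
                    retweet_of=src.post_id,
                )
            )
            post_flags[pid] = {"planted": "retweet", "first_person": False,
                               "duplicate_of": None, "reply": False}
        if n_rt:
            retweet_counts[src.post_id] = n_rt

    posts = [
        p if p.post_id not in retweet_counts
        else Post(**{**p.__dict__, "retweet_count": retweet_counts[p.post_id]})
        for p in posts
    ]
    posts.sort(key=lambda p: (p.day, p.post_id))
    stream = Stream(posts=posts, users=users, window=window)
    stream.validate()
    truth = GroundTruth(
        event_terms=event_terms,
        topic_terms=topic_terms,
        noise_terms=noise_terms,
        user_archetype=archetype,
        intended_band=intended_band,
        intended_profile=intended_profile,
        post_flags=post_flags,
    )
    return stream, truth


# ------------------------------------------------------------------ fixtures

def small_fixture() -> tuple[Stream, GroundTruth]:
    """A deterministic ~200-post, 10-user, 30-day, two-language stream with
    one planted event, two topics, one bot and one out-of-domain user.
    Used by unit tests and the documentation examples."""
    cfg = SynthConfig(
        seed=42,
        n_days=30,
        users_per_archetype={
            "lay": 4, "concerned": 1, "journalist": 1, "organization": 1,
            "professional": 1, "bot": 1, "offdomain": 1,
        },
        n_events=1,
        events=(
            EventSpec(
                terms=(("dana", "rivas"), ("rivas", "verdict")),
                peak_day=12, width=3, volume=26, topic=("skin", "cancer"),
            ),
        ),
        topics=(
            TopicSpec(term=("skin", "cancer"), daily_rate=0.8),
            TopicSpec(term=("leukemia",), daily_rate=0.8),
        ),
        n_noise_bigrams=5,
        noise_max_posts=3,
        background_posts=12,
        duplicate_factor=0.0,
        retweet_rate=0.12,
        reply_prob=0.15,
        bot_posts=100,
        offdomain_posts=6,
    )
    return generate_stream(cfg)


def generate_profile_descriptions(
    n_per_class: int, seed: int, noise_fraction: float = 0.3,
    labels: Sequence[str] | None = None,
) -> list[LabelledUser]:
    """Labelled synthetic account descriptions: words from each profile's
    seed vocabulary mixed with common background noise words."""
    if not 0.0 <= noise_fraction <= 0.5:
        raise ValueError("noise_fraction must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    labels = tuple(labels) if labels is not None else tuple(PROFILE_SEED_VOCAB)
    out: list[LabelledUser] = []
    i = 0
    for label in labels:
        vocab = PROFILE_SEED_VOCAB[label]
        for _ in range(n_per_class):
            n_words = int(rng.integers(5, 9))
            words = []
            for _ in range(n_words):
                if rng.random() < noise_fraction:
                    words.append(BACKGROUND_COMMON[int(rng.integers(300))])
                else:
                    words.append(str(rng.choice(vocab)))
            i += 1
            out.append(LabelledUser(user_id=f"lu{i:05d}",
                                    description=" ".join(words), label=label))
    return out


def make_planted_cooccurrence_graph(
    n_groups: int = 5, nodes_per_group: int = 8, seed: int = 0,
    within_weight: float = 8.0, p_between: float = 0.02,
) -> tuple[nx.Graph, dict[str, int]]:
    """A weighted graph with a planted community structure, shaped like a
    term co-occurrence graph: dense heavy edges within each planted group,
    sparse unit-weight edges between groups.  Returns (graph, node->group).
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    membership: dict[str, int] = {}
    groups: list[list[str]] = []
    for gi in range(n_groups):
        nodes = [f"t{gi}_{k}" for k in range(nodes_per_group)]
        groups.append(nodes)
        for n in nodes:
            membership[n] = gi
            g.add_node(n)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                if rng.random() < 0.8:
                    g.add_edge(a, b, weight=float(1 + rng.poisson(within_weight)))
    for gi in range(n_groups):
        for gj in range(gi + 1, n_groups):
            for a in groups[gi]:
                for b in groups[gj]:
                    if rng.random() < p_between:
                        g.add_edge(a, b, weight=1.0)
    return g, membership


def write_domain_lexicon(path: str | Path, extra_weight: float = 3.0) -> None:
    """Write the built-in medical vocabulary as a term<TAB>weight TSV domain
    lexicon (collection keywords get ``extra_weight``, the rest weight 1)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for term in DOMAIN_VOCAB:
            w = extra_weight if term in DOMAIN_KEYWORDS else 1.0
            fh.write(f"{term}\t{w}\n")
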