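"""Event and topic detection from bigram temporal distributions.

Every candidate term (an adjacent word pair, plus a few whitelisted
single-word themes) gets a daily occurrence series over the stream window.
The shape of that series separates two kinds of discussion:

* an **event** is a short, tall burst — high excess kurtosis of the daily
  series (>= 10 by default), a peak of at least 20 occurrences in one day,
  and a first-to-last-day span of at most 10 days;
* a **topic** is a sustained theme — frequent overall (>= 20 occurrences)
  but *not* burst-shaped.

Kurtosis is computed over the full daily series including zero days with
population (biased) moments, so an isolated spike in a long window scores
very high (a single-spike series of length n behaves like a scaled
Bernoulli(1/n), whose excess kurtosis is (1-6pq)/(pq)) while a uniform
daily rate scores near zero.

Selected terms co-occur inside the posts that discuss the same real-world
happening, so they are clustered by greedy modularity maximization
(Louvain) on the weighted co-occurrence graph; each community becomes one
event or topic group.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from . import textmetrics
from .stream_io import Stream

Term = tuple[str, ...]

__all__ = [
    "DailySeries",
    "BigramStats",
    "EventThresholds",
    "TermGroup",
    "daily_series",
    "series_kurtosis",
    "compute_bigram_stats",
    "select_event_bigrams",
    "select_topic_bigrams",
    "cooccurrence_graph",
    "modularity",
    "cluster_terms",
    "assign_posts",
]


@dataclass(frozen=True)
class DailySeries:
    """Occurrence counts for one term, one entry per day in the window."""

    window: tuple[date, date]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        n_days = (self.window[1] - self.window[0]).days + 1
        if len(self.counts) != n_days:
            raise ValueError(
                f"series length {len(self.counts)} != window length {n_days}"
            )


@dataclass(frozen=True)
class BigramStats:
    """Temporal summary of one term over the stream window."""

    term: Term
    total: int
    peak: int
    span: int  # days between first and last occurrence, inclusive; 0 if absent
    kurtosis: float


@dataclass(frozen=True)
class EventThresholds:
    """Selection thresholds for the event/topic classifiers.

    ``min_peak`` is the minimum burst height: reported events carry
    hundreds to thousands of posts, so a term must reach at least 20
    occurrences on its peak day to qualify.
    """

    min_kurtosis: float = 10.0
    min_peak: int = 20
    max_span_days: int = 10
    topic_min_total: int = 20

    def __post_init__(self) -> None:
        if min(self.min_kurtosis, self.min_peak, self.max_span_days,
               self.topic_min_total) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class TermGroup:
    """A cluster of terms labelled as an event or a topic."""

    group_id: str
    kind: str  # "event" | "topic"
    terms: frozenset[Term]
    post_ids: set[str] = field(default_factory=set)


def _post_terms(
    stream: Stream, unigram_whitelist: frozenset[str] = frozenset()
) -> list[tuple[str, date, Counter]]:
    """(post_id, day, term multiset) for every post."""
    out = []
    for p in stream.posts:
        toks = textmetrics.tokenize(p.text, p.lang)
        out.append((p.post_id, p.day, textmetrics.extract_bigrams(toks, unigram_whitelist)))
    return out


def daily_series(
    stream: Stream,
    term: Term,
    window: tuple[date, date] | None = None,
    unigram_whitelist: frozenset[str] = frozenset(),
) -> DailySeries:
    """Daily occurrence counts of one term; a post contributes once per
    occurrence of the term in its text."""
    window = window or stream.window
    if window is None:
        raise ValueError("daily_series: no window")
    n_days = (window[1] - window[0]).days + 1
    counts = [0] * n_days
    for _pid, day, terms in _post_terms(stream, unigram_whitelist):
        c = terms.get(term, 0)
        if c:
            counts[(day - window[0]).days] += c
    return DailySeries(window=window, counts=tuple(counts))


def series_kurtosis(series: DailySeries | Sequence[int]) -> float:
    """Population excess kurtosis g2 = m4/m2^2 - 3 of the daily counts.

    Zero-variance series score 0 by convention.  Raises on length < 2.
    """
    x = np.asarray(series.counts if isinstance(series, DailySeries) else series,
                   dtype=float)
    if x.size < 2:
        raise ValueError("kurtosis needs a series of length >= 2")
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.kurtosis(x, fisher=True, bias=True))


def compute_bigram_stats(
    stream: Stream,
    window: tuple[date, date] | None = None,
    unigram_whitelist: frozenset[str] = frozenset(),
    min_total: int = 1,
) -> list[BigramStats]:
    """Temporal statistics for every term in the stream (vectorized).

    Central moments over the full daily vector (zero days included) are
    accumulated from raw power sums per term, so the per-term dense series
    never needs materializing.  ``min_total`` drops very rare terms early.
    """
    window = window or stream.window
    if window is None:
        raise ValueError("compute_bigram_stats: empty stream")
    n_days = (window[1] - window[0]).days + 1
    per_term: dict[Term, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for _pid, day, terms in _post_terms(stream, unigram_whitelist):
        d = (day - window[0]).days
        for t, c in terms.items():
            per_term[t][d] += c

    out: list[BigramStats] = []
    for term, day_counts in per_term.items():
        c = np.fromiter(day_counts.values(), dtype=float)
        total = int(c.sum())
        if total < min_total:
            continue
        days = list(day_counts.keys())
        span = max(days) - min(days) + 1
        peak = int(c.max())
        # population moments over the n_days-long series with implicit zeros
        mu = total / n_days
        m2 = (c**2).sum() / n_days - mu**2
        if m2 <= 0 or n_days < 2:
            g2 = 0.0
        else:
            m4 = (
                (c**4).sum()
                - 4 * mu * (c**3).sum()
                + 6 * mu**2 * (c**2).sum()
                - 4 * mu**3 * c.sum()
            ) / n_days + mu**4
            g2 = m4 / (m2 * m2) - 3.0
        out.append(BigramStats(term=term, total=total, peak=peak,
                               span=span, kurtosis=float(g2)))
    out.sort(key=lambda s: (-s.total, s.term))
    return out


def _is_event(s: BigramStats, th: EventThresholds) -> bool:
    return (s.kurtosis >= th.min_kurtosis and s.peak >= th.min_peak
            and s.span <= th.max_span_days)


def select_event_bigrams(
    stats: Iterable[BigramStats], th: EventThresholds = EventThresholds()
) -> set[Term]:
    """Burst-shaped terms: kurtosis >= 10, peak >= 20, span <= 10 days."""
    return {s.term for s in stats if _is_event(s, th)}


def select_topic_bigrams(
    stats: Iterable[BigramStats], th: EventThresholds = EventThresholds()
) -> set[Term]:
    """Frequent, sustained terms: total >= topic_min_total and not
    burst-shaped (a tall burst inside a sustained series still counts as a
    topic, so topics may contain their events)."""
    return {
        s.term
        for s in stats
        if s.total >= th.topic_min_total
        and not (s.kurtosis >= th.min_kurtosis and s.span <= th.max_span_days)
    }


def cooccurrence_graph(
    stream: Stream,
    terms: set[Term],
    unigram_whitelist: frozenset[str] = frozenset(),
) -> nx.Graph:
    """Weighted undirected graph on the selected terms; edge weight =
    number of posts containing both endpoints.  No self-loops; zero-weight
    edges absent.  Isolated selected terms stay as isolated nodes."""
    g = nx.Graph()
    g.add_nodes_from(sorted(terms))
    weights: Counter[tuple[Term, Term]] = Counter()
    for _pid, _day, post_terms in _post_terms(stream, unigram_whitelist):
        present = sorted(t for t in post_terms if t in terms)
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                weights[(a, b)] += 1
    for (a, b), w in weights.items():
        g.add_edge(a, b, weight=w)
    return g


def modularity(graph: nx.Graph, partition: Iterable[Iterable[Hashable]]) -> float:
    """Newman modularity Q = sum_c [ e_c/m - (d_c/2m)^2 ] of a node
    partition, with weighted edge mass m, within-community mass e_c and
    community degree d_c.  Raises on an edgeless graph and on a partition
    that is not a disjoint cover of the nodes."""
    parts = [set(c) for c in partition]
    covered: set = set()
    for c in parts:
        if covered & c:
            raise ValueError("partition communities overlap")
        covered |= c
    if covered != set(graph.nodes):
        raise ValueError("partition does not cover all nodes")
    m = graph.size(weight="weight")
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    degree = dict(graph.degree(weight="weight"))
    q = 0.0
    for c in parts:
        e_c = sum(
            d.get("weight", 1.0)
            for u, v, d in graph.edges(c, data=True)
            if u in c and v in c
        )
        d_c = sum(degree[u] for u in c)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def cluster_terms(
    graph: nx.Graph, seed: int = 0, kind: str = "event"
) -> tuple[list[TermGroup], float]:
    """Cluster terms into groups by greedy (Louvain-style) modularity
    maximization; deterministic for a fixed seed.

    Isolated nodes become singleton groups.  Returns the groups (stable
    ids ``{kind}_{i:03d}`` ordered by size then lexicographic first term)
    and the partition's modularity Q (0.0 for an edgeless graph).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cluster_terms: empty graph")
    if graph.number_of_edges() == 0:
        comms = [{n} for n in graph.nodes]
    else:
        comms = [set(c) for c in nx.community.louvain_communities(
            graph, weight="weight", seed=seed)]
    comms.sort(key=lambda c: (-len(c), min(c)))
    groups = [
        TermGroup(group_id=f"{kind}_{i:03d}", kind=kind, terms=frozenset(c))
        for i, c in enumerate(comms)
    ]
    q = modularity(graph, comms) if graph.number_of_edges() else 0.0
    return groups, q


def assign_posts(
    groups: Sequence[TermGroup],
    stream: Stream,
    unigram_whitelist: frozenset[str] = frozenset(),
) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Assign posts to every group owning a term they contain.

    Fills each group's ``post_ids`` in place and returns the mapping plus
    coverage fractions over the stream: posts in >= 1 event group, in
    >= 1 topic group, and the fraction of event posts also in a topic.
    """
    term_to_groups: dict[Term, list[str]] = defaultdict(list)
    by_id = {g.group_id: g for g in groups}
    for g in groups:
        for t in g.terms:
            term_to_groups[t].append(g.group_id)
    assignment: dict[str, set[str]] = {g.group_id: set() for g in groups}
    event_posts: set[str] = set()
    topic_posts: set[str] = set()
    n_posts = len(stream.posts)
    for pid, _day, post_terms in _post_terms(stream, unigram_whitelist):
        hit_groups: set[str] = set()
        for t in post_terms:
            hit_groups.update(term_to_groups.get(t, ()))
        for gid in hit_groups:
            assignment[gid].add(pid)
            if by_id[gid].kind == "event":
                event_posts.add(pid)
            else:
                topic_posts.add(pid)
    for g in groups:
        g.post_ids = assignment[g.group_id]
    coverage = {
        "event_fraction": len(event_posts) / n_posts if n_posts else 0.0,
        "topic_fraction": len(topic_posts) / n_posts if n_posts else 0.0,
        "event_topic_overlap": (
            len(event_posts & topic_posts) / len(event_posts) if event_posts else 0.0
        ),
    }
    return assignment, coverage
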