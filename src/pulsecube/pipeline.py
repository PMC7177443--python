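"""End-to-end orchestration: the standard analysis run over one stream.

Order of operations: split retweets from originals, compute user facts
and quality bands, drop posts of filtered users, then detect events and
topics on the cleaned originals, cluster the selected terms, assign posts
to groups and build the report rows.  Used by the command-line interface
and by reproduction scripts; each stage is also callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import cube, eventtopic, stream_io, synthgen
from .cube import GroupReport, QualityThresholds, UserFact
from .eventtopic import BigramStats, EventThresholds, TermGroup
from .profiling import ProfileModel
from .textmetrics import LanguageModel, model_from_weights


def default_domain_model() -> LanguageModel:
    """Domain model over the built-in medical vocabulary (collection
    keywords weighted 3x)."""
    weights = {
        t: (3.0 if t in synthgen.DOMAIN_KEYWORDS else 1.0)
        for t in synthgen.DOMAIN_VOCAB
    }
    return model_from_weights(weights)


@dataclass
class AnalysisResult:
    facts: dict[str, UserFact]
    removed_fraction: float
    originals: stream_io.Stream  # filtered originals used for detection
    retweets: stream_io.Stream
    stats: list[BigramStats]
    event_terms: set
    topic_terms: set
    event_groups: list[TermGroup]
    topic_groups: list[TermGroup]
    event_q: float
    topic_q: float
    coverage: dict[str, float]
    reports: list[GroupReport] = field(default_factory=list)


def run_analysis(
    stream: stream_io.Stream,
    domain_lm: LanguageModel | None = None,
    profile_model: ProfileModel | None = None,
    seed: int = 0,
    quality_th: QualityThresholds = QualityThresholds(),
    event_th: EventThresholds = EventThresholds(),
    unigram_whitelist: frozenset[str] = synthgen.DEFAULT_UNIGRAM_WHITELIST,
) -> AnalysisResult:
    domain_lm = domain_lm or default_domain_model()
    facts = cube.build_user_facts(stream, domain_lm, profile_model)
    cube.assign_quality_bands(facts, quality_th)
    clean, removed = cube.filter_stream(stream, facts)
    originals, retweets = stream_io.split_retweets(clean)

    stats = eventtopic.compute_bigram_stats(
        originals, unigram_whitelist=unigram_whitelist, min_total=2
    )
    ev_terms = eventtopic.select_event_bigrams(stats, event_th)
    tp_terms = eventtopic.select_topic_bigrams(stats, event_th)

    groups: list[TermGroup] = []
    ev_groups: list[TermGroup] = []
    tp_groups: list[TermGroup] = []
    ev_q = tp_q = 0.0
    if ev_terms:
        g = eventtopic.cooccurrence_graph(originals, ev_terms, unigram_whitelist)
        ev_groups, ev_q = eventtopic.cluster_terms(g, seed=seed, kind="event")
    if tp_terms:
        g = eventtopic.cooccurrence_graph(originals, tp_terms, unigram_whitelist)
        tp_groups, tp_q = eventtopic.cluster_terms(g, seed=seed, kind="topic")
    groups = ev_groups + tp_groups
    _, coverage = eventtopic.assign_posts(groups, originals, unigram_whitelist)

    reports = [
        cube.group_report(g, originals, retweets, facts)
        for g in groups
        if g.post_ids
    ]
    return AnalysisResult(
        facts=facts,
        removed_fraction=removed,
        originals=originals,
        retweets=retweets,
        stats=stats,
        event_terms=ev_terms,
        topic_terms=tp_terms,
        event_groups=ev_groups,
        topic_groups=tp_groups,
        event_q=ev_q,
        topic_q=tp_q,
        coverage=coverage,
        reports=reports,
    )
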