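"""Tokenization, unigram language models and user-quality text metrics.

Two per-user quality metrics drive the filtering of a surveillance stream:

* **Vocabulary diversity** — Yule's I, the inverse of Yule's
  characteristic K.  With ``M1`` the number of word types and
  ``M2 = sum_i i^2 * V_i`` over the frequency spectrum (``V_i`` = number of
  types occurring exactly ``i`` times),

      I = M1^2 / (M2 - M1).

  I is insensitive to text length, which matters because account volumes
  span four orders of magnitude.  Low I means repetitive, template-like
  text: automated accounts typically score below 30 while genuine human
  accounts score far higher.

* **Domain coherence** — the inner product of the user's unigram
  distribution with a domain (medical-term) distribution,
  ``sum_w P_user(w) * P_domain(w)``: the probability that one word drawn
  from each coincides.  It is zero iff the vocabularies are disjoint, so
  prolific but off-topic accounts score near zero.  Its magnitude scales
  inversely with the size of the domain lexicon.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TokenSequence",
    "FrequencySpectrum",
    "LanguageModel",
    "tokenize",
    "frequency_spectrum",
    "yules_i",
    "YULE_CAP",
    "build_language_model",
    "domain_coherence",
    "read_lexicon",
    "is_first_person",
    "extract_bigrams",
    "STOPWORDS",
    "FIRST_PERSON",
]

#: Reported value for Yule's I when every type occurs exactly once
#: (M2 == M1, I undefined/infinite).  Configurable at call sites.
YULE_CAP = 10_000.0

# Small built-in stopword lists; callers may pass their own.
STOPWORDS: dict[str, frozenset[str]] = {
    "en": frozenset(
        """a an the and or but if of in on at to for from by with about as is
        are was were be been being am do does did have has had will would can
        could should this that these those it its he she they them his her
        their we you your our us not no so than then there here what which who
        whom how when where why all any both each few more most other some
        such only own same too very just also after before during again once
        up down out off over under because until while rt via amp""".split()
    ),
    "es": frozenset(
        """el la los las un una unos unas y o pero si de del en a al por para
        con sin sobre entre como es son era eran ser estar fue fueron hay que
        cual quien cuando donde porque muy mas menos ya no ni lo le les se su
        sus mi mis tu tus nos os este esta estos estas ese esa esos esas aqui
        alli tambien hasta desde durante contra todo toda todos todas otro
        otra otros otras rt via""".split()
    ),
}

#: Per-language first-person marker lexicons (the stream carries en and es).
FIRST_PERSON: dict[str, frozenset[str]] = {
    "en": frozenset({"i", "i'm", "i've", "me", "my", "mine"}),
    "es": frozenset({"yo", "me", "mi", "mis", "estoy", "tengo", "tuve"}),
}

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
# A token is an @mention or a run of word characters (unicode, so accented
# Spanish words survive) with internal apostrophes ("i'm", "don't").
_TOKEN_RE = re.compile(r"@\w+|[\w']+", re.UNICODE)


@dataclass(frozen=True)
class TokenSequence:
    """Ordered lowercase word tokens from one text, tagged with language."""

    tokens: tuple[str, ...]
    lang: str = "en"

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str, lang: str = "en") -> TokenSequence:
    """Lowercase word tokens: URLs removed, ``@name`` kept whole,
    ``#tag`` kept as ``tag``, punctuation stripped, order preserved."""
    text = _URL_RE.sub(" ", text.lower()).replace("#", " ")
    toks = []
    for tok in _TOKEN_RE.findall(text):
        tok = tok.strip("'_")
        if tok and tok not in ("@",):
            toks.append(tok)
    return TokenSequence(tokens=tuple(toks), lang=lang)


@dataclass(frozen=True)
class FrequencySpectrum:
    """Word frequency spectrum: ``spectrum[i]`` = number of types seen
    exactly ``i`` times; M1 = #types, M2 = sum i^2*V_i, N = #tokens."""

    spectrum: Mapping[int, int]
    M1: int
    M2: int
    N: int


def frequency_spectrum(tokens: Iterable[str] | TokenSequence) -> FrequencySpectrum:
    counts = Counter(tokens.tokens if isinstance(tokens, TokenSequence) else tokens)
    spec = Counter(counts.values())
    m1 = sum(spec.values())
    m2 = sum(i * i * v for i, v in spec.items())
    n = sum(i * v for i, v in spec.items())
    return FrequencySpectrum(spectrum=dict(spec), M1=m1, M2=m2, N=n)


def yules_i(spec: FrequencySpectrum, cap: float | None = None) -> float:
    """Yule's I = M1^2 / (M2 - M1).

    When every type is a hapax (M2 == M1) the statistic diverges; returns
    ``math.inf``, or ``cap`` if given (reports use :data:`YULE_CAP`).
    Raises ValueError on an empty spectrum.
    """
    if spec.N == 0:
        raise ValueError("yules_i undefined for empty token sequence")
    denom = spec.M2 - spec.M1
    if denom == 0:
        return math.inf if cap is None else float(cap)
    return spec.M1 * spec.M1 / denom


@dataclass(frozen=True)
class LanguageModel:
    """A unigram distribution over words (probabilities sum to 1)."""

    probs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.probs:
            total = sum(self.probs.values())
            if any(p < 0 for p in self.probs.values()):
                raise ValueError("negative probability in language model")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"language model sums to {total}, not 1")

    def __len__(self) -> int:
        return len(self.probs)

    def top_words(self, k: int = 5) -> list[tuple[str, float]]:
        return sorted(self.probs.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def build_language_model(
    texts: Iterable[TokenSequence | Sequence[str]],
) -> LanguageModel:
    """Maximum-likelihood unigram model pooled over all token sequences.
    Empty input yields an empty model."""
    counts: Counter[str] = Counter()
    for seq in texts:
        counts.update(seq.tokens if isinstance(seq, TokenSequence) else seq)
    n = sum(counts.values())
    if n == 0:
        return LanguageModel(probs={})
    return LanguageModel(probs={w: c / n for w, c in counts.items()})


def model_from_weights(weights: Mapping[str, float]) -> LanguageModel:
    """Normalize arbitrary non-negative term weights into a LanguageModel."""
    total = sum(weights.values())
    if total <= 0:
        return LanguageModel(probs={})
    return LanguageModel(probs={w: v / total for w, v in weights.items()})


def domain_coherence(user_lm: LanguageModel, domain_lm: LanguageModel) -> float:
    """Inner product of the two unigram distributions over the shared
    vocabulary — the probability that independent draws coincide.

    Bounded by each model's collision probability (Cauchy–Schwarz); 0 iff
    the vocabularies are disjoint.  An empty user model scores 0.
    """
    if not user_lm.probs:
        import logging

        logging.getLogger(__name__).warning("empty user language model: coherence 0")
        return 0.0
    small, large = sorted((user_lm.probs, domain_lm.probs), key=len)
    return sum(p * large.get(w, 0.0) for w, p in small.items())


def read_lexicon(path: str | Path) -> LanguageModel:
    """Read a two-column ``term<TAB>weight`` TSV into a domain model.

    Multiword terms contribute their weight to each constituent unigram, so
    a two-word condition name still raises the coherence of users who write
    either word.  Weights are normalized to a distribution.
    """
    weights: Counter[str] = Counter()
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected term<TAB>weight")
            term, w = parts[0].lower(), float(parts[1])
            if w < 0:
                raise ValueError(f"{path}: line {lineno}: negative weight")
            for word in term.split():
                weights[word] += w
    return model_from_weights(weights)


def is_first_person(tokens: TokenSequence) -> bool:
    """True iff any token hits the language's first-person marker lexicon."""
    try:
        lexicon = FIRST_PERSON[tokens.lang]
    except KeyError:
        raise ValueError(f"unsupported language {tokens.lang!r}") from None
    return any(t in lexicon for t in tokens.tokens)


def extract_bigrams(
    tokens: TokenSequence,
    unigram_whitelist: frozenset[str] | set[str] = frozenset(),
    stopwords: frozenset[str] | None = None,
) -> Counter[tuple[str, ...]]:
    """Adjacent word pairs, skipping pairs touching a stopword or @mention.

    Whitelisted unigrams (a few unambiguous single-word themes) are
    additionally emitted as degenerate one-word terms.  Returns a multiset.
    """
    if stopwords is None:
        stopwords = STOPWORDS.get(tokens.lang, frozenset())
    out: Counter[tuple[str, ...]] = Counter()
    toks = tokens.tokens
    for a, b in zip(toks, toks[1:]):
        if a in stopwords or b in stopwords:
            continue
        if a.startswith("@") or b.startswith("@"):
            continue
        out[(a, b)] += 1
    if unigram_whitelist:
        for t in toks:
            if t in unigram_whitelist:
                out[(t,)] += 1
    return out
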