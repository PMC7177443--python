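"""User-profile classification from account self-descriptions.

Accounts introduce themselves in a short free-text description; those few
words are strongly indicative of the poster's role in a health stream
(care professionals mention their specialty, journalists their outlet,
concerned people their survivorship, alternative-therapy accounts their
practices).  A small feed-forward neural network over bag-of-words counts
(unigrams plus adjacent bigrams of the description) is trained on a
manually labelled user set and then predicts the profile of every incoming
account.  The closed profile vocabulary has eleven roles; accounts with an
empty description fall into ``others``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from . import textmetrics
from .textmetrics import LanguageModel, TokenSequence, build_language_model, tokenize

__all__ = [
    "PROFILE_LABELS",
    "PROFILE_SEED_VOCAB",
    "LabelledUser",
    "ProfileModel",
    "description_features",
    "train_profile_classifier",
    "predict_profile",
    "profile_language_models",
    "read_labelled_users",
    "save_model",
    "load_model",
]

#: Closed vocabulary of user roles (the Profile dimension).
PROFILE_LABELS: tuple[str, ...] = (
    "professional",
    "ex-professional",
    "student",
    "sports",
    "religion",
    "p.services",
    "h.services",
    "concerned",
    "pseudo",
    "journalist",
    "others",
)

#: Characteristic description vocabulary per role — the seed lexicon used
#: both to bootstrap manual labelling and by the synthetic generator.
PROFILE_SEED_VOCAB: dict[str, tuple[str, ...]] = {
    "professional": ("radiosurgery", "oncoplastic", "oncologist",
                     "haemato-oncology", "consultants"),
    "ex-professional": ("retired", "former", "senate", "viet", "colonel"),
    "student": ("student", "thesis", "undergraduate", "engineering", "studying"),
    "sports": ("runner", "marathon", "athlete", "skater", "rider"),
    "religion": ("amin", "allah", "savior", "hindu", "jesus"),
    "p.services": ("traffic", "24h", "breaking", "weather", "protection"),
    "h.services": ("urgencias", "screenings", "specialties", "uninsured", "visitors"),
    "concerned": ("survivor", "reminder_ribbon", "survivorship", "warrior"),
    "pseudo": ("reiki", "meditation", "yoga", "ayurveda", "remedial"),
    "journalist": ("medline-indexed", "issn", "journal", "indexed", "open-access"),
    "others": ("zombies", "yin-yang", "weekends", "voracious", "virgo"),
}

Feature = str | tuple[str, str]


@dataclass(frozen=True)
class LabelledUser:
    user_id: str
    description: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in PROFILE_LABELS:
            raise ValueError(f"unknown profile label {self.label!r}")
        if not self.description and self.label != "others":
            raise ValueError(
                f"user {self.user_id}: empty description only allowed for 'others'"
            )


def description_features(description: str) -> Counter[Feature]:
    """Bag of unigram and adjacent-bigram counts of a description."""
    toks = tokenize(description).tokens
    feats: Counter[Feature] = Counter(toks)
    feats.update(zip(toks, toks[1:]))
    return feats


def _vectorize(
    feature_bags: Sequence[Counter[Feature]], vocabulary: dict[Feature, int]
) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for i, bag in enumerate(feature_bags):
        for f, c in bag.items():
            j = vocabulary.get(f)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(c)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(feature_bags), len(vocabulary)), dtype=float
    )


@dataclass
class ProfileModel:
    """A trained description classifier (deterministic given its state)."""

    vocabulary: dict[Feature, int]
    classes: tuple[str, ...]
    clf: object
    seed: int


def train_profile_classifier(
    data: Sequence[LabelledUser],
    seed: int = 0,
    hidden_units: int = 64,
    backend: str = "mlp",
    min_per_class: int = 5,
) -> ProfileModel:
    """Train the profile classifier on labelled users.

    ``backend='mlp'`` fits one hidden layer of ``hidden_units`` ReLU units;
    ``backend='logistic'`` selects the multinomial-logistic fallback.
    Requires at least two classes and ``min_per_class`` examples per
    present class.  Reproducible for a fixed seed.
    """
    by_class = Counter(u.label for u in data)
    if len(by_class) < 2:
        raise ValueError("need at least 2 profile classes to train")
    thin = sorted(c for c, n in by_class.items() if n < min_per_class)
    if thin:
        raise ValueError(
            f"classes with fewer than {min_per_class} examples: {', '.join(thin)}"
        )
    bags = [description_features(u.description) for u in data]
    vocab: dict[Feature, int] = {}
    for bag in bags:
        for f in bag:
            if f not in vocab:
                vocab[f] = len(vocab)
    x = _vectorize(bags, vocab)
    y = np.array([u.label for u in data])
    if backend == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            random_state=seed,
            max_iter=600,
            early_stopping=False,
        )
    elif backend == "logistic":
        clf = LogisticRegression(max_iter=1000, random_state=seed)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    clf.fit(x, y)
    return ProfileModel(
        vocabulary=vocab, classes=tuple(clf.classes_), clf=clf, seed=seed
    )


def predict_profile(
    model: ProfileModel, description: str
) -> tuple[str, dict[str, float]]:
    """Predict the role of one account from its description.

    Returns the argmax label and the per-class probability map (sums to
    1).  An empty description is ``others`` with certainty by contract.
    """
    if not description.strip():
        return "others", {c: (1.0 if c == "others" else 0.0) for c in PROFILE_LABELS}
    x = _vectorize([description_features(description)], model.vocabulary)
    probs = model.clf.predict_proba(x)[0]
    prob_map = {c: float(p) for c, p in zip(model.classes, probs)}
    label = max(prob_map, key=lambda c: (prob_map[c], c))
    return label, prob_map


def profile_language_models(
    users: Iterable[LabelledUser], top_k: int = 5
) -> dict[str, tuple[LanguageModel, list[tuple[str, float]]]]:
    """Per-profile unigram model over pooled descriptions, with the top-k
    words for report output."""
    pooled: dict[str, list[TokenSequence]] = {}
    for u in users:
        pooled.setdefault(u.label, []).append(tokenize(u.description))
    out = {}
    for label, seqs in pooled.items():
        lm = build_language_model(seqs)
        out[label] = (lm, lm.top_words(top_k))
    return out


def read_labelled_users(
    path: str | Path, descriptions: Mapping[str, str]
) -> list[LabelledUser]:
    """Read a ``user_id<TAB>label`` TSV, resolving descriptions from the
    given user_id -> description mapping."""
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected user_id<TAB>label")
            uid, label = parts
            out.append(
                LabelledUser(user_id=uid, description=descriptions.get(uid, ""),
                             label=label)
            )
    return out


def save_model(model: ProfileModel, path: str | Path) -> None:
    import joblib

    joblib.dump(model, path)


def load_model(path: str | Path) -> ProfileModel:
    import joblib

    return joblib.load(path)
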