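"""Rule-based linguistic signals: question probability Q(p) and
future-action probability A(p).

Q(p) uses two rule families: a question mark anywhere in a sentence (high
confidence) and constrained 5W1H patterns — an interrogative word (what, who,
when, where, why, how) followed by an auxiliary, at the *beginning* of a
sentence (lower confidence).  A post's Q is the max over its sentences.

A(p) fires (probability 1.0) when any sentence contains a modal auxiliary
(Penn Treebank MD: will, can, could, may, must, would, should, might, shall)
or a "going to <verb>" future construction; otherwise it falls back to 0.5 to
absorb typos and informal writing that hide the tense.  Negation is
deliberately ignored: a negated plan still signals engagement with the
suggestion, and the polarity flip is carried by the relevance vectors instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .threads import Post

__all__ = [
    "QuestionRuleTable",
    "SignalScores",
    "split_sentences",
    "tokenize",
    "sentence_question_prob",
    "post_question_prob",
    "post_action_prob",
    "annotate_sentences",
    "MODAL_AUXILIARIES",
]

FIVE_W1H = ("what", "who", "when", "where", "why", "how")
_AUXILIARIES = (
    "is", "are", "was", "were",
    "do", "does", "did",
    "can", "could", "should", "would", "will",
)

#: Penn Treebank MD tag lexicon.
MODAL_AUXILIARIES = frozenset(
    {"will", "can", "could", "may", "must", "would", "should", "might", "shall"}
)

# words that cannot head a verb phrase after "going to"; a crude base-form
# verb filter in lieu of a full tagger
_NON_VERB_AFTER_TO = frozenset(
    {"the", "a", "an", "my", "your", "his", "her", "their", "our", "its",
     "this", "that", "these", "those", "me", "you", "him", "them", "us", "it"}
)

_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"[\w']+")


def _default_patterns() -> tuple[tuple[str, ...], ...]:
    return tuple((w, aux) for w in FIVE_W1H for aux in _AUXILIARIES)


@dataclass(frozen=True)
class QuestionRuleTable:
    """Confidences and sentence-initial 5W1H patterns for question detection.

    The question mark is the most reliable cue, so ``qmark_confidence`` must
    strictly dominate ``pattern_confidence``.
    """

    qmark_confidence: float = 1.0
    pattern_confidence: float = 0.9
    patterns: tuple[tuple[str, ...], ...] = field(default_factory=_default_patterns)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pattern_confidence < self.qmark_confidence <= 1.0:
            raise ValueError(
                "require 0 <= pattern_confidence < qmark_confidence <= 1"
            )
        for pat in self.patterns:
            if not pat or pat[0] not in FIVE_W1H:
                raise ValueError(f"pattern {pat!r} must start with a 5W1H word")
            if any(tok != tok.lower() for tok in pat):
                raise ValueError(f"pattern {pat!r} must be lowercase")


@dataclass(frozen=True)
class SignalScores:
    """The two dense features of a post: Q(p) and A(p)."""

    q: float
    a: float


def split_sentences(text: str) -> list[str]:
    """Split text into sentences on terminal punctuation (., !, ?).

    Ellipses stay attached to the preceding sentence fragment.  Empty
    sentences are never returned.
    """
    parts = [s.strip() for s in _SENT_SPLIT.split(text)]
    return [s for s in parts if s]


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens (alphanumerics and apostrophes)."""
    return _TOKEN.findall(text.lower())


def sentence_question_prob(
    sentence: str, rules: QuestionRuleTable | None = None
) -> float:
    """Probability that a single sentence is a question.

    Question mark anywhere -> ``qmark_confidence``; otherwise a 5W1H pattern
    matching the sentence-initial tokens (case-insensitive) ->
    ``pattern_confidence``; otherwise 0.
    """
    rules = rules or QuestionRuleTable()
    if "?" in sentence:
        return rules.qmark_confidence
    tokens = tokenize(sentence)
    for pat in rules.patterns:
        if tuple(tokens[: len(pat)]) == pat:
            return rules.pattern_confidence
    return 0.0


def post_question_prob(post: Post, rules: QuestionRuleTable | None = None) -> float:
    """Q(p): the max sentence-level question probability of the post."""
    if not post.sentences:
        return 0.0
    return max(sentence_question_prob(s, rules) for s in post.sentences)


def _has_future_construction(tokens: list[str]) -> bool:
    for tok in tokens:
        if tok in MODAL_AUXILIARIES:
            return True
    for i in range(len(tokens) - 2):
        if (
            tokens[i] == "going"
            and tokens[i + 1] == "to"
            and tokens[i + 2] not in _NON_VERB_AFTER_TO
        ):
            return True
    return False


def post_action_prob(post: Post) -> float:
    """A(p): 1.0 when a future-action cue is present in any sentence,
    0.5 otherwise (the fallback for missed informal phrasings)."""
    for sentence in post.sentences:
        if _has_future_construction(tokenize(sentence)):
            return 1.0
    return 0.5


def annotate_sentences(post: Post) -> Post:
    """Return the post with its ``sentences`` field populated."""
    return post.with_sentences(split_sentences(post.text))
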