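"""Synthetic discussion-thread corpus with gold relevance and influence labels.

The generator emulates the statistical skeleton of decision-making threads in
an online health community: an initial post on one topic, replies that share
the parent's topic with a controllable probability, and counter-replies by the
initial author that may contain a question and/or a future-action sentence.
Pairwise relevance is purely topical (two posts are relevant iff they were
generated from the same topic vocabulary — mirroring a shared-medical-terms
labeling rule), and a triple is an influence relationship iff both of its
pairs are relevant and the counter-reply got a question or action sentence.

Default parameters follow the label rates observed on real OHC data:
~70% of reply pairs relevant and ~31% of triples positive.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .threads import Thread, build_reply_tree, save_threads_jsonl

__all__ = [
    "SynthConfig",
    "PairLabel",
    "TripleLabel",
    "SyntheticCorpus",
    "make_worked_example_thread",
    "generate_corpus",
    "write_corpus",
    "QUESTION_TEMPLATES",
    "ACTION_TEMPLATES",
]

# Question sentences always carry a terminal question mark so the question
# rules fire at full confidence on every gold-positive sentence; none of them
# contains a modal auxiliary, so they never trip the action rule.
QUESTION_TEMPLATES = (
    "what is {w}?",
    "what does {w} feel like?",
    "how do you manage {w}?",
    "where do you read about {w}?",
    "did it hurt when you had {w}?",
)

# Action sentences always carry a modal auxiliary or a going-to construction.
ACTION_TEMPLATES = (
    "i will consider {w} for my treatment plan.",
    "i will ask my doctor about {w}.",
    "i am going to try {w} next week.",
    "i would like to start {w} soon.",
    "we might schedule {w} after the next scan.",
)


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; probabilities are per-branch Bernoulli rates."""

    n_threads: int = 200
    topics: int = 4
    topic_vocab_size: int = 25
    shared_vocab_size: int = 40
    sentence_length: int = 8
    sentences_per_post: int = 2
    branching: int = 3
    p_reply_relevant: float = 0.7
    p_question: float = 0.4
    p_action: float = 0.4
    p_counter_reply: float = 0.8
    noise_rate: float = 0.6
    noise_spread: float = 0.35
    seed: int = 7

    def __post_init__(self):
        for name in ("p_reply_relevant", "p_question", "p_action",
                     "p_counter_reply", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_threads", "topics", "topic_vocab_size",
                     "shared_vocab_size", "sentence_length",
                     "sentences_per_post"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_threads > 0 and self.branching < 1:
            raise ValueError("branching must be >= 1 to produce any triples")


@dataclass(frozen=True)
class PairLabel:
    thread_id: str
    post_id_a: str
    post_id_b: str
    label: int  # 1 relevant, 0 irrelevant


@dataclass(frozen=True)
class TripleLabel:
    thread_id: str
    a_id: str
    b_id: str
    c_id: str
    label: int  # +1 influence, -1 not
    q_inserted: bool = False
    a_inserted: bool = False


@dataclass
class SyntheticCorpus:
    config: SynthConfig
    threads: list[Thread] = field(default_factory=list)
    pair_labels: list[PairLabel] = field(default_factory=list)
    triple_labels: list[TripleLabel] = field(default_factory=list)

    def thread_map(self) -> dict[str, Thread]:
        return {t.thread_id: t for t in self.threads}


def make_worked_example_thread() -> Thread:
    """The five-post worked example: an initial post with two reply chains,
    each chain ending in a counter-reply by the initial author.  Exactly two
    relationship triples exist in this thread."""
    records = [
        ("u1", 0, "Should my mom have chemotherapy before her surgery? "
                  "The oncologist left the decision to us and I am lost."),
        ("u2", 1, "I had chemo first and it shrank the tumor before my "
                  "operation. I would suggest discussing neoadjuvant chemo."),
        ("u1", 2, "Thank you so much. How long was your chemo course before "
                  "the surgery?"),
        ("u3", 1, "My surgeon recommended operating first in my case. Every "
                  "tumor is different, so ask about the biology of hers."),
        ("u1", 2, "That makes sense. I will bring up the tumor biology at "
                  "our next appointment."),
    ]
    return build_reply_tree(
        records,
        thread_id="example",
        post_ids=["pA", "pB", "pC", "pBp", "pCp"],
    )


def _vocab(cfg: SynthConfig) -> tuple[list[list[str]], list[str]]:
    topics = [
        [f"t{t}w{i}" for i in range(cfg.topic_vocab_size)]
        for t in range(cfg.topics)
    ]
    shared = [f"gen{i}" for i in range(cfg.shared_vocab_size)]
    return topics, shared


def _plain_sentence(rng, cfg, topic_words, shared, noise: float) -> str:
    toks = []
    for _ in range(cfg.sentence_length):
        if rng.random() < noise:
            toks.append(shared[rng.integers(len(shared))])
        else:
            toks.append(topic_words[rng.integers(len(topic_words))])
    return " ".join(toks) + "."


def _post_text(rng, cfg, topic_words, shared, extra: Sequence[str] = ()) -> str:
    # posts differ in how on-topic they are: the generic-token rate is drawn
    # per post around noise_rate, so some posts are strongly topical and some
    # are almost entirely generic chatter — which is what makes the relevance
    # labels imperfectly recoverable from text, as in real labeled pairs
    noise = float(np.clip(
        rng.uniform(cfg.noise_rate - cfg.noise_spread,
                    cfg.noise_rate + cfg.noise_spread),
        0.0, 1.0,
    ))
    sents = [
        _plain_sentence(rng, cfg, topic_words, shared, noise)
        for _ in range(cfg.sentences_per_post)
    ]
    sents.extend(extra)
    return " ".join(sents)


def _pick_topic(rng, cfg, parent_topic: int, relevant: bool) -> int:
    if relevant:
        return parent_topic
    others = [t for t in range(cfg.topics) if t != parent_topic]
    if not others:
        raise ValueError("need >= 2 topics to generate irrelevant replies")
    return others[rng.integers(len(others))]


def generate_corpus(config: SynthConfig | None = None) -> SyntheticCorpus:
    """Generate threads plus gold pair and triple labels, deterministically
    from ``config.seed``."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    topics_vocab, shared = _vocab(cfg)
    corpus = SyntheticCorpus(config=cfg)

    for ti in range(cfg.n_threads):
        thread_id = f"t{ti:04d}"
        root_author = f"u{ti}_0"
        root_topic = int(rng.integers(cfg.topics))
        records: list[tuple[str, int, str]] = [
            (root_author, 0,
             _post_text(rng, cfg, topics_vocab[root_topic], shared,
                        extra=["what should i do about this?"]))
        ]
        # (record index of B, record index of C or None, bookkeeping)
        branches = []
        n_branches = int(rng.integers(1, cfg.branching + 1))
        for k in range(n_branches):
            rel_ab = bool(rng.random() < cfg.p_reply_relevant)
            topic_b = _pick_topic(rng, cfg, root_topic, rel_ab)
            b_idx = len(records)
            records.append(
                (f"u{ti}_{k + 1}", 1,
                 _post_text(rng, cfg, topics_vocab[topic_b], shared))
            )
            if rng.random() >= cfg.p_counter_reply:
                continue  # reply never answered by the initial author
            rel_bc = bool(rng.random() < cfg.p_reply_relevant)
            topic_c = _pick_topic(rng, cfg, topic_b, rel_bc)
            q_ins = bool(rng.random() < cfg.p_question)
            a_ins = bool(rng.random() < cfg.p_action)
            extra = []
            tw = topics_vocab[topic_c]
            if q_ins:
                tpl = QUESTION_TEMPLATES[rng.integers(len(QUESTION_TEMPLATES))]
                extra.append(tpl.format(w=tw[rng.integers(len(tw))]))
            if a_ins:
                tpl = ACTION_TEMPLATES[rng.integers(len(ACTION_TEMPLATES))]
                extra.append(tpl.format(w=tw[rng.integers(len(tw))]))
            c_idx = len(records)
            records.append(
                (root_author, 2,
                 _post_text(rng, cfg, tw, shared, extra=extra))
            )
            branches.append((b_idx, c_idx, rel_ab, rel_bc, q_ins, a_ins))

        thread = build_reply_tree(records, thread_id=thread_id)
        corpus.threads.append(thread)
        posts = thread.posts  # build keeps input order; no posts are dropped
        for b_idx, c_idx, rel_ab, rel_bc, q_ins, a_ins in branches:
            a_id = posts[0].post_id
            b_id = posts[b_idx].post_id
            c_id = posts[c_idx].post_id
            corpus.pair_labels.append(
                PairLabel(thread_id, a_id, b_id, int(rel_ab))
            )
            corpus.pair_labels.append(
                PairLabel(thread_id, b_id, c_id, int(rel_bc))
            )
            label = 1 if (rel_ab and rel_bc and (q_ins or a_ins)) else -1
            corpus.triple_labels.append(
                TripleLabel(thread_id, a_id, b_id, c_id, label, q_ins, a_ins)
            )
    return corpus


def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> None:
    """Write threads.jsonl, pairs.tsv, triples.tsv and a manifest.json."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_threads_jsonl(corpus.threads, outdir / "threads.jsonl")
    pd.DataFrame(
        [(p.thread_id, p.post_id_a, p.post_id_b, p.label)
         for p in corpus.pair_labels],
        columns=["thread_id", "post_id_a", "post_id_b", "label"],
    ).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(t.thread_id, t.a_id, t.b_id, t.c_id, t.label)
         for t in corpus.triple_labels],
        columns=["thread_id", "a_id", "b_id", "c_id", "label"],
    ).to_csv(outdir / "triples.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"config": asdict(corpus.config)}, fh, indent=2)
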