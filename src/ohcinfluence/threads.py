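"""Discussion-thread domain model and relationship extraction.

An online health community (OHC) thread is a set of posts plus a reply map
``R`` (child post -> parent post) forming a tree rooted at the *initial post*
``p_A``.  A *relationship* is an ordered post triple ``(p_A, p_B, p_C)`` where
``p_B`` replies to the initial post, ``p_C`` replies to ``p_B``, the author of
``p_C`` is the initial author, and the author of ``p_B`` is somebody else.
These triples are the unit of influence classification downstream.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Post",
    "Thread",
    "Relationship",
    "ThreadError",
    "EmptyThreadError",
    "MalformedIndentError",
    "build_reply_tree",
    "extract_relationships",
    "thread_from_json",
    "thread_to_json",
    "load_threads_jsonl",
    "save_threads_jsonl",
    "parse_html_thread",
]

_WS = re.compile(r"\s+")


class ThreadError(ValueError):
    """Base class for malformed thread input."""


class EmptyThreadError(ThreadError):
    """Raised when a thread has no (non-empty) posts."""


class MalformedIndentError(ThreadError):
    """Raised when a post's indent depth has no plausible parent."""


@dataclass(frozen=True)
class Post:
    """One forum message.

    ``depth`` is the number of indent units below the initial post (0 for the
    initial post itself); ``order_index`` is the chronological rank within the
    thread.  ``sentences`` is filled by the linguistic-signal layer.
    """

    post_id: str
    author_id: str
    order_index: int
    depth: int
    text: str
    sentences: tuple[str, ...] = ()

    def with_sentences(self, sentences: Sequence[str]) -> "Post":
        return replace(self, sentences=tuple(sentences))


@dataclass
class Thread:
    """A post set plus the reply map R and the distinguished initial post."""

    thread_id: str
    posts: list[Post]
    reply_map: dict[str, str]  # child post_id -> parent post_id
    initial_post_id: str
    _by_id: dict[str, Post] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._by_id = {p.post_id: p for p in self.posts}

    def post(self, post_id: str) -> Post:
        return self._by_id[post_id]

    @property
    def initial_post(self) -> Post:
        return self._by_id[self.initial_post_id]

    def children(self, post_id: str) -> list[Post]:
        kids = [p for p in self.posts if self.reply_map.get(p.post_id) == post_id]
        return sorted(kids, key=lambda p: p.order_index)

    def author(self, post_id: str) -> str:
        """The author function U."""
        return self._by_id[post_id].author_id

    def map_posts(self, fn) -> "Thread":
        """Return a copy with ``fn`` applied to every post (e.g. sentence fill)."""
        return Thread(
            thread_id=self.thread_id,
            posts=[fn(p) for p in self.posts],
            reply_map=dict(self.reply_map),
            initial_post_id=self.initial_post_id,
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ThreadError on violation."""
        if not self.posts:
            raise EmptyThreadError("thread has no posts")
        orders = [p.order_index for p in self.posts]
        if len(set(orders)) != len(orders):
            raise ThreadError("order_index values are not unique")
        root = self.initial_post
        if root.order_index != 0 or root.depth != 0:
            raise ThreadError("initial post must have order_index 0 and depth 0")
        for p in self.posts:
            if p.post_id == self.initial_post_id:
                if p.post_id in self.reply_map:
                    raise ThreadError("initial post cannot reply to anything")
                continue
            if p.depth == 0:
                raise ThreadError(f"non-root post {p.post_id} has depth 0")
            parent_id = self.reply_map.get(p.post_id)
            if parent_id is None:
                raise ThreadError(f"post {p.post_id} has no parent")
            parent = self._by_id[parent_id]
            if not parent.order_index < p.order_index:
                raise ThreadError("parent must precede child chronologically")
        # acyclicity with a single root: walking up from any post reaches the root
        for p in self.posts:
            seen = set()
            cur = p.post_id
            while cur in self.reply_map:
                if cur in seen:
                    raise ThreadError("reply map contains a cycle")
                seen.add(cur)
                cur = self.reply_map[cur]
            if cur != self.initial_post_id:
                raise ThreadError("reply map has more than one root")


@dataclass(frozen=True)
class Relationship:
    """An ordered triple (p_A, p_B, p_C): initial post, outside reply,
    and the initial author's counter-reply."""

    thread_id: str
    a_id: str
    b_id: str
    c_id: str


def _normalize(text: str) -> str:
    return _WS.sub(" ", text).strip()


def build_reply_tree(
    records: Sequence[tuple[str, int, str]],
    thread_id: str = "thread",
    post_ids: Sequence[str] | None = None,
) -> Thread:
    """Build a thread tree from chronologically ordered, indent-annotated posts.

    Each record is ``(author_id, depth, text)``.  A post at depth ``d >= 1``
    attaches to the most recent preceding post at depth ``d - 1`` (the tab
    indentation convention of forum HTML dumps).  Posts whose text is empty
    after whitespace normalization are dropped with a warning and their
    children are re-attached to the most recent surviving shallower post.

    Raises
    ------
    EmptyThreadError
        If no records are given or the initial post is empty.
    MalformedIndentError
        If the first post is not at depth 0, or a later post's depth jumps so
        that no preceding post at depth ``d - 1`` exists.
    """
    if not records:
        raise EmptyThreadError("no posts supplied")
    if post_ids is None:
        post_ids = [f"p{i + 1}" for i in range(len(records))]
    if len(post_ids) != len(records):
        raise ThreadError("post_ids length must match records")

    # indent validation runs on the raw sequence, before any drops
    max_depth_seen = 0
    for i, (_, depth, _) in enumerate(records):
        if i == 0:
            if depth != 0:
                raise MalformedIndentError("initial post must have depth 0")
            continue
        if depth < 1:
            raise MalformedIndentError(f"post {i + 1}: non-initial depth must be >= 1")
        if depth > max_depth_seen + 1:
            raise MalformedIndentError(
                f"post {i + 1}: depth {depth} has no preceding post at depth {depth - 1}"
            )
        max_depth_seen = max(max_depth_seen, depth)

    kept: list[Post] = []
    reply_map: dict[str, str] = {}
    for i, (author, depth, text) in enumerate(records):
        text = _normalize(text)
        if not text:
            if i == 0:
                raise EmptyThreadError("initial post is empty")
            warnings.warn(
                f"dropping empty post {post_ids[i]} in thread {thread_id}",
                stacklevel=2,
            )
            continue
        post = Post(
            post_id=str(post_ids[i]),
            author_id=str(author),
            order_index=len(kept),
            depth=int(depth),
            text=text,
        )
        if kept:
            parent = _most_recent_shallower(kept, post.depth)
            reply_map[post.post_id] = parent.post_id
        kept.append(post)

    thread = Thread(
        thread_id=thread_id,
        posts=kept,
        reply_map=reply_map,
        initial_post_id=kept[0].post_id,
    )
    thread.validate()
    return thread


def _most_recent_shallower(kept: list[Post], depth: int) -> Post:
    # prefer the exact parent depth; fall back to the nearest shallower post
    # (only reachable when an intermediate post was dropped as empty)
    for post in reversed(kept):
        if post.depth == depth - 1:
            return post
    for post in reversed(kept):
        if post.depth < depth:
            return post
    raise MalformedIndentError(f"no parent candidate for depth {depth}")


def extract_relationships(thread: Thread) -> list[Relationship]:
    """Enumerate all (p_A, p_B, p_C) triples of the thread.

    p_A is the initial post; p_B is a direct reply to it by a *different*
    author; p_C is a direct reply to p_B by the *initial* author.  Output is
    ordered by (order of p_B, order of p_C), so it is deterministic.
    """
    root = thread.initial_post
    out: list[Relationship] = []
    for b in thread.children(root.post_id):
        if b.author_id == root.author_id:
            continue
        for c in thread.children(b.post_id):
            if c.author_id == root.author_id:
                out.append(
                    Relationship(thread.thread_id, root.post_id, b.post_id, c.post_id)
                )
    return out


# ---------------------------------------------------------------------------
# external formats


def thread_from_json(obj: dict) -> Thread:
    """Build a Thread from the JSON schema
    ``{"thread_id": ..., "posts": [{"post_id", "author_id", "depth", "text"}, ...]}``
    with posts listed chronologically."""
    posts = obj["posts"]
    return build_reply_tree(
        [(p["author_id"], p["depth"], p["text"]) for p in posts],
        thread_id=obj["thread_id"],
        post_ids=[p["post_id"] for p in posts],
    )


def thread_to_json(thread: Thread) -> dict:
    return {
        "thread_id": thread.thread_id,
        "posts": [
            {
                "post_id": p.post_id,
                "author_id": p.author_id,
                "depth": p.depth,
                "text": p.text,
            }
            for p in sorted(thread.posts, key=lambda p: p.order_index)
        ],
    }


def load_threads_jsonl(path: str | Path) -> list[Thread]:
    """Read threads from a JSON-lines file (one thread object per line)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(thread_from_json(json.loads(line)))
    return out


def save_threads_jsonl(threads: Iterable[Thread], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in threads:
            fh.write(json.dumps(thread_to_json(t)) + "\n")


def parse_html_thread(html: str, thread_id: str = "thread") -> Thread:
    """Parse an HTML dump where each post is an element with class ``post``,
    an author in ``data-author``, and reply depth encoded as the number of
    leading tab characters of the post text."""
    from lxml import html as lxml_html

    doc = lxml_html.fromstring(html)
    nodes = doc.xpath(
        "//*[contains(concat(' ', normalize-space(@class), ' '), ' post ')]"
    )
    if not nodes:
        raise EmptyThreadError("no post blocks found in HTML")
    records = []
    for node in nodes:
        raw = node.text_content()
        stripped = raw.lstrip("\n")
        depth = len(stripped) - len(stripped.lstrip("\t"))
        records.append((node.get("data-author", ""), depth, stripped))
    return build_reply_tree(records, thread_id=thread_id)
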