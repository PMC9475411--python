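"""Word embeddings trained on the training corpus, and the word-interaction
matrix consumed by interaction-based relevance matching.

The embedder is a skip-gram model with negative sampling (SGNS), the word2vec
variant appropriate for small domain corpora: for each (center, context) pair
inside a fixed window it raises sigma(w_c . c_o) while pushing down the score
of k noise words drawn from the unigram distribution raised to 3/4.  Training
is plain SGD with a linearly decaying learning rate, single-threaded and
seeded, so runs are exactly reproducible.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["SkipGramEmbeddings", "train_embeddings", "interaction_matrix"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class SkipGramEmbeddings(BaseEstimator):
    """Skip-gram word embeddings with negative sampling.

    Parameters
    ----------
    dim : embedding width.
    window : symmetric context window in tokens.
    min_count : minimum corpus frequency for a token to get a vector.
    negative : noise words per positive pair.
    epochs : passes over the pair list.
    lr : initial learning rate per averaged chunk update (decays linearly
        to ~0); see ``_sgd`` for the update rule.
    seed : RNG seed; identical seeds give identical matrices.

    Attributes
    ----------
    vocabulary_ : dict mapping token -> row index into ``vectors_``.
    vectors_ : (|V|, dim) float array of input vectors.
    counts_ : corpus frequency per vocabulary row.
    """

    def __init__(
        self,
        dim: int = 50,
        window: int = 4,
        min_count: int = 1,
        negative: int = 5,
        epochs: int = 10,
        lr: float = 0.2,
        seed: int = 0,
    ):
        self.dim = dim
        self.window = window
        self.min_count = min_count
        self.negative = negative
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def fit(self, corpus: Sequence[Sequence[str]], y=None):
        if not corpus or all(len(s) == 0 for s in corpus):
            raise ValueError("empty corpus")
        counts = Counter(tok for sent in corpus for tok in sent)
        vocab = [
            tok
            for tok, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if c >= self.min_count
        ]
        if not vocab:
            raise ValueError("no token meets min_count")
        self.vocabulary_ = {tok: i for i, tok in enumerate(vocab)}
        self.counts_ = np.array([counts[t] for t in vocab], dtype=np.int64)

        centers, contexts = self._pairs(corpus)
        rng = np.random.default_rng(self.seed)
        nv = len(vocab)
        W = (rng.random((nv, self.dim)) - 0.5) / self.dim
        C = np.zeros((nv, self.dim))
        if centers.size:
            self._sgd(W, C, centers, contexts, rng)
        self.vectors_ = W
        return self

    def _pairs(self, corpus) -> tuple[np.ndarray, np.ndarray]:
        centers, contexts = [], []
        vocab = self.vocabulary_
        for sent in corpus:
            ids = [vocab[t] for t in sent if t in vocab]
            for i, c in enumerate(ids):
                lo = max(0, i - self.window)
                hi = min(len(ids), i + self.window + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(c)
                        contexts.append(ids[j])
        return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)

    def _sgd(self, W, C, centers, contexts, rng, chunk: int = 2048) -> None:
        # Chunked SGD with per-word gradient averaging: within a chunk the
        # accumulated gradient of each row is divided by how often the row was
        # touched, so the step size per word is bounded by lr regardless of
        # how frequent the word is (a plain summed update diverges on small
        # vocabularies where one chunk hits the same word hundreds of times).
        n = centers.size
        nv = len(self.counts_)
        noise = self.counts_.astype(np.float64) ** 0.75
        noise /= noise.sum()
        total = self.epochs * n
        done = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, chunk):
                idx = order[start : start + chunk]
                c, o = centers[idx], contexts[idx]
                lr = self.lr * max(1.0 - done / total, 1e-4)
                neg = rng.choice(nv, size=(idx.size, self.negative), p=noise)
                wc = W[c]  # (m, d)
                co = C[o]
                cn = C[neg]  # (m, k, d)
                g_pos = _sigmoid(np.sum(wc * co, axis=1)) - 1.0  # (m,)
                g_neg = _sigmoid(np.einsum("md,mkd->mk", wc, cn))  # (m, k)

                gW = np.zeros_like(W)
                grad_wc = g_pos[:, None] * co + np.einsum("mk,mkd->md", g_neg, cn)
                np.add.at(gW, c, grad_wc)
                cnt_w = np.bincount(c, minlength=nv)
                W -= lr * gW / np.maximum(cnt_w, 1)[:, None]

                gC = np.zeros_like(C)
                np.add.at(gC, o, g_pos[:, None] * wc)
                np.add.at(
                    gC,
                    neg.ravel(),
                    (g_neg[..., None] * wc[:, None, :]).reshape(-1, self.dim),
                )
                cnt_c = np.bincount(o, minlength=nv) + np.bincount(
                    neg.ravel(), minlength=nv
                )
                C -= lr * gC / np.maximum(cnt_c, 1)[:, None]
                done += idx.size

    # -- lookup -------------------------------------------------------------

    def lookup(self, tokens: Sequence[str]) -> np.ndarray:
        """Embed a token list as an (n, dim) array; out-of-vocabulary tokens
        map to the zero vector."""
        out = np.zeros((len(tokens), self.dim))
        for i, tok in enumerate(tokens):
            j = self.vocabulary_.get(tok)
            if j is not None:
                out[i] = self.vectors_[j]
        return out

    def token_ids(self, tokens: Sequence[str]) -> np.ndarray:
        """Row ids shifted by one: 0 is the shared padding/OOV id."""
        return np.array(
            [self.vocabulary_.get(t, -1) + 1 for t in tokens], dtype=np.int64
        )

    def padded_matrix(self) -> np.ndarray:
        """(|V| + 1, dim) matrix whose row 0 is the zero pad/OOV vector."""
        return np.vstack([np.zeros((1, self.dim)), self.vectors_])


def train_embeddings(
    corpus: Sequence[Sequence[str]],
    dim: int = 50,
    window: int = 4,
    min_count: int = 1,
    seed: int = 0,
    **kwargs,
) -> SkipGramEmbeddings:
    """Train skip-gram embeddings on tokenized sentences (thin wrapper)."""
    return SkipGramEmbeddings(
        dim=dim, window=window, min_count=min_count, seed=seed, **kwargs
    ).fit(corpus)


def interaction_matrix(
    tokens_a: Sequence[str],
    tokens_b: Sequence[str],
    emb: SkipGramEmbeddings,
) -> np.ndarray:
    """Word-by-word relevance matrix M[i, j] = <emb(a_i), emb(b_j)>."""
    if not tokens_a or not tokens_b:
        raise ValueError("token lists must be non-empty")
    return emb.lookup(tokens_a) @ emb.lookup(tokens_b).T
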