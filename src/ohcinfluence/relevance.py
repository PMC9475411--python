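"""Trainable text-relevance measurement for post pairs.

Two architectures are provided behind a single estimator surface:

* ``arc1`` — representation-based matching: each text is embedded, passed
  through a 1-D convolution and masked global max-pooling, and the two pooled
  feature vectors are concatenated into a fully connected layer that scores
  the pair.  Relevance is judged from whole-text representations.
* ``matchpyramid`` — interaction-based matching: a word-by-word dot-product
  matrix of the two texts is built first, and a 2-D convolution plus adaptive
  max-pooling extracts local interaction patterns before the dense layers.

Both emit a scalar relevance score in [0, 1] (terminal sigmoid) and a
penultimate-layer *relevance vector* — the richer pair representation that
the influence combiner consumes.  Word embeddings are trained separately on
the training corpus and stay frozen inside the matchers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import Adam, bce_loss, glorot, relu, sigmoid
from .embeddings import SkipGramEmbeddings

__all__ = [
    "RelevancePair",
    "RelevanceOutput",
    "RelevanceClassifier",
    "train_relevance_model",
    "arc1_forward",
    "matchpyramid_forward",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelevancePair:
    """A directional post pair; label 1 = relevant, 0 = irrelevant."""

    tokens_a: tuple[str, ...]
    tokens_b: tuple[str, ...]
    label: int | None = None


@dataclass(frozen=True)
class RelevanceOutput:
    """Scalar relevance score plus the penultimate-layer relevance vector."""

    score: float
    vector: np.ndarray


def _as_token_lists(X) -> list[tuple[Sequence[str], Sequence[str]]]:
    out = []
    for item in X:
        if isinstance(item, RelevancePair):
            out.append((item.tokens_a, item.tokens_b))
        else:
            a, b = item
            out.append((a, b))
    return out


class RelevanceClassifier(BaseEstimator, ClassifierMixin):
    """Post-pair relevance classifier (ARC-I or MatchPyramid style).

    Parameters
    ----------
    embeddings : fitted :class:`SkipGramEmbeddings` providing the frozen
        embedding layer (the layer is pluggable: anything exposing
        ``token_ids``/``padded_matrix``/``dim`` works).
    arch : ``"arc1"`` (representation-based) or ``"matchpyramid"``
        (interaction-based).
    max_len : hard cap on tokens per text; longer texts are truncated (logged,
        never an error).  The effective padded length also shrinks to the
        longest training text, which only removes all-pad columns.
    n_filters, kernel : convolution width (1-D kernel for arc1, square 2-D
        kernel for matchpyramid).
    hidden_dim : width of the relevance vector (last hidden layer).
    pool_grid : adaptive pooling grid (matchpyramid only).
    epochs, batch_size, lr, seed : Adam training schedule; with ``epochs=0``
    the seeded random initialization is returned untrained.
    """

    def __init__(
        self,
        embeddings: SkipGramEmbeddings | None = None,
        arch: str = "arc1",
        max_len: int = 128,
        n_filters: int = 32,
        kernel: int = 3,
        hidden_dim: int = 64,
        pool_grid: int = 4,
        epochs: int = 10,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        self.embeddings = embeddings
        self.arch = arch
        self.max_len = max_len
        self.n_filters = n_filters
        self.kernel = kernel
        self.hidden_dim = hidden_dim
        self.pool_grid = pool_grid
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    # -- encoding -----------------------------------------------------------

    def _encode(self, pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        L = self.pad_len_
        n = len(pairs)
        Xa = np.zeros((n, L), dtype=np.int64)
        Xb = np.zeros((n, L), dtype=np.int64)
        la = np.empty(n, dtype=np.int64)
        lb = np.empty(n, dtype=np.int64)
        truncated = 0
        for i, (a, b) in enumerate(pairs):
            for X, lens, toks in ((Xa, la, a), (Xb, lb, b)):
                ids = self.embeddings.token_ids(toks)
                if ids.size > L:
                    truncated += 1
                    ids = ids[:L]
                X[i, : ids.size] = ids
                lens[i] = max(ids.size, 1)
        if truncated:
            logger.warning("truncated %d over-long texts to %d tokens", truncated, L)
        return Xa, Xb, la, lb

    # -- parameter initialization -------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d, F, k, H = self.embeddings.dim, self.n_filters, self.kernel, self.hidden_dim
        p: dict[str, np.ndarray] = {}
        if self.arch == "arc1":
            p["Wc"] = glorot(rng, k * d, F)
            p["bc"] = np.zeros(F)
            p["W1"] = glorot(rng, 2 * F, H)
        elif self.arch == "matchpyramid":
            p["Wc"] = glorot(rng, k * k, F, shape=(k, k, F))
            p["bc"] = np.zeros(F)
            g = self.grid_
            p["W1"] = glorot(rng, g * g * F, H)
        else:
            raise ValueError(f"unknown arch {self.arch!r}")
        p["b1"] = np.zeros(H)
        # zero-init the scoring layer: training starts at score 0.5 instead of
        # a saturated sigmoid (pooled conv features have unbounded magnitude)
        p["w2"] = np.zeros((H, 1))
        p["b2"] = np.zeros(1)
        return p

    # -- forward / backward -------------------------------------------------

    def _conv1d_pool(self, X, lens):
        """Embed, convolve and masked-max-pool one text batch."""
        E = self.E_
        k = self.kernel
        Ea = E[X]  # (B, L, d)
        win = sliding_window_view(Ea, k, axis=1)  # (B, P, d, k)
        win = win.transpose(0, 1, 3, 2).reshape(win.shape[0], win.shape[1], -1)
        Z = win @ self.params_["Wc"] + self.params_["bc"]  # (B, P, F)
        A = relu(Z)
        P = Z.shape[1]
        valid = np.maximum(lens - k + 1, 1)  # windows fully inside the text
        mask = np.arange(P)[None, :] < valid[:, None]
        Am = np.where(mask[:, :, None], A, -1e30)
        amax = Am.argmax(axis=1)  # (B, F)
        h = np.take_along_axis(Am, amax[:, None, :], axis=1)[:, 0, :]
        return h, (win, Z, amax)

    def _conv1d_pool_back(self, cache, dh):
        win, Z, amax = cache
        B, P, F = Z.shape
        dA = np.zeros((B, P, F))
        np.add.at(dA, (np.arange(B)[:, None], amax, np.arange(F)[None, :]), dh)
        dZ = dA * (Z > 0)
        dWc = np.einsum("bpx,bpf->xf", win, dZ)
        dbc = dZ.sum(axis=(0, 1))
        return dWc, dbc

    def _forward(self, Xa, Xb, la, lb):
        p = self.params_
        if self.arch == "arc1":
            ha, ca = self._conv1d_pool(Xa, la)
            hb, cb = self._conv1d_pool(Xb, lb)
            h = np.concatenate([ha, hb], axis=1)
            cache_arch = (ca, cb)
        else:
            E = self.E_
            M = np.einsum("bld,bmd->blm", E[Xa], E[Xb])  # interaction matrix
            k = self.kernel
            win = sliding_window_view(M, (k, k), axis=(1, 2))  # (B,Ph,Pw,k,k)
            Z = np.einsum("bpqkl,klf->bpqf", win, p["Wc"]) + p["bc"]
            A = relu(Z)
            pooled, idx = _adaptive_maxpool(A, self.grid_)
            h = pooled.reshape(A.shape[0], -1)
            cache_arch = (win, Z, idx, pooled.shape)
        u_pre = h @ p["W1"] + p["b1"]
        u = relu(u_pre)  # the relevance vector
        z = u @ p["w2"] + p["b2"]
        s = sigmoid(z)[:, 0]
        return s, u, (h, u_pre, u, cache_arch)

    def _backward(self, Xa, Xb, cache, dz):
        p = self.params_
        h, u_pre, u, cache_arch = cache
        grads: dict[str, np.ndarray] = {}
        grads["w2"] = u.T @ dz
        grads["b2"] = dz.sum(axis=0)
        du = (dz @ p["w2"].T) * (u_pre > 0)
        grads["W1"] = h.T @ du
        grads["b1"] = du.sum(axis=0)
        dh = du @ p["W1"].T
        if self.arch == "arc1":
            ca, cb = cache_arch
            F = self.n_filters
            dWa, dba = self._conv1d_pool_back(ca, dh[:, :F])
            dWb, dbb = self._conv1d_pool_back(cb, dh[:, F:])
            grads["Wc"] = dWa + dWb
            grads["bc"] = dba + dbb
        else:
            win, Z, idx, pooled_shape = cache_arch
            dpooled = dh.reshape(pooled_shape)
            B, Ph, Pw, F = Z.shape
            dA = np.zeros_like(Z)
            bi = np.arange(B)[:, None, None, None]
            fi = np.arange(F)[None, None, None, :]
            np.add.at(dA, (bi, idx[..., 0], idx[..., 1], fi), dpooled)
            dZ = dA * (Z > 0)
            grads["Wc"] = np.einsum("bpqkl,bpqf->klf", win, dZ)
            grads["bc"] = dZ.sum(axis=(0, 1, 2))
        return grads

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        if self.embeddings is None or not hasattr(self.embeddings, "vectors_"):
            raise ValueError("a fitted embeddings model is required")
        pairs = _as_token_lists(X)
        y = np.asarray(y, dtype=np.int64)
        if len(pairs) != y.size:
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if not np.all(np.isin(classes, [0, 1])):
            raise ValueError("labels must be 0 (irrelevant) or 1 (relevant)")
        if classes.size < 2:
            raise ValueError("both classes must be present to train")
        self.classes_ = np.array([0, 1])

        longest = max(max(len(a), len(b)) for a, b in pairs)
        self.pad_len_ = max(min(self.max_len, longest), self.kernel)
        if self.arch == "matchpyramid":
            self.grid_ = min(self.pool_grid, self.pad_len_ - self.kernel + 1)
        rng = np.random.default_rng(self.seed)
        self.E_ = self.embeddings.padded_matrix()
        self.params_ = self._init_params(rng)
        opt = Adam(self.params_, lr=self.lr)

        Xa, Xb, la, lb = self._encode(pairs)
        n = y.size
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                s, _, cache = self._forward(Xa[idx], Xb[idx], la[idx], lb[idx])
                yb = y[idx]
                epoch_loss += bce_loss(s, yb) * idx.size
                dz = ((s - yb) / idx.size)[:, None]
                grads = self._backward(Xa[idx], Xb[idx], cache, dz)
                opt.step(grads)
            self.loss_history_.append(epoch_loss / n)
        return self

    def _batched_forward(self, X, chunk: int = 256):
        pairs = _as_token_lists(X)
        Xa, Xb, la, lb = self._encode(pairs)
        scores, vectors = [], []
        for start in range(0, len(pairs), chunk):
            sl = slice(start, start + chunk)
            s, u, _ = self._forward(Xa[sl], Xb[sl], la[sl], lb[sl])
            scores.append(s)
            vectors.append(u)
        return np.concatenate(scores), np.vstack(vectors)

    def predict_proba(self, X) -> np.ndarray:
        s, _ = self._batched_forward(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def transform(self, X) -> np.ndarray:
        """Relevance vectors (n_pairs, hidden_dim)."""
        _, u = self._batched_forward(X)
        return u

    def relevance_outputs(self, X) -> list[RelevanceOutput]:
        """Score and vector for each pair in one pass."""
        s, u = self._batched_forward(X)
        return [RelevanceOutput(float(si), ui) for si, ui in zip(s, u)]

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint the fitted model (weights + embeddings + a JSON config
        manifest) to an ``.npz`` file."""
        import json

        manifest = {
            k: v for k, v in self.get_params(deep=False).items() if k != "embeddings"
        }
        manifest["pad_len_"] = int(self.pad_len_)
        if self.arch == "matchpyramid":
            manifest["grid_"] = int(self.grid_)
        emb = self.embeddings
        vocab = sorted(emb.vocabulary_, key=emb.vocabulary_.get)
        np.savez_compressed(
            path,
            manifest=json.dumps(manifest),
            emb_vocab=np.array(vocab, dtype=object),
            emb_vectors=emb.vectors_,
            emb_counts=emb.counts_,
            **{f"p_{k}": v for k, v in self.params_.items()},
        )

    @classmethod
    def load(cls, path) -> "RelevanceClassifier":
        import json

        with np.load(path, allow_pickle=True) as data:
            manifest = json.loads(str(data["manifest"]))
            emb = SkipGramEmbeddings(dim=int(data["emb_vectors"].shape[1]))
            emb.vocabulary_ = {t: i for i, t in enumerate(data["emb_vocab"])}
            emb.vectors_ = data["emb_vectors"]
            emb.counts_ = data["emb_counts"]
            pad_len = manifest.pop("pad_len_")
            grid = manifest.pop("grid_", None)
            model = cls(embeddings=emb, **manifest)
            model.pad_len_ = pad_len
            if grid is not None:
                model.grid_ = grid
            model.classes_ = np.array([0, 1])
            model.E_ = emb.padded_matrix()
            model.params_ = {
                k[2:]: data[k] for k in data.files if k.startswith("p_")
            }
        return model


def _adaptive_maxpool(A: np.ndarray, g: int):
    """Max-pool (B, Ph, Pw, F) onto a g x g grid; returns pooled values and
    the (row, col) argmax indices needed for backprop."""
    B, Ph, Pw, F = A.shape
    re = np.linspace(0, Ph, g + 1).astype(int)
    ce = np.linspace(0, Pw, g + 1).astype(int)
    pooled = np.empty((B, g, g, F))
    idx = np.empty((B, g, g, F, 2), dtype=np.int64)
    for i in range(g):
        for j in range(g):
            block = A[:, re[i] : re[i + 1], ce[j] : ce[j + 1], :]
            h, w = block.shape[1], block.shape[2]
            flat = block.reshape(B, h * w, F)
            am = flat.argmax(axis=1)
            pooled[:, i, j, :] = np.take_along_axis(flat, am[:, None, :], axis=1)[:, 0, :]
            idx[:, i, j, :, 0] = re[i] + am // w
            idx[:, i, j, :, 1] = ce[j] + am % w
    return pooled, idx


# -- thin operation wrappers -------------------------------------------------


def train_relevance_model(
    pairs: Sequence[RelevancePair],
    arch: str = "arc1",
    embeddings: SkipGramEmbeddings | None = None,
    seed: int = 0,
    **hyper,
) -> RelevanceClassifier:
    """Train a relevance model on labeled pairs; returns the fitted estimator
    (its ``loss_history_`` holds the training-loss trajectory)."""
    y = [p.label for p in pairs]
    if any(v is None for v in y):
        raise ValueError("all pairs must be labeled")
    if embeddings is None:
        corpus = [list(p.tokens_a) for p in pairs] + [list(p.tokens_b) for p in pairs]
        embeddings = SkipGramEmbeddings(seed=seed).fit(corpus)
    return RelevanceClassifier(
        embeddings=embeddings, arch=arch, seed=seed, **hyper
    ).fit(pairs, y)


def _single_forward(pair: RelevancePair, model: RelevanceClassifier) -> RelevanceOutput:
    return model.relevance_outputs([pair])[0]


def arc1_forward(pair: RelevancePair, model: RelevanceClassifier) -> RelevanceOutput:
    """Score one pair with a representation-based (ARC-I style) model."""
    if model.arch != "arc1":
        raise ValueError("model is not an arc1 architecture")
    return _single_forward(pair, model)


def matchpyramid_forward(
    pair: RelevancePair, model: RelevanceClassifier
) -> RelevanceOutput:
    """Score one pair with an interaction-based (MatchPyramid style) model."""
    if model.arch != "matchpyramid":
        raise ValueError("model is not a matchpyramid architecture")
    return _single_forward(pair, model)
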