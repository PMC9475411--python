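"""Influence-relationship classification from combined features.

For a relationship triple (p_A, p_B, p_C) the features are the two relevance
vectors/scores (V_AB/P_AB between initial post and reply, V_BC/P_BC between
reply and counter-reply) and the two dense signals of the counter-reply:
question probability Q and action probability A.

Two combiners are provided:

* the *baseline* product rule — score = P_AB * P_BC * max(Q, A), with a
  positive label only when each component clears its threshold
  (0.5, 0.5, 0.9 by default);
* the *deep* feature-fusion network — V_AB and V_BC are each combined with Q
  and A via ``cat`` (append the scalar) or ``dot`` (scale elementwise),
  giving four vectors that pass through four dense+ReLU layers (summarized
  vectors S_1..S_4), are concatenated, pass a merge dense+ReLU layer, and end
  in a 2-way softmax.  Training minimizes binary cross-entropy with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import Adam, glorot, relu, softmax
from .signals import (
    QuestionRuleTable,
    annotate_sentences,
    post_action_prob,
    post_question_prob,
    tokenize,
)
from .threads import Relationship, Thread

__all__ = [
    "FeatureBundle",
    "InfluencePrediction",
    "combine",
    "baseline_classify",
    "BaselineInfluenceClassifier",
    "DeepInfluenceClassifier",
    "build_feature_bundle",
    "build_feature_bundles",
    "deep_forward",
    "train_deep",
]


@dataclass(frozen=True)
class FeatureBundle:
    """All features of one relationship triple."""

    v_ab: np.ndarray
    v_bc: np.ndarray
    q: float
    a: float
    p_ab: float
    p_bc: float

    def __post_init__(self):
        if self.v_ab.shape != self.v_bc.shape:
            raise ValueError("v_ab and v_bc must have the same width")


@dataclass(frozen=True)
class InfluencePrediction:
    """Influence score plus the thresholded label in {+1, -1}."""

    score: float
    label: int


def combine(v: np.ndarray, s: float, op: str) -> np.ndarray:
    """The feature-combination operator: ``dot`` scales the vector by the
    scalar elementwise; ``cat`` appends the scalar as an extra dimension."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("vector must be non-empty")
    if not 0.0 <= s <= 1.0:
        raise ValueError("scalar must lie in [0, 1]")
    if op == "dot":
        return s * v
    if op == "cat":
        return np.append(v, s)
    raise ValueError(f"unknown combine op {op!r}")


def _check_unit(name: str, x: float) -> float:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name}={x} outside [0, 1]")
    return float(x)


def baseline_classify(
    p_ab: float,
    p_bc: float,
    q: float,
    a: float,
    thresholds: tuple[float, float, float] = (0.5, 0.5, 0.9),
) -> InfluencePrediction:
    """Product-rule baseline: the score multiplies the three components and
    the label is positive only when every component clears its threshold."""
    p_ab = _check_unit("p_ab", p_ab)
    p_bc = _check_unit("p_bc", p_bc)
    q = _check_unit("q", q)
    a = _check_unit("a", a)
    qa = max(q, a)
    score = p_ab * p_bc * qa
    t1, t2, t3 = thresholds
    label = 1 if (p_ab >= t1 and p_bc >= t2 and qa >= t3) else -1
    return InfluencePrediction(score=score, label=label)


def _bundle_arrays(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(X, (tuple, list)) and len(X) == 4 and isinstance(X[0], np.ndarray):
        v_ab, v_bc, q, a = X
        return (
            np.asarray(v_ab, float),
            np.asarray(v_bc, float),
            np.asarray(q, float),
            np.asarray(a, float),
        )
    v_ab = np.vstack([b.v_ab for b in X])
    v_bc = np.vstack([b.v_bc for b in X])
    q = np.array([b.q for b in X], float)
    a = np.array([b.a for b in X], float)
    return v_ab, v_bc, q, a


class BaselineInfluenceClassifier(BaseEstimator, ClassifierMixin):
    """Estimator wrapper around the product-rule baseline (no learning)."""

    def __init__(self, thresholds: tuple[float, float, float] = (0.5, 0.5, 0.9)):
        self.thresholds = thresholds

    def fit(self, X=None, y=None):
        self.classes_ = np.array([-1, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        """The product score P_AB * P_BC * max(Q, A) per bundle."""
        scores = []
        for b in X:
            scores.append(baseline_classify(b.p_ab, b.p_bc, b.q, b.a).score)
        return np.array(scores)

    def predict(self, X) -> np.ndarray:
        labels = []
        for b in X:
            labels.append(
                baseline_classify(b.p_ab, b.p_bc, b.q, b.a, self.thresholds).label
            )
        return np.array(labels, dtype=np.int64)


class DeepInfluenceClassifier(BaseEstimator, ClassifierMixin):
    """The deep feature-fusion combiner.

    Parameters
    ----------
    combine_op : ``"dot"`` or ``"cat"`` — how Q and A attach to the relevance
        vectors (``cat`` adds one input dimension to dense layers 1-4).
    hidden_dim : width of each summarized vector S_1..S_4.
    merge_dim : width of the merge dense layer.
    threshold : decision threshold on the softmax positive-class probability.
    pos_weight : optional loss weight for the positive class (imbalance aid);
        ``None`` means unweighted.
    epochs, batch_size, lr, seed : Adam schedule; ``epochs=0`` keeps the
        seeded random initialization.
    """

    def __init__(
        self,
        combine_op: str = "dot",
        hidden_dim: int = 32,
        merge_dim: int = 32,
        threshold: float = 0.5,
        pos_weight: float | None = None,
        epochs: int = 30,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        self.combine_op = combine_op
        self.hidden_dim = hidden_dim
        self.merge_dim = merge_dim
        self.threshold = threshold
        self.pos_weight = pos_weight
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    # -- internals ----------------------------------------------------------

    def _combine_batch(self, V: np.ndarray, s: np.ndarray) -> np.ndarray:
        if self.combine_op == "dot":
            return V * s[:, None]
        if self.combine_op == "cat":
            return np.hstack([V, s[:, None]])
        raise ValueError(f"unknown combine op {self.combine_op!r}")

    def _init_params(self, rng: np.random.Generator, d_in: int):
        H, M = self.hidden_dim, self.merge_dim
        p: dict[str, np.ndarray] = {}
        for i in range(1, 5):
            p[f"W{i}"] = glorot(rng, d_in, H)
            p[f"b{i}"] = np.zeros(H)
        p["Wm"] = glorot(rng, 4 * H, M)
        p["bm"] = np.zeros(M)
        # zero-init the output layer so training starts at the uniform
        # class distribution rather than a saturated softmax
        p["Wo"] = np.zeros((M, 2))
        p["bo"] = np.zeros(2)
        return p

    def _forward(self, v_ab, v_bc, q, a):
        p = self.params_
        inputs = (
            self._combine_batch(v_ab, q),
            self._combine_batch(v_ab, a),
            self._combine_batch(v_bc, q),
            self._combine_batch(v_bc, a),
        )
        pre = [X @ p[f"W{i + 1}"] + p[f"b{i + 1}"] for i, X in enumerate(inputs)]
        S = [relu(z) for z in pre]  # summarized vectors S_1..S_4
        Scat = np.hstack(S)
        m_pre = Scat @ p["Wm"] + p["bm"]
        m = relu(m_pre)
        logits = m @ p["Wo"] + p["bo"]
        probs = softmax(logits)
        return probs, (inputs, pre, Scat, m_pre, m)

    def _backward(self, cache, dlogits):
        p = self.params_
        inputs, pre, Scat, m_pre, m = cache
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = m.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dm = (dlogits @ p["Wo"].T) * (m_pre > 0)
        grads["Wm"] = Scat.T @ dm
        grads["bm"] = dm.sum(axis=0)
        dScat = dm @ p["Wm"].T
        H = self.hidden_dim
        for i in range(4):
            dSi = dScat[:, i * H : (i + 1) * H] * (pre[i] > 0)
            grads[f"W{i + 1}"] = inputs[i].T @ dSi
            grads[f"b{i + 1}"] = dSi.sum(axis=0)
        return grads

    @property
    def n_parameters_(self) -> int:
        return int(sum(v.size for v in self.params_.values()))

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        v_ab, v_bc, q, a = _bundle_arrays(X)
        y = np.asarray(y)
        y01 = np.where(y > 0, 1, 0).astype(np.int64)  # {+1,-1} -> {1,0}
        if np.unique(y01).size < 2:
            raise ValueError("both classes must be present to train")
        self.classes_ = np.array([-1, 1])
        self.vector_width_ = v_ab.shape[1]
        d_in = self.vector_width_ + (1 if self.combine_op == "cat" else 0)
        rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(rng, d_in)
        opt = Adam(self.params_, lr=self.lr)
        w = np.where(y01 == 1, self.pos_weight or 1.0, 1.0)

        n = y01.size
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                probs, cache = self._forward(v_ab[idx], v_bc[idx], q[idx], a[idx])
                yb, wb = y01[idx], w[idx]
                ll = -np.log(np.clip(probs[np.arange(idx.size), yb], 1e-12, None))
                loss = float((wb * ll).sum() / wb.sum())
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at step {len(self.loss_history_)}: "
                        f"{loss}"
                    )
                epoch_loss += loss * idx.size
                onehot = np.zeros_like(probs)
                onehot[np.arange(idx.size), yb] = 1.0
                dlogits = (wb[:, None] * (probs - onehot)) / wb.sum()
                opt.step(self._backward(cache, dlogits))
            self.loss_history_.append(epoch_loss / n)
        return self

    def predict_proba(self, X) -> np.ndarray:
        v_ab, v_bc, q, a = _bundle_arrays(X)
        if v_ab.shape[1] != self.vector_width_:
            raise ValueError(
                f"bundle width {v_ab.shape[1]} != model width {self.vector_width_}"
            )
        probs, _ = self._forward(v_ab, v_bc, q, a)
        return probs

    def predict(self, X) -> np.ndarray:
        scores = self.predict_proba(X)[:, 1]
        return np.where(scores >= self.threshold, 1, -1).astype(np.int64)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint weights plus a JSON config manifest to an ``.npz``."""
        import json

        manifest = dict(self.get_params(deep=False))
        manifest["vector_width_"] = int(self.vector_width_)
        np.savez_compressed(
            path,
            manifest=json.dumps(manifest),
            **{f"p_{k}": v for k, v in self.params_.items()},
        )

    @classmethod
    def load(cls, path) -> "DeepInfluenceClassifier":
        import json

        with np.load(path, allow_pickle=True) as data:
            manifest = json.loads(str(data["manifest"]))
            width = manifest.pop("vector_width_")
            model = cls(**manifest)
            model.vector_width_ = width
            model.classes_ = np.array([-1, 1])
            model.params_ = {
                k[2:]: data[k] for k in data.files if k.startswith("p_")
            }
        return model


# -- feature assembly --------------------------------------------------------


def build_feature_bundles(
    relationships: Sequence[Relationship],
    threads: dict[str, Thread],
    relevance_model,
    rules: QuestionRuleTable | None = None,
) -> list[FeatureBundle]:
    """Assemble feature bundles for many triples with batched relevance calls."""
    pairs = []
    qa = []
    for rel in relationships:
        thread = threads[rel.thread_id]
        try:
            pa, pb, pc = (thread.post(i) for i in (rel.a_id, rel.b_id, rel.c_id))
        except KeyError as exc:
            raise ValueError(f"relationship references missing post: {exc}") from exc
        if not pc.sentences:
            pc = annotate_sentences(pc)
        pairs.append((tokenize(pa.text), tokenize(pb.text)))
        pairs.append((tokenize(pb.text), tokenize(pc.text)))
        qa.append((post_question_prob(pc, rules), post_action_prob(pc)))
    outputs = relevance_model.relevance_outputs(pairs)
    bundles = []
    for i, (q, a) in enumerate(qa):
        ab, bc = outputs[2 * i], outputs[2 * i + 1]
        bundles.append(
            FeatureBundle(
                v_ab=ab.vector, v_bc=bc.vector, q=q, a=a,
                p_ab=ab.score, p_bc=bc.score,
            )
        )
    return bundles


def build_feature_bundle(
    rel: Relationship,
    thread: Thread,
    relevance_model,
    rules: QuestionRuleTable | None = None,
) -> FeatureBundle:
    """Features for a single triple (see :func:`build_feature_bundles`)."""
    return build_feature_bundles([rel], {rel.thread_id: thread}, relevance_model, rules)[0]


# -- thin operation wrappers -------------------------------------------------


def deep_forward(bundle: FeatureBundle, model: DeepInfluenceClassifier) -> InfluencePrediction:
    """Score one bundle with a trained deep combiner."""
    score = float(model.predict_proba([bundle])[0, 1])
    return InfluencePrediction(score=score, label=1 if score >= model.threshold else -1)


def train_deep(
    bundles: Sequence[FeatureBundle],
    labels: Sequence[int],
    combine_op: str = "dot",
    seed: int = 0,
    **hyper,
) -> DeepInfluenceClassifier:
    """Train the deep combiner on labeled bundles (labels in {+1, -1})."""
    return DeepInfluenceClassifier(combine_op=combine_op, seed=seed, **hyper).fit(
        bundles, labels
    )
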