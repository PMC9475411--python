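"""Feature combination: the product-rule baseline and the deep combiner."""

import numpy as np
import pytest

from ohcinfluence.influence import (
    BaselineInfluenceClassifier,
    DeepInfluenceClassifier,
    FeatureBundle,
    baseline_classify,
    build_feature_bundle,
    combine,
    deep_forward,
    train_deep,
)
from ohcinfluence.metrics import compute_metrics
from ohcinfluence.relevance import RelevanceClassifier
from ohcinfluence.signals import annotate_sentences, tokenize
from ohcinfluence.synthetic import make_worked_example_thread
from ohcinfluence.threads import Relationship, extract_relationships


class TestCombine:
    def test_dot_is_elementwise_product(self):
        np.testing.assert_allclose(combine(np.array([1, 2, 3]), 0.5, "dot"),
                                   [0.5, 1.0, 1.5])

    def test_dot_identity_and_annihilator(self):
        v = np.array([0.3, -1.2, 4.0])
        np.testing.assert_array_equal(combine(v, 1.0, "dot"), v)
        np.testing.assert_array_equal(combine(v, 0.0, "dot"), np.zeros(3))

    def test_cat_appends_scalar(self):
        out = combine(np.array([1.0, 2.0, 3.0]), 0.9, "cat")
        assert out.shape == (4,)
        np.testing.assert_allclose(out, [1, 2, 3, 0.9])

    def test_errors(self):
        with pytest.raises(ValueError):
            combine(np.array([]), 0.5, "dot")
        with pytest.raises(ValueError):
            combine(np.array([1.0]), 1.5, "dot")
        with pytest.raises(ValueError):
            combine(np.array([1.0]), 0.5, "sum")


def brute_force_baseline(p_ab, p_bc, q, a, thresholds=(0.5, 0.5, 0.9)):
    """Independent re-statement of the product rule and its three cuts."""
    score = p_ab * p_bc * (q if q > a else a)
    ok = (p_ab >= thresholds[0]) and (p_bc >= thresholds[1]) and (
        (q if q > a else a) >= thresholds[2]
    )
    return score, (1 if ok else -1)


class TestBaseline:
    def test_all_maximal(self):
        out = baseline_classify(1, 1, 1, 0.5)
        assert out.score == 1.0 and out.label == 1

    def test_product_arithmetic(self):
        out = baseline_classify(0.6, 0.7, 0.95, 0.5)
        assert out.score == pytest.approx(0.399)
        assert out.label == 1

    def test_threshold_overrides_score(self):
        out = baseline_classify(0.4, 0.9, 1.0, 1.0)
        assert out.score == pytest.approx(0.36)
        assert out.label == -1

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            baseline_classify(1.2, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            baseline_classify(0.5, 0.5, -0.1, 0.5)

    def test_oracle_equivalence_on_random_quadruples(self):
        rng = np.random.default_rng(2024)
        X = rng.random((10_000, 4))
        for p_ab, p_bc, q, a in X:
            got = baseline_classify(p_ab, p_bc, q, a)
            score, label = brute_force_baseline(p_ab, p_bc, q, a)
            assert got.score == pytest.approx(score)
            assert got.label == label

    def test_estimator_wrapper(self):
        bundles = [
            FeatureBundle(np.ones(4), np.ones(4), q=1.0, a=0.5, p_ab=0.9, p_bc=0.8),
            FeatureBundle(np.ones(4), np.ones(4), q=0.0, a=0.5, p_ab=0.9, p_bc=0.8),
        ]
        clf = BaselineInfluenceClassifier().fit()
        np.testing.assert_array_equal(clf.predict(bundles), [1, -1])
        np.testing.assert_allclose(clf.decision_function(bundles), [0.72, 0.36])


def _synthetic_bundles(seed=7, n=400, width=16):
    """Bundles with recoverable structure: relevance vectors cluster by the
    gold pair relevance, and the label follows the influence definition."""
    rng = np.random.default_rng(seed)
    proto_rel = rng.normal(size=width)
    proto_irr = rng.normal(size=width)

    def vec(relevant):
        base = proto_rel if relevant else proto_irr
        return base + 0.4 * rng.normal(size=width)

    bundles, labels = [], []
    for _ in range(n):
        rel_ab = rng.random() < 0.7
        rel_bc = rng.random() < 0.7
        q = 1.0 if rng.random() < 0.4 else 0.0
        a = 1.0 if rng.random() < 0.4 else 0.5
        bundles.append(
            FeatureBundle(
                v_ab=vec(rel_ab), v_bc=vec(rel_bc), q=q, a=a,
                p_ab=0.8 if rel_ab else 0.3, p_bc=0.8 if rel_bc else 0.3,
            )
        )
        labels.append(1 if (rel_ab and rel_bc and (q == 1.0 or a == 1.0)) else -1)
    return bundles, np.array(labels)


@pytest.fixture(scope="module")
def bundle_corpus():
    return _synthetic_bundles()


class TestDeepCombiner:
    def test_softmax_outputs_sum_to_one(self, bundle_corpus):
        bundles, y = bundle_corpus
        model = DeepInfluenceClassifier(epochs=2, seed=1).fit(bundles[:100], y[:100])
        probs = model.predict_proba(bundles[100:140])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_inference_deterministic(self, bundle_corpus):
        bundles, y = bundle_corpus
        model = DeepInfluenceClassifier(epochs=2, seed=1).fit(bundles[:100], y[:100])
        a = model.predict_proba(bundles[:20])
        b = model.predict_proba(bundles[:20])
        np.testing.assert_array_equal(a, b)

    def test_dot_annihilation_gives_constant_score(self, bundle_corpus):
        bundles, y = bundle_corpus
        model = DeepInfluenceClassifier(combine_op="dot", epochs=2, seed=1)
        model.fit(bundles[:100], y[:100])
        width = bundles[0].v_ab.size
        zeroed = [
            FeatureBundle(np.full(width, v), np.full(width, -v), q=0.0, a=0.0,
                          p_ab=0.5, p_bc=0.5)
            for v in (1.0, 7.0, -3.0)
        ]
        scores = model.predict_proba(zeroed)[:, 1]
        assert np.ptp(scores) == 0.0

    def test_width_mismatch_raises(self, bundle_corpus):
        bundles, y = bundle_corpus
        model = DeepInfluenceClassifier(epochs=1, seed=1).fit(bundles[:60], y[:60])
        bad = [FeatureBundle(np.ones(3), np.ones(3), q=0.5, a=0.5,
                             p_ab=0.5, p_bc=0.5)]
        with pytest.raises(ValueError, match="width"):
            model.predict_proba(bad)

    def test_cat_has_one_extra_input_dimension_and_more_params(self, bundle_corpus):
        bundles, y = bundle_corpus
        dot = DeepInfluenceClassifier(combine_op="dot", epochs=1, seed=1)
        cat = DeepInfluenceClassifier(combine_op="cat", epochs=1, seed=1)
        dot.fit(bundles[:60], y[:60])
        cat.fit(bundles[:60], y[:60])
        for i in range(1, 5):
            assert cat.params_[f"W{i}"].shape[0] == dot.params_[f"W{i}"].shape[0] + 1
        assert cat.n_parameters_ > dot.n_parameters_

    def test_label_convention_invariance(self, bundle_corpus):
        # {+1,-1} and {1,0} labels are the same training problem
        bundles, y = bundle_corpus
        m1 = DeepInfluenceClassifier(epochs=2, seed=5).fit(bundles[:80], y[:80])
        m2 = DeepInfluenceClassifier(epochs=2, seed=5).fit(
            bundles[:80], (y[:80] > 0).astype(int)
        )
        for k in m1.params_:
            np.testing.assert_array_equal(m1.params_[k], m2.params_[k])
        assert set(np.unique(m1.predict(bundles[80:120]))) <= {-1, 1}

    def test_single_class_raises(self, bundle_corpus):
        bundles, y = bundle_corpus
        with pytest.raises(ValueError, match="both classes"):
            DeepInfluenceClassifier().fit(bundles[:10], np.ones(10))

    def test_nonfinite_features_raise_diagnostic(self, bundle_corpus):
        bundles, y = bundle_corpus
        width = bundles[0].v_ab.size
        bad = [FeatureBundle(np.full(width, np.inf), np.ones(width),
                             q=1.0, a=1.0, p_ab=0.5, p_bc=0.5)] * 4
        with np.errstate(all="ignore"), pytest.raises(RuntimeError, match="non-finite"):
            DeepInfluenceClassifier(epochs=1, batch_size=2).fit(
                bad + bundles[:4], [1, 1, -1, -1, 1, -1, 1, -1]
            )

    def test_backprop_matches_finite_differences(self, bundle_corpus):
        bundles, y = bundle_corpus
        model = DeepInfluenceClassifier(hidden_dim=6, merge_dim=5, epochs=0, seed=2)
        model.fit(bundles[:8], y[:8])
        jitter = np.random.default_rng(42)
        for P in model.params_.values():
            P += jitter.normal(scale=0.05, size=P.shape)
        from ohcinfluence.influence import _bundle_arrays

        v_ab, v_bc, q, a = _bundle_arrays(bundles[:6])
        y01 = (y[:6] > 0).astype(int)

        def loss():
            probs, _ = model._forward(v_ab, v_bc, q, a)
            return float(-np.mean(np.log(probs[np.arange(6), y01])))

        probs, cache = model._forward(v_ab, v_bc, q, a)
        onehot = np.zeros_like(probs)
        onehot[np.arange(6), y01] = 1.0
        grads = model._backward(cache, (probs - onehot) / 6)
        check = np.random.default_rng(0)
        eps = 1e-6
        for key, P in model.params_.items():
            for _ in range(4):
                idx = tuple(check.integers(0, d) for d in P.shape)
                orig = P[idx]
                P[idx] = orig + eps
                up = loss()
                P[idx] = orig - eps
                down = loss()
                P[idx] = orig
                num = (up - down) / (2 * eps)
                assert num == pytest.approx(grads[key][idx], rel=1e-3, abs=1e-7), key


class TestDeepTraining:
    def test_recovers_separable_structure(self, bundle_corpus):
        bundles, y = bundle_corpus
        train_b, test_b = bundles[:360], bundles[360:]
        y_train, y_test = y[:360], y[360:]
        dot = train_deep(train_b, y_train, combine_op="dot", seed=7)
        scores = dot.predict_proba(test_b)[:, 1]
        m_dot = compute_metrics(y_test, scores, threshold=dot.threshold)
        assert m_dot.roc_auc >= 0.85
        assert dot.loss_history_[-1] < dot.loss_history_[0]
        assert np.all(np.isfinite(dot.loss_history_))

        cat = train_deep(train_b, y_train, combine_op="cat", seed=7)
        m_cat = compute_metrics(y_test, cat.predict_proba(test_b)[:, 1],
                                threshold=cat.threshold)
        assert m_cat.recall <= m_dot.recall + 0.05

    def test_zero_epochs_is_chance_level(self, bundle_corpus):
        bundles, y = bundle_corpus
        model = DeepInfluenceClassifier(epochs=0, seed=3).fit(bundles[:100], y[:100])
        scores = model.predict_proba(bundles[100:300])[:, 1]
        m = compute_metrics(y[100:300], scores)
        assert 0.3 <= m.roc_auc <= 0.7


@pytest.fixture(scope="module")
def fixture_setup():
    thread = make_worked_example_thread().map_posts(annotate_sentences)
    corpus = [tokenize(p.text) for p in thread.posts]
    from ohcinfluence.embeddings import train_embeddings

    emb = train_embeddings(corpus, dim=8, seed=0, epochs=2)
    pairs = [(corpus[0], corpus[1]), (corpus[0], corpus[3])]
    model = RelevanceClassifier(embeddings=emb, hidden_dim=8, epochs=1,
                                seed=0).fit(pairs, [1, 0])
    return thread, model


class TestBuildFeatureBundle:
    def test_action_triple(self, fixture_setup):
        thread, model = fixture_setup
        rels = extract_relationships(thread)
        # the second chain's counter-reply states a plan ("I will bring up...")
        bundle = build_feature_bundle(rels[1], thread, model)
        assert bundle.a == 1.0
        assert bundle.v_ab.shape == (model.hidden_dim,)
        assert bundle.v_bc.shape == (model.hidden_dim,)
        assert 0.0 <= bundle.p_ab <= 1.0 and 0.0 <= bundle.p_bc <= 1.0

    def test_question_triple(self, fixture_setup):
        thread, model = fixture_setup
        rels = extract_relationships(thread)
        bundle = build_feature_bundle(rels[0], thread, model)
        assert bundle.q == 1.0

    def test_neutral_counter_reply(self, fixture_setup):
        thread, model = fixture_setup
        from ohcinfluence.threads import Post, Thread

        posts = [
            thread.post("pA"),
            thread.post("pB"),
            annotate_sentences(
                Post("pC2", "u1", 2, 2, "Thanks so much for the kind reply!")
            ),
        ]
        t2 = Thread("mini", posts, {"pB": "pA", "pC2": "pB"}, "pA")
        bundle = build_feature_bundle(
            Relationship("mini", "pA", "pB", "pC2"), t2, model
        )
        assert bundle.q == 0.0 and bundle.a == 0.5

    def test_missing_post_raises(self, fixture_setup):
        thread, model = fixture_setup
        with pytest.raises(ValueError, match="missing post"):
            build_feature_bundle(
                Relationship(thread.thread_id, "pA", "nope", "pC"), thread, model
            )

    def test_deep_forward_wrapper(self, fixture_setup, bundle_corpus):
        bundles, y = bundle_corpus
        model = DeepInfluenceClassifier(epochs=2, seed=1).fit(bundles[:100], y[:100])
        pred = deep_forward(bundles[150], model)
        assert 0.0 <= pred.score <= 1.0
        assert pred.label == (1 if pred.score >= 0.5 else -1)
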