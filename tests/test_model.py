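import numpy as np
import pytest

from ensembert.embedding import embed_texts
from ensembert.model import (
    HeadParameters,
    ItemInstance,
    ModelError,
    TrainConfig,
    _batch_forward,
    _batch_gradients,
    _batch_loss,
    build_instances,
    choice_similarities,
    combine,
    cross_attention,
    ensemble,
    featurize,
    forward,
    init_parameters,
    predict_user,
    softmax,
    submodel_a,
    submodel_b,
    train,
)
from conftest import fast_train_config


def _params(dim, seed=0, **kw):
    return init_parameters(dim, seed=seed, **kw)


def _zero_params(dim, **kw):
    return HeadParameters(
        W_out=np.zeros((4, dim)),
        b_out=np.zeros(4),
        W_ens=np.zeros((4, 8)),
        b_ens=np.zeros(4),
        **kw,
    )


class TestSoftmax:
    def test_hand_computed_two_logits(self):
        # e^1/(e^1+e^0) = 0.731058..., the logistic value at 1
        np.testing.assert_allclose(softmax([1.0, 0.0]), [0.7310585786, 0.2689414214], atol=1e-9)

    def test_shift_invariance_and_overflow_safety(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(softmax(x), softmax(x + 1000.0), atol=1e-12)
        assert np.all(np.isfinite(softmax([1e4, -1e4, 0.0, 5.0])))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        p = softmax(rng.standard_normal((6, 4)), axis=1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)


class TestCrossAttention:
    def test_single_post_gets_all_attention(self):
        RP = np.array([[2.0, 0.0, 1.0]])
        out = cross_attention(np.array([1.0, 1.0, 1.0]), RP)
        np.testing.assert_allclose(out.weights, [1.0])
        np.testing.assert_allclose(out.context, RP[0])

    def test_orthogonal_posts_get_equal_weights_and_mean_context(self):
        D = np.array([0.0, 0.0, 1.0])
        RP = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])  # both logits are 0
        out = cross_attention(D, RP)
        np.testing.assert_allclose(out.weights, [0.5, 0.5])
        np.testing.assert_allclose(out.context, [0.5, 0.5, 0.0])

    def test_hand_computed_logits(self):
        # logits = D @ RP.T = (1, 0) -> alpha = (0.7310..., 0.2689...)
        D = np.array([1.0, 0.0])
        RP = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = cross_attention(D, RP)
        np.testing.assert_allclose(out.weights, [0.7310585786, 0.2689414214], atol=1e-9)
        np.testing.assert_allclose(out.context, out.weights, atol=1e-12)

    def test_weights_are_a_distribution(self):
        rng = np.random.default_rng(3)
        out = cross_attention(rng.standard_normal(8), rng.standard_normal((17, 8)))
        assert out.weights.shape == (17,)
        assert np.all(out.weights > 0)
        assert out.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ModelError):
            cross_attention(np.zeros(3), np.zeros((2, 4)))


class TestChoiceSimilarities:
    def test_parallel_orthogonal_antiparallel(self):
        CA = np.array([1.0, 0.0])
        C = np.array([[2.0, 0.0], [0.0, 5.0], [-3.0, 0.0], [1.0, 1.0]])
        cs = choice_similarities(CA, C)
        np.testing.assert_allclose(cs, [1.0, 0.0, -1.0, 1.0 / np.sqrt(2)], atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        CA = rng.standard_normal(5)
        C = rng.standard_normal((4, 5))
        np.testing.assert_allclose(
            choice_similarities(CA, C), choice_similarities(3.7 * CA, C), atol=1e-12
        )

    def test_zero_norm_rejected(self):
        with pytest.raises(ModelError):
            choice_similarities(np.zeros(3), np.eye(3)[:3].repeat(2, 0)[:4].reshape(4, 3))


class TestSubmodelA:
    def test_equal_cosines_give_uniform(self):
        np.testing.assert_allclose(submodel_a(np.full(4, 0.3)), np.full(4, 0.25), atol=1e-12)

    def test_hand_computed_one_hot_logit(self):
        # cs=(1,0,0,0), tau=1: p0 = e/(e+3)
        e = np.e
        expected = np.array([e, 1, 1, 1]) / (e + 3)
        np.testing.assert_allclose(submodel_a(np.array([1.0, 0, 0, 0])), expected, atol=1e-12)

    def test_temperature_sharpens(self):
        cs = np.array([0.9, 0.1, 0.0, -0.2])
        assert submodel_a(cs, tau=5.0)[0] > submodel_a(cs, tau=1.0)[0]

    def test_zero_temperature_is_uniform(self):
        np.testing.assert_allclose(
            submodel_a(np.array([0.9, 0.1, 0.0, -0.2]), tau=0.0), np.full(4, 0.25), atol=1e-12
        )


class TestCombine:
    def test_one_hot_weights_select_the_choice(self):
        C = np.eye(4)
        RP = np.ones((2, 4))
        alpha = np.array([0.5, 0.5])
        out = combine(np.array([0.0, 0.0, 1.0, 0.0]), C, alpha, RP)
        # selected choice e_2 plus (alpha @ RP)/2 = 0.5 * ones
        np.testing.assert_allclose(out, np.array([0.5, 0.5, 1.5, 0.5]))

    def test_hand_computed_sum(self):
        C = np.array([[1.0, 0], [0, 1.0], [0, 0], [0, 0]])
        RP = np.array([[2.0, 2.0]])
        out = combine(np.array([0.5, 0.5, 0, 0]), C, np.array([1.0]), RP)
        # 0.5*C0 + 0.5*C1 + (1*RP0)/1 = (0.5,0.5) + (2,2)
        np.testing.assert_allclose(out, [2.5, 2.5])

    def test_convexity_bound_with_softmax_weights(self):
        rng = np.random.default_rng(2)
        C = rng.standard_normal((4, 6))
        RP = rng.standard_normal((5, 6))
        alpha = softmax(rng.standard_normal(5))
        pa = softmax(rng.standard_normal(4))
        out = combine(pa, C, alpha, RP)
        choice_part = out - (alpha @ RP) / 5
        assert np.all(choice_part <= C.max(axis=0) + 1e-12)
        assert np.all(choice_part >= C.min(axis=0) - 1e-12)

    def test_fixed_k_denominator(self):
        C = np.zeros((4, 2))
        RP = np.array([[10.0, 0.0]])
        alpha = np.array([1.0])
        retrieved = combine(np.full(4, 0.25), C, alpha, RP, post_denominator="retrieved")
        fixed = combine(np.full(4, 0.25), C, alpha, RP, post_denominator="fixed_k", k=20)
        np.testing.assert_allclose(retrieved, [10.0, 0.0])
        np.testing.assert_allclose(fixed, [0.5, 0.0])

    def test_cosine_mode_uses_raw_scores(self):
        C = np.eye(4)[:, :4]
        cs = np.array([0.2, -0.1, 0.4, 0.0])
        out = combine(None, C, np.array([1.0]), np.zeros((1, 4)), cs=cs, mode="cosine")
        np.testing.assert_allclose(out, cs)
        with pytest.raises(ModelError):
            combine(None, C, np.array([1.0]), np.zeros((1, 4)), mode="cosine")


class TestOutputLayers:
    def test_zero_parameters_give_uniform_everywhere(self):
        params = _zero_params(dim=6)
        np.testing.assert_allclose(submodel_b(np.ones(6), params), np.full(4, 0.25))
        np.testing.assert_allclose(
            ensemble(np.full(4, 0.25), np.full(4, 0.25), params), np.full(4, 0.25)
        )

    def test_against_independent_matmul_oracle(self):
        rng = np.random.default_rng(4)
        params = _params(dim=6, seed=4)
        combined = rng.standard_normal(6)
        pa = softmax(rng.standard_normal(4))
        pb = submodel_b(combined, params)

        def oracle_softmax(z):
            e = [np.exp(v - max(z)) for v in z]
            return np.array(e) / sum(e)

        z_b = [sum(params.W_out[r, c] * combined[c] for c in range(6)) + params.b_out[r]
               for r in range(4)]
        np.testing.assert_allclose(pb, oracle_softmax(z_b), atol=1e-12)

        x = list(pa) + list(pb)
        z_f = [sum(params.W_ens[r, c] * x[c] for c in range(8)) + params.b_ens[r]
               for r in range(4)]
        np.testing.assert_allclose(ensemble(pa, pb, params), oracle_softmax(z_f), atol=1e-12)


class TestForward:
    @staticmethod
    def _instance(dim=8, seed=0, n_posts=5):
        rng = np.random.default_rng(seed)
        return ItemInstance(
            description_embedding=rng.standard_normal(dim),
            choice_embeddings=rng.standard_normal((4, dim)),
            post_embeddings=rng.standard_normal((n_posts, dim)),
            gold_score=2,
            user_id="u",
            item_id=1,
        )

    def test_probability_contracts(self):
        pred = forward(self._instance(), _params(8))
        for p in (pred.probs_a, pred.probs_b, pred.probs_final):
            assert p.shape == (4,)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0)
        assert pred.alpha.sum() == pytest.approx(1.0, abs=1e-12)
        assert 0 <= pred.predicted_score <= 3

    def test_determinism(self):
        inst = self._instance(seed=5)
        p1 = forward(inst, _params(8, seed=1))
        p2 = forward(inst, _params(8, seed=1))
        np.testing.assert_array_equal(p1.probs_final, p2.probs_final)
        assert p1.predicted_score == p2.predicted_score

    def test_tie_breaks_toward_lowest_score(self):
        # zero parameters make every stage uniform, so all four final
        # probabilities tie at 0.25 and the argmax must pick score 0
        pred = forward(self._instance(), _zero_params(dim=8))
        np.testing.assert_allclose(pred.probs_final, np.full(4, 0.25))
        assert pred.predicted_score == 0

    def test_batch_forward_matches_single_instance_path(self):
        instances = [self._instance(seed=s) for s in range(6)]
        params = _params(8, seed=2)
        feats = featurize(instances, params_like=params)
        p = {"W_out": params.W_out, "b_out": params.b_out,
             "W_ens": params.W_ens, "b_ens": params.b_ens, "tau": params.tau}
        _, _, _, _, pf = _batch_forward(feats, np.arange(6), p, params.combine_mode)
        singles = np.stack([forward(i, params).probs_final for i in instances])
        np.testing.assert_allclose(pf, singles, atol=1e-12)

    def test_shape_validation(self):
        with pytest.raises(ModelError):
            ItemInstance(
                description_embedding=np.zeros(4),
                choice_embeddings=np.zeros((3, 4)),
                post_embeddings=np.zeros((2, 4)),
            )
        with pytest.raises(ModelError):
            ItemInstance(
                description_embedding=np.zeros(4),
                choice_embeddings=np.zeros((4, 4)),
                post_embeddings=np.zeros((0, 4)),
            )


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(7)
        dim, n = 5, 12
        instances = [
            ItemInstance(
                description_embedding=rng.standard_normal(dim),
                choice_embeddings=rng.standard_normal((4, dim)),
                post_embeddings=rng.standard_normal((3, dim)),
                gold_score=int(rng.integers(0, 4)),
                user_id=f"u{i % 4}",
            )
            for i in range(n)
        ]
        feats = featurize(instances)
        p = {
            "W_out": 0.3 * rng.standard_normal((4, dim)),
            "b_out": 0.1 * rng.standard_normal(4),
            "W_ens": 0.3 * rng.standard_normal((4, 8)),
            "b_ens": 0.1 * rng.standard_normal(4),
            "tau": 1.3,
        }
        idx = np.arange(n)
        la, lf = 0.7, 1.0
        grads = _batch_gradients(feats, idx, p, "softmax", la, lf)
        h = 1e-6
        for key in p:
            g_num = np.zeros_like(np.atleast_1d(np.asarray(p[key], dtype=float)))
            flat = np.atleast_1d(np.asarray(p[key], dtype=float)).ravel()
            for j in range(flat.size):
                for sign, store in ((+1, "plus"), (-1, "minus")):
                    pert = {k: (np.array(v, dtype=float) if np.ndim(v) else float(v))
                            for k, v in p.items()}
                    arr = np.atleast_1d(np.asarray(pert[key], dtype=float)).copy()
                    arr.ravel()[j] += sign * h
                    pert[key] = float(arr[0]) if np.ndim(p[key]) == 0 else arr.reshape(
                        np.shape(p[key])
                    )
                    loss = _batch_loss(feats, idx, pert, "softmax", la, lf)
                    if sign > 0:
                        loss_plus = loss
                    else:
                        loss_minus = loss
                g_num.ravel()[j] = (loss_plus - loss_minus) / (2 * h)
            g_ana = np.atleast_1d(np.asarray(grads[key], dtype=float))
            np.testing.assert_allclose(g_ana, g_num.reshape(g_ana.shape), atol=1e-5, rtol=1e-4)

    def test_loss_is_ce_of_the_two_heads(self):
        # lambda_a=0 must reduce the loss to the final CE alone
        rng = np.random.default_rng(9)
        dim = 4
        instances = [
            ItemInstance(
                description_embedding=rng.standard_normal(dim),
                choice_embeddings=rng.standard_normal((4, dim)),
                post_embeddings=rng.standard_normal((2, dim)),
                gold_score=int(rng.integers(0, 4)),
            )
            for _ in range(5)
        ]
        feats = featurize(instances)
        p = {"W_out": rng.standard_normal((4, dim)), "b_out": np.zeros(4),
             "W_ens": rng.standard_normal((4, 8)), "b_ens": np.zeros(4), "tau": 1.0}
        idx = np.arange(5)
        full = _batch_loss(feats, idx, p, "softmax", 1.0, 1.0)
        only_a = _batch_loss(feats, idx, p, "softmax", 1.0, 0.0)
        only_f = _batch_loss(feats, idx, p, "softmax", 0.0, 1.0)
        assert full == pytest.approx(only_a + only_f, abs=1e-10)


def _planted_instances(backend, questionnaire, rng, n_users=30, posts_per_item=3):
    """Separable instances: each item's retrieved posts ARE its gold-choice
    text embeddings, so the attended context points at the right choice."""
    desc = embed_texts(backend, [it.description for it in questionnaire]).vectors
    choice_texts = [[c.text for c in it.choices] for it in questionnaire]
    all_choice = embed_texts(
        backend, [t for row in choice_texts for t in row]
    ).vectors.reshape(len(questionnaire), 4, -1)
    out = []
    for u in range(n_users):
        for it in questionnaire:
            gold = int(rng.integers(0, 4))
            i = it.item_id - 1
            out.append(
                ItemInstance(
                    description_embedding=desc[i],
                    choice_embeddings=all_choice[i],
                    post_embeddings=np.tile(all_choice[i, gold], (posts_per_item, 1)),
                    gold_score=gold,
                    user_id=f"u{u}",
                    item_id=it.item_id,
                )
            )
    return out


class TestTraining:
    def test_loss_decreases_on_random_but_labelled_data(self, backend, questionnaire):
        rng = np.random.default_rng(0)
        instances = _planted_instances(backend, questionnaire, rng, n_users=10)
        params, log = train(instances, fast_train_config(epochs=40, patience=40))
        assert log.train_loss[-1] < log.train_loss[0]
        assert np.all(np.isfinite(log.train_loss))

    def test_planted_signal_is_learned(self, backend, questionnaire):
        rng = np.random.default_rng(1)
        instances = _planted_instances(backend, questionnaire, rng, n_users=30)
        params, _ = train(instances, fast_train_config(seed=1))
        preds = [forward(i, params).predicted_score for i in instances]
        acc = float(np.mean([p == i.gold_score for p, i in zip(preds, instances)]))
        assert acc > 0.9

    def test_shuffled_labels_stay_near_chance(self, backend, questionnaire):
        rng = np.random.default_rng(2)
        instances = _planted_instances(backend, questionnaire, rng, n_users=20)
        golds = np.array([i.gold_score for i in instances])
        shuffled = golds[rng.permutation(golds.size)]
        broken = [
            ItemInstance(
                description_embedding=i.description_embedding,
                choice_embeddings=i.choice_embeddings,
                post_embeddings=rng.standard_normal(i.post_embeddings.shape),
                gold_score=int(s),
                user_id=i.user_id,
                item_id=i.item_id,
            )
            for i, s in zip(instances, shuffled)
        ]
        params, _ = train(broken, fast_train_config(seed=2))
        # held-out planted data: the head trained on noise can do no better
        # than a constant/marginal predictor there
        fresh = _planted_instances(backend, questionnaire, np.random.default_rng(3), n_users=10)
        preds = [forward(i, params).predicted_score for i in fresh]
        per_class = np.bincount([i.gold_score for i in fresh], minlength=4) / len(fresh)
        acc = float(np.mean([p == i.gold_score for p, i in zip(preds, fresh)]))
        assert acc <= per_class.max() + 0.10

    def test_training_is_deterministic(self, backend, questionnaire):
        rng = np.random.default_rng(4)
        instances = _planted_instances(backend, questionnaire, rng, n_users=8)
        cfg = fast_train_config(seed=3, epochs=20, patience=20)
        p1, l1 = train(instances, cfg)
        p2, l2 = train(instances, cfg)
        np.testing.assert_array_equal(p1.W_out, p2.W_out)
        np.testing.assert_array_equal(p1.W_ens, p2.W_ens)
        assert p1.tau == p2.tau
        assert l1.train_loss == l2.train_loss

    def test_empty_and_unlabelled_inputs_rejected(self):
        with pytest.raises(ModelError):
            train([], fast_train_config())
        inst = ItemInstance(
            description_embedding=np.ones(3),
            choice_embeddings=np.eye(4)[:, :3] + 1,
            post_embeddings=np.ones((1, 3)),
            gold_score=None,
        )
        with pytest.raises(ModelError):
            train([inst], fast_train_config())


class TestSerialization:
    def test_save_load_round_trip_is_bitwise(self, tmp_path):
        params = _params(dim=16, seed=11, k=7, backend_id="mock:dim=16")
        params.tau = 1.2345678901234567
        path = tmp_path / "params.json"
        params.save(path)
        back = HeadParameters.load(path)
        np.testing.assert_array_equal(back.W_out, params.W_out)
        np.testing.assert_array_equal(back.b_out, params.b_out)
        np.testing.assert_array_equal(back.W_ens, params.W_ens)
        np.testing.assert_array_equal(back.b_ens, params.b_ens)
        assert back.tau == params.tau
        assert (back.dim, back.k, back.backend_id) == (16, 7, "mock:dim=16")
        assert back.combine_mode == params.combine_mode

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ModelError):
            HeadParameters(
                W_out=np.zeros((3, 5)), b_out=np.zeros(4),
                W_ens=np.zeros((4, 8)), b_ens=np.zeros(4),
            )
        with pytest.raises(ModelError):
            _zero_params(dim=4, combine_mode="nonsense")


class TestUserPrediction:
    def test_predict_user_sums_item_argmaxes(self, backend, questionnaire, small_cohort):
        corpus = small_cohort.corpora[0]
        params = _params(dim=backend.dim, seed=0, backend_id="mock")
        up = predict_user(corpus, questionnaire, params, backend, k=5)
        assert len(up.item_scores) == 21
        assert up.overall == sum(up.item_scores)
        assert len(up.predictions) == 21
        report = up.attention_report()
        assert len(report) == 21
        for row in report:
            assert sum(row["alpha"]) == pytest.approx(1.0, abs=1e-9)

    def test_build_instances_counts_and_gold(self, backend, questionnaire, small_cohort):
        corpora = list(small_cohort.corpora[:3])
        instances = build_instances(corpora, questionnaire, backend, k=5)
        assert len(instances) == 3 * 21
        for inst in instances:
            assert 1 <= inst.post_embeddings.shape[0] <= 5
            assert inst.gold_score in (0, 1, 2, 3)
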