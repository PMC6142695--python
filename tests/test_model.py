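import dataclasses

import numpy as np
import pytest

from cidrex.autograd import Tensor
from cidrex.embeddings import PAD_ID, TensorizedInstance
from cidrex.model import (
    ModelConfig,
    aggregate_knowledge,
    attention_weights,
    classify,
    convolve_sentences,
    encode_document,
    encode_sentence,
    forward,
    init_params,
    load_checkpoint,
    predict,
    predict_label,
    save_checkpoint,
    train,
)
from cidrex.autograd import cross_entropy


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept free of any cidrex model code)
# ---------------------------------------------------------------------------

def oracle_softmax(z):
    e = np.exp(z - z.max())
    return e / e.sum()


def oracle_attention(a_prime, W, r_e, m):
    scores = np.array([a_prime @ W @ r_e[k] / m for k in range(len(r_e))])
    return oracle_softmax(scores)


def oracle_aggregate(alpha, r_e, mode):
    if mode == "sum":
        return sum(alpha[k] * r_e[k] for k in range(len(alpha)))
    if mode == "max":
        return r_e[int(np.argmax(alpha))]
    return np.concatenate([alpha[k] * r_e[k] for k in range(len(alpha))])


def oracle_conv_maxpool(d_e, w_c, b_c, window):
    sums = []
    for i in range(d_e.shape[0] - window + 1):
        flat = d_e[i: i + window].reshape(-1)
        sums.append(np.maximum(flat @ w_c + b_c, 0.0))
    return np.max(np.stack(sums), axis=0)


def make_params(config, vocab=12, pos_vocab=6):
    return init_params(config, vocab, pos_vocab)


def random_instance(config, rng, vocab=12, pos_vocab=6, label=0):
    n_sent = int(rng.integers(1, config.n1 + 1))
    word = np.full((config.n1, config.n2), PAD_ID, dtype=np.int32)
    pos = np.full((config.n1, config.n2), PAD_ID, dtype=np.int32)
    for i in range(n_sent):
        ln = int(rng.integers(1, config.n2 + 1))
        word[i, :ln] = rng.integers(2, vocab, size=ln)
        pos[i, :ln] = rng.integers(2, pos_vocab, size=ln)
    title = np.full(config.n2, PAD_ID, dtype=np.int32)
    tl = int(rng.integers(1, config.n2 + 1))
    title[:tl] = rng.integers(2, vocab, size=tl)
    rel = np.sort(rng.choice(4, size=4, replace=True)).astype(np.int32)
    rel = np.asarray([0, 1, 2, 3], dtype=np.int32) if rng.random() < 0.5 else rel
    return TensorizedInstance(
        word_ids=word, pos_ids=pos, title_word_ids=title,
        title_pos_ids=np.where(title != PAD_ID, 2, PAD_ID).astype(np.int32),
        relation_ids=rel, label=label,
    )


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

class TestSentenceEncoder:
    def test_output_dimension(self, tiny_config):
        params = make_params(tiny_config)
        row = np.array([2, 3, 4] + [PAD_ID] * (tiny_config.n2 - 3), dtype=np.int32)
        pos = np.array([2, 2, 2] + [PAD_ID] * (tiny_config.n2 - 3), dtype=np.int32)
        out = encode_sentence(row, pos, params)
        assert out.shape == (1, 2 * tiny_config.h1)

    def test_all_pad_sentence_is_zero(self, tiny_config):
        params = make_params(tiny_config)
        row = np.full(tiny_config.n2, PAD_ID, dtype=np.int32)
        out = encode_sentence(row, row, params)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_padding_never_changes_result(self, tiny_config, rng):
        params = make_params(tiny_config)
        row = np.array([3, 4] + [PAD_ID] * (tiny_config.n2 - 2), dtype=np.int32)
        pos = np.array([2, 3] + [PAD_ID] * (tiny_config.n2 - 2), dtype=np.int32)
        short = encode_sentence(row[:2], pos[:2], params)
        padded = encode_sentence(row, pos, params)
        np.testing.assert_allclose(short.data, padded.data)

    def test_single_step_matches_hand_lstm(self):
        """A 1-token, 1-unit LSTM reproduces the gate equations evaluated
        by hand: i,f,o = sigmoid, g = tanh, c = i*g (zero initial state),
        h = o * tanh(c)."""
        config = ModelConfig(l1=1, l2=1, m=2, n1=2, n2=2, window=1,
                             filters=1, h1=1, h2=1, seed=0)
        params = make_params(config, vocab=3, pos_vocab=3)
        # fix the embeddings and forward-LSTM weights
        params.tensors["word_emb"].data[2] = [0.5]
        params.tensors["pos_emb"].data[2] = [-0.25]
        params.tensors["sent_f_Wx"].data[:] = np.array(
            [[0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8]]
        )
        params.tensors["sent_f_Wh"].data[:] = 0.0
        params.tensors["sent_f_b"].data[:] = np.array([0.0, 1.0, 0.0, -0.5])

        x = np.array([0.5, -0.25])
        gates = x @ params.tensors["sent_f_Wx"].data + params.tensors["sent_f_b"].data
        sig = lambda v: 1 / (1 + np.exp(-v))
        i, f, g, o = sig(gates[0]), sig(gates[1]), np.tanh(gates[2]), sig(gates[3])
        c = i * g
        h_expected = o * np.tanh(c)

        row = np.array([2, PAD_ID], dtype=np.int32)
        out = encode_sentence(row, row, params)
        assert abs(out.data[0, 0] - h_expected) < 1e-12


class TestDocumentEncoder:
    def test_document_dimension_contract(self, tiny_config, rng):
        params = make_params(tiny_config)
        inst = random_instance(tiny_config, rng)
        out = encode_document(inst, params)
        assert out.shape == (1, tiny_config.doc_dim)

    @pytest.mark.parametrize("h1,h2,f", [(4, 3, 5), (2, 7, 1), (5, 5, 8)])
    def test_shape_ledger_at_arbitrary_configs(self, h1, h2, f, rng):
        config = ModelConfig(l1=4, l2=2, m=3, n1=4, n2=6, window=2,
                             filters=f, h1=h1, h2=h2, seed=1)
        params = make_params(config)
        inst = random_instance(config, rng)
        out = encode_document(inst, params)
        assert out.shape == (1, 2 * h2 + f + 2 * h1)

    def test_default_config_doc_dim_is_960(self):
        assert ModelConfig().doc_dim == 960

    def test_zero_sentence_vectors_give_zero_conv(self, tiny_config):
        params = make_params(tiny_config)
        params.tensors["conv_b"].data[:] = 0.0
        d_e = Tensor(np.zeros((4, 2 * tiny_config.h1)))
        out = convolve_sentences(d_e, params)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_hand_computed_convolution_window_sums(self):
        """One all-ones filter over w=2 windows of [[1,0],[0,2],[3,0]]:
        window sums are 3 and 5, so the pooled value is 5."""
        config = ModelConfig(l1=1, l2=1, m=2, n1=3, n2=2, window=2,
                             filters=1, h1=1, h2=1, seed=0)
        params = make_params(config)
        params.tensors["conv_W"].data[:] = 1.0
        params.tensors["conv_b"].data[:] = 0.0
        d_e = Tensor(np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 0.0]]))
        out = convolve_sentences(d_e, params)
        assert out.data.reshape(-1)[0] == pytest.approx(5.0)

    def test_conv_matches_oracle_on_random_inputs(self, rng):
        config = ModelConfig(l1=2, l2=2, m=2, n1=6, n2=4, window=3,
                             filters=4, h1=3, h2=2, seed=3)
        params = make_params(config)
        for _ in range(20):
            d_e = rng.normal(size=(int(rng.integers(3, 7)), 2 * config.h1))
            ours = convolve_sentences(Tensor(d_e), params).data.reshape(-1)
            expected = oracle_conv_maxpool(
                d_e, params["conv_W"].data, params["conv_b"].data, config.window
            )
            np.testing.assert_allclose(ours, expected, atol=1e-10)


# ---------------------------------------------------------------------------
# Attention, aggregation, classification
# ---------------------------------------------------------------------------

class TestAttention:
    def test_zero_scores_give_uniform_weights(self, tiny_config, rng):
        params = make_params(tiny_config)
        params.tensors["att_W"].data[:] = 0.0
        a = Tensor(rng.normal(size=(1, tiny_config.doc_dim)))
        alpha, _ = attention_weights(a, np.array([0, 1, 2, 3]), params)
        np.testing.assert_allclose(alpha.data, 0.25)

    def test_closed_form_softmax(self):
        np.testing.assert_allclose(
            oracle_softmax(np.array([np.log(2), 0, 0, 0])),
            [0.4, 0.2, 0.2, 0.2],
        )

    def test_matches_independent_oracle(self, tiny_config, rng):
        params = make_params(tiny_config)
        for _ in range(25):
            a = rng.normal(size=(1, tiny_config.doc_dim))
            rel = rng.integers(0, 4, size=4)
            alpha, r_e = attention_weights(Tensor(a), rel, params)
            expected = oracle_attention(
                a.reshape(-1), params["att_W"].data,
                params["rel_emb"].data[rel], tiny_config.m,
            )
            np.testing.assert_allclose(alpha.data.reshape(-1), expected, atol=1e-9)
            assert alpha.data.min() >= 0
            assert alpha.data.sum() == pytest.approx(1.0)


class TestAggregation:
    def test_sum_with_one_hot_weights(self):
        alpha = Tensor(np.array([[1.0, 0.0, 0.0, 0.0]]))
        r_e = Tensor(np.array([[3.0, 4.0], [9, 9], [9, 9], [9, 9]]))
        out = aggregate_knowledge(alpha, r_e, "sum")
        np.testing.assert_allclose(out.data, [[3.0, 4.0]])

    def test_max_returns_unweighted_row(self):
        alpha = Tensor(np.array([[0.1, 0.7, 0.1, 0.1]]))
        r_e = Tensor(np.array([[1.0, 1], [5, -2], [0, 0], [0, 0]]))
        out = aggregate_knowledge(alpha, r_e, "max")
        np.testing.assert_array_equal(out.data, [[5.0, -2.0]])  # not 0.7*row

    def test_max_ties_break_to_lower_index(self):
        alpha = Tensor(np.full((1, 4), 0.25))
        r_e = Tensor(np.arange(8.0).reshape(4, 2))
        out = aggregate_knowledge(alpha, r_e, "max")
        np.testing.assert_array_equal(out.data, [[0.0, 1.0]])

    def test_con_concatenates_weighted_segments(self):
        alpha_v = np.array([[0.4, 0.3, 0.2, 0.1]])
        r_e_v = np.arange(8.0).reshape(4, 2)
        out = aggregate_knowledge(Tensor(alpha_v), Tensor(r_e_v), "con")
        assert out.shape == (1, 8)
        for k in range(4):
            np.testing.assert_allclose(
                out.data[0, 2 * k: 2 * k + 2], alpha_v[0, k] * r_e_v[k]
            )

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            aggregate_knowledge(Tensor(np.ones((1, 4))), Tensor(np.ones((4, 2))), "avg")

    def test_matches_oracle_all_modes(self, rng):
        for _ in range(20):
            alpha = oracle_softmax(rng.normal(size=4)).reshape(1, 4)
            r_e = rng.normal(size=(4, 3))
            for mode in ("sum", "max", "con"):
                ours = aggregate_knowledge(Tensor(alpha), Tensor(r_e), mode)
                np.testing.assert_allclose(
                    ours.data.reshape(-1),
                    oracle_aggregate(alpha.reshape(-1), r_e, mode),
                    atol=1e-12,
                )


class TestClassifier:
    def test_zero_weights_give_even_split_and_null_label(self, tiny_config, rng):
        params = make_params(tiny_config)
        params.tensors["softmax_W"].data[:] = 0.0
        params.tensors["softmax_b"].data[:] = 0.0
        a = Tensor(rng.normal(size=(1, tiny_config.doc_dim)))
        k = Tensor(rng.normal(size=(1, tiny_config.knowledge_dim)))
        logits = classify(a, k, params)
        _, p = cross_entropy(logits, 0)
        np.testing.assert_allclose(p, [0.5, 0.5])
        assert predict_label(p) == 0  # ties go to the negative class

    def test_log3_logit_gives_three_quarters(self):
        p = oracle_softmax(np.array([np.log(3), 0.0]))
        np.testing.assert_allclose(p, [0.75, 0.25])

    def test_classify_matches_softmax_oracle(self, tiny_config, rng):
        params = make_params(tiny_config)
        for _ in range(20):
            a = rng.normal(size=(1, tiny_config.doc_dim))
            k = rng.normal(size=(1, tiny_config.knowledge_dim))
            logits = classify(Tensor(a), Tensor(k), params)
            _, p = cross_entropy(logits, 0)
            d_s = np.concatenate([a, k], axis=1)
            expected = oracle_softmax(
                (d_s @ params["softmax_W"].data + params["softmax_b"].data).reshape(-1)
            )
            np.testing.assert_allclose(p, expected, atol=1e-10)
            assert p.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def separable_instances(config, rng, n=30):
    """Label 1 iff marker/mechanism (relation id 0) heads the sequence."""
    out = []
    for _ in range(n):
        label = int(rng.random() < 0.5)
        rel = np.array([0, 3, 3, 3] if label else [3, 3, 3, 3], dtype=np.int32)
        inst = random_instance(config, rng, label=label)
        inst.relation_ids = rel
        out.append(inst)
    return out


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        config = ModelConfig(l1=4, l2=2, m=3, n1=3, n2=6, window=2, filters=4,
                             h1=3, h2=3, epochs=8, seed=9, dropout=0.2)
        params = make_params(config)
        instances = separable_instances(config, rng, n=30)
        _, history = train(instances, params)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_identical_seed_identical_run(self, rng):
        config = ModelConfig(l1=3, l2=2, m=2, n1=2, n2=5, window=2, filters=2,
                             h1=2, h2=2, epochs=2, seed=4)
        instances = separable_instances(config, rng, n=10)
        runs = []
        for _ in range(2):
            params = make_params(config)
            trained, history = train(instances, params)
            runs.append((history[-1]["train_loss"],
                         trained["softmax_W"].data.copy()))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_empty_training_set_errors(self, tiny_config):
        with pytest.raises(ValueError, match="empty"):
            train([], make_params(tiny_config))


class TestPredict:
    def test_empty_input_empty_output(self, tiny_config):
        assert predict([], make_params(tiny_config)) == []

    def test_alpha_normalised_and_order_invariant(self, tiny_config, rng):
        params = make_params(tiny_config)
        instances = [random_instance(tiny_config, rng) for _ in range(6)]
        preds = predict(instances, params)
        for _, p_cid, alpha in preds:
            assert alpha.sum() == pytest.approx(1.0)
            assert (alpha >= 0).all()
            assert 0.0 <= p_cid <= 1.0
        shuffled = predict(instances[::-1], params)
        for fwd, rev in zip(preds, shuffled[::-1]):
            assert fwd[0] == rev[0]
            assert fwd[1] == pytest.approx(rev[1])


class TestNoKb:
    def test_no_kb_ignores_knowledge(self, tiny_config, rng):
        config = dataclasses.replace(tiny_config, use_kb=False)
        params = make_params(config)
        inst = random_instance(config, rng)
        logits1, _ = forward(inst, params)
        inst.relation_ids = np.array([3, 3, 3, 3], dtype=np.int32)
        logits2, _ = forward(inst, params)
        np.testing.assert_allclose(logits1.data, logits2.data)


class TestCheckpoint:
    def test_round_trip(self, tiny_config, rng, tmp_path):
        params = make_params(tiny_config)
        path = str(tmp_path / "model.npz")
        save_checkpoint(params, path, vocabs={"word": {"<PAD>": 0}})
        loaded, vocabs = load_checkpoint(path)
        assert vocabs["word"] == {"<PAD>": 0}
        assert loaded.config == params.config
        inst = random_instance(tiny_config, rng)
        a, _ = forward(inst, params)
        b, _ = forward(inst, loaded)
        np.testing.assert_array_equal(a.data, b.data)
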