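"""The document-level network with knowledge attention, and its training loop.

Architecture, bottom-up, for one candidate (chemical, disease) pair:

1. every token is the concatenation of its word embedding (l1) and PoS
   embedding (l2); each sentence runs through a bidirectional LSTM whose two
   final hidden states concatenate into the sentence vector S'_i (2*h1);
2. the sequence of sentence vectors D^e feeds (a) a document-level BLSTM
   whose final states give the long-range representation A^t (2*h2) and
   (b) a 1-D convolution over windows of w adjacent sentences with f filters,
   ReLU and max-over-positions pooling, giving the local-context
   representation A^c (f); the title runs through its own BLSTM to give the
   theme vector T' (2*h1); the document representation is
   A' = [A^t; A^c; T'];
3. the pair's knowledge-base relation sequence (4 slots over
   marker/mechanism, therapeutic, inferred, null) is embedded as rows r_k of
   R^e (4 x m); attention scores s_k = A' W r_k / m softmax-normalise to
   weights alpha, and the knowledge vector K' aggregates the weighted rows by
   one of three modes: ``sum`` (sum_k alpha_k r_k), ``max`` (the unweighted
   row with the largest alpha), or ``con`` (concatenation of all alpha_k r_k);
4. the classifier input is D_s = [beta1 A'; beta2 K'] and a softmax layer
   yields p(CID | document, pair).

Training minimises cross-entropy with RMSprop (lr 0.001), mini-batches of 8,
dropout 0.5 on the sentence-encoder output and the classifier input, with
best-dev-F checkpointing.  All randomness (init, shuffling, dropout) derives
from the config seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .autograd import Tensor, concat, cross_entropy, dropout, softmax
from .embeddings import PAD_ID, TensorizedInstance
from .knowledge import N_RELATIONS

logger = logging.getLogger("cidrex")

AGGREGATION_MODES = ("sum", "max", "con")


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the reference system's tuned values."""

    l1: int = 100  # word embedding size
    l2: int = 10  # PoS embedding size
    m: int = 200  # knowledge (relation) embedding size
    n1: int = 30  # max sentences per article
    n2: int = 120  # max words per sentence
    n3: int = N_RELATIONS
    window: int = 5  # CNN window over sentences
    filters: int = 300  # CNN filters
    h1: int = 110  # sentence/title BLSTM units per direction (concat 220)
    h2: int = 220  # document BLSTM units per direction (concat 440)
    mode: str = "sum"  # knowledge aggregation: sum | max | con
    beta1: float = 1.0
    beta2: float = 1.0
    dropout: float = 0.5
    lr: float = 0.001
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    use_kb: bool = True  # False zeroes K' (the "without KB" ablation)

    def __post_init__(self):
        if self.mode not in AGGREGATION_MODES:
            raise ValueError(f"unknown aggregation mode {self.mode!r}")
        if self.n3 != N_RELATIONS:
            raise ValueError("the relation sequence length is fixed at 4")
        for name in ("l1", "l2", "m", "n1", "n2", "window", "filters", "h1", "h2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def word_dim(self) -> int:
        return self.l1 + self.l2

    @property
    def doc_dim(self) -> int:
        """dim(A') = 2*h2 + f + 2*h1 (960 at defaults)."""
        return 2 * self.h2 + self.filters + 2 * self.h1

    @property
    def knowledge_dim(self) -> int:
        return 4 * self.m if self.mode == "con" else self.m

    @property
    def classifier_dim(self) -> int:
        return self.doc_dim + self.knowledge_dim


@dataclass
class ModelParams:
    """All learned tensors, keyed by name."""

    tensors: dict[str, Tensor]
    config: ModelConfig

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def zero_grads(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def copy(self) -> "ModelParams":
        return ModelParams(
            tensors={k: Tensor(v.data.copy()) for k, v in self.tensors.items()},
            config=copy.deepcopy(self.config),
        )


def _lstm_shapes(in_dim: int, hidden: int) -> dict[str, tuple[int, ...]]:
    return {"Wx": (in_dim, 4 * hidden), "Wh": (hidden, 4 * hidden), "b": (4 * hidden,)}


def init_params(
    config: ModelConfig,
    word_vocab_size: int,
    pos_vocab_size: int,
    word_matrix: np.ndarray | None = None,
    pos_matrix: np.ndarray | None = None,
    relation_matrix: np.ndarray | None = None,
) -> ModelParams:
    """Initialise all parameters uniform(-0.05, 0.05) from the config seed.

    Pretrained embedding matrices (word/PoS/relation), when given, override
    the random tables.  LSTM forget-gate biases start at 1.
    """
    rng = np.random.default_rng(config.seed)
    shapes: dict[str, tuple[int, ...]] = {
        "word_emb": (word_vocab_size, config.l1),
        "pos_emb": (pos_vocab_size, config.l2),
        "rel_emb": (N_RELATIONS, config.m),
        "conv_W": (config.window * 2 * config.h1, config.filters),
        "conv_b": (config.filters,),
        "att_W": (config.doc_dim, config.m),
        "softmax_W": (config.classifier_dim, 2),
        "softmax_b": (2,),
    }
    for enc, in_dim, hidden in (
        ("sent", config.word_dim, config.h1),
        ("title", config.word_dim, config.h1),
        ("doc", 2 * config.h1, config.h2),
    ):
        for direction in ("f", "b"):
            for part, shape in _lstm_shapes(in_dim, hidden).items():
                shapes[f"{enc}_{direction}_{part}"] = shape

    tensors: dict[str, Tensor] = {}
    for name, shape in shapes.items():
        data = rng.uniform(-0.05, 0.05, size=shape)
        if name.endswith("_b") and name not in ("softmax_b", "conv_b"):
            hidden = shape[0] // 4
            data = np.zeros(shape)
            data[hidden: 2 * hidden] = 1.0  # forget-gate bias
        tensors[name] = Tensor(data)
    if word_matrix is not None:
        tensors["word_emb"] = Tensor(np.array(word_matrix, dtype=np.float64))
    if pos_matrix is not None:
        tensors["pos_emb"] = Tensor(np.array(pos_matrix, dtype=np.float64))
    if relation_matrix is not None:
        if relation_matrix.shape != (N_RELATIONS, config.m):
            raise ValueError("relation matrix shape mismatch")
        tensors["rel_emb"] = Tensor(np.array(relation_matrix, dtype=np.float64))
    tensors["word_emb"].data[PAD_ID] = 0.0
    tensors["pos_emb"].data[PAD_ID] = 0.0
    return ModelParams(tensors=tensors, config=config)


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def _lstm_step(x, h, c, Wx, Wh, b, hidden):
    gates = x @ Wx + h @ Wh + b
    i = gates[:, 0:hidden].sigmoid()
    f = gates[:, hidden: 2 * hidden].sigmoid()
    g = gates[:, 2 * hidden: 3 * hidden].tanh()
    o = gates[:, 3 * hidden: 4 * hidden].sigmoid()
    c_new = f * c + i * g
    h_new = o * c_new.tanh()
    return h_new, c_new


def _run_lstm(
    x_seq: Tensor,  # (B, T, d)
    lengths: np.ndarray,  # (B,)
    params: ModelParams,
    prefix: str,
    hidden: int,
) -> Tensor:
    """Run a masked unidirectional LSTM; returns the last valid state (B, h).

    Steps past a row's length carry the previous state through, so padding
    never influences the result and an all-pad row stays the zero vector.
    """
    B, T, _ = x_seq.shape
    Wx, Wh, b = params[f"{prefix}_Wx"], params[f"{prefix}_Wh"], params[f"{prefix}_b"]
    h = Tensor(np.zeros((B, hidden)), requires_grad=False)
    c = Tensor(np.zeros((B, hidden)), requires_grad=False)
    for t in range(T):
        x_t = x_seq[:, t, :]
        h_new, c_new = _lstm_step(x_t, h, c, Wx, Wh, b, hidden)
        mask = (t < lengths).astype(np.float64).reshape(B, 1)
        if mask.all():
            h, c = h_new, c_new
        else:
            m = Tensor(mask, requires_grad=False)
            inv = Tensor(1.0 - mask, requires_grad=False)
            h = h_new * m + h * inv
            c = c_new * m + c * inv
    return h


def _reverse_rows(ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's first ``length`` entries, leaving padding in place."""
    out = ids.copy()
    for i, n in enumerate(lengths):
        out[i, :n] = ids[i, :n][::-1]
    return out


def _embed(word_ids: np.ndarray, pos_ids: np.ndarray, params: ModelParams) -> Tensor:
    w = params["word_emb"].take_rows(word_ids)
    p = params["pos_emb"].take_rows(pos_ids)
    return concat([w, p], axis=2)


def encode_sentences(
    word_ids: np.ndarray,  # (S, n2)
    pos_ids: np.ndarray,
    params: ModelParams,
    encoder: str = "sent",
) -> Tensor:
    """BLSTM-encode a batch of sentences into (S, 2*h1) vectors.

    The forward and backward LSTMs read the sentence in opposite directions;
    their final hidden states concatenate.  All-pad sentences yield zeros.
    """
    config = params.config
    lengths = (word_ids != PAD_ID).sum(axis=1)
    T = max(int(lengths.max()), 1)
    word_ids = word_ids[:, :T]
    pos_ids = pos_ids[:, :T]
    x_f = _embed(word_ids, pos_ids, params)
    h_f = _run_lstm(x_f, lengths, params, f"{encoder}_f", config.h1)
    x_b = _embed(
        _reverse_rows(word_ids, lengths), _reverse_rows(pos_ids, lengths), params
    )
    h_b = _run_lstm(x_b, lengths, params, f"{encoder}_b", config.h1)
    return concat([h_f, h_b], axis=1)


def encode_sentence(
    word_row: np.ndarray,
    pos_row: np.ndarray,
    params: ModelParams,
    encoder: str = "sent",
) -> Tensor:
    """Encode a single sentence; returns a (1, 2*h1) tensor."""
    return encode_sentences(
        word_row.reshape(1, -1), pos_row.reshape(1, -1), params, encoder
    )


def convolve_sentences(sentence_vectors: Tensor, params: ModelParams) -> Tensor:
    """f-filter convolution over windows of w adjacent sentence vectors,
    ReLU, then max pooling over window positions; returns (1, f).

    Articles shorter than one window are zero-padded up to w rows.
    """
    config = params.config
    w = config.window
    n = sentence_vectors.shape[0]
    if n < w:
        pad = Tensor(np.zeros((w - n, sentence_vectors.shape[1])), requires_grad=False)
        sentence_vectors = concat([sentence_vectors, pad], axis=0)
        n = w
    windows = concat(
        [sentence_vectors[i: i + w].reshape(1, -1) for i in range(n - w + 1)], axis=0
    )
    lc = (windows @ params["conv_W"] + params["conv_b"]).relu()
    return lc.max(axis=0).reshape(1, -1)


def encode_document(
    inst: TensorizedInstance,
    params: ModelParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Full document representation A' = [A^t; A^c; T'] of shape (1, doc_dim)."""
    config = params.config
    sent_mask = (inst.word_ids != PAD_ID).any(axis=1)
    n_real = max(int(sent_mask.sum()), 1)
    sent_vecs = encode_sentences(
        inst.word_ids[:n_real], inst.pos_ids[:n_real], params, "sent"
    )
    if training and rng is not None:
        sent_vecs = dropout(sent_vecs, config.dropout, rng, training)

    # Document BLSTM over the sentence sequence (batch of one).
    seq = sent_vecs.reshape(1, n_real, 2 * config.h1)
    lengths = np.asarray([n_real])
    a_t_f = _run_lstm(seq, lengths, params, "doc_f", config.h2)
    rev = sent_vecs.data.shape[0]
    seq_rev = concat(
        [sent_vecs[i: i + 1] for i in range(rev - 1, -1, -1)], axis=0
    ).reshape(1, n_real, 2 * config.h1)
    a_t_b = _run_lstm(seq_rev, lengths, params, "doc_b", config.h2)
    a_t = concat([a_t_f, a_t_b], axis=1)

    a_c = convolve_sentences(sent_vecs, params)

    title = encode_sentence(inst.title_word_ids, inst.title_pos_ids, params, "title")

    return concat([a_t, a_c, title], axis=1)


# ---------------------------------------------------------------------------
# Knowledge attention and classification
# ---------------------------------------------------------------------------

def attention_weights(
    a_prime: Tensor,
    relation_ids: np.ndarray,
    params: ModelParams,
) -> tuple[Tensor, Tensor]:
    """Score each knowledge relation against the document representation.

    s_k = (A' W r_k) / m, alpha = softmax(s); returns (alpha (1,4), R^e (4,m)).
    """
    config = params.config
    r_e = params["rel_emb"].take_rows(np.asarray(relation_ids))
    v = a_prime @ params["att_W"]  # (1, m)
    scores = (r_e @ v.reshape(config.m, 1)).reshape(1, N_RELATIONS) / config.m
    return softmax(scores, axis=1), r_e


def aggregate_knowledge(alpha: Tensor, r_e: Tensor, mode: str) -> Tensor:
    """Aggregate attention-weighted relation embeddings into K'.

    ``sum``: weighted sum (1, m); ``max``: the *unweighted* embedding row of
    the highest-weight relation, ties to the lower index (1, m); ``con``:
    concatenation of all weighted rows (1, 4m).
    """
    if mode == "sum":
        return alpha @ r_e
    if mode == "max":
        k = int(np.argmax(alpha.data.reshape(-1)))
        return r_e[k: k + 1, :]
    if mode == "con":
        parts = [alpha[:, k: k + 1] * r_e[k: k + 1, :] for k in range(N_RELATIONS)]
        return concat(parts, axis=1)
    raise ValueError(f"unknown aggregation mode {mode!r}")


def classify(
    a_prime: Tensor,
    k_prime: Tensor,
    params: ModelParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Logits of the softmax layer over {null, CID}: D_s W_s + b_s."""
    config = params.config
    d_s = concat([a_prime * config.beta1, k_prime * config.beta2], axis=1)
    if training and rng is not None:
        d_s = dropout(d_s, config.dropout, rng, training)
    return d_s @ params["softmax_W"] + params["softmax_b"]


def forward(
    inst: TensorizedInstance,
    params: ModelParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, np.ndarray]:
    """Run the whole network for one instance; returns (logits, alpha)."""
    config = params.config
    a_prime = encode_document(inst, params, training, rng)
    alpha_t, r_e = attention_weights(a_prime, inst.relation_ids, params)
    if config.use_kb:
        k_prime = aggregate_knowledge(alpha_t, r_e, config.mode)
    else:
        k_prime = Tensor(np.zeros((1, config.knowledge_dim)), requires_grad=False)
    logits = classify(a_prime, k_prime, params, training, rng)
    return logits, alpha_t.data.reshape(-1).copy()


def predict_label(probs: np.ndarray) -> int:
    """argmax with ties broken toward the negative class."""
    return 1 if probs[1] > probs[0] else 0


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _dev_f_score(instances: Sequence[TensorizedInstance], params: ModelParams) -> float:
    """Binary F on a held-out set (falls back to accuracy with no positives)."""
    tp = fp = fn = correct = 0
    for inst in instances:
        logits, _ = forward(inst, params, training=False)
        _, p = cross_entropy(logits, inst.label)
        pred = predict_label(p)
        correct += int(pred == inst.label)
        if pred == 1 and inst.label == 1:
            tp += 1
        elif pred == 1:
            fp += 1
        elif inst.label == 1:
            fn += 1
    if tp + fn == 0:
        return correct / max(len(instances), 1)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


def train(
    instances: Sequence[TensorizedInstance],
    params: ModelParams,
    dev: Sequence[TensorizedInstance] | None = None,
) -> tuple[ModelParams, list[dict]]:
    """RMSprop / cross-entropy training; returns (best params, history).

    With a dev set the parameters snapshotted at the best dev F are returned;
    otherwise the final-epoch parameters.  Deterministic under the config
    seed.
    """
    if not instances:
        raise ValueError("empty training set")
    config = params.config
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)
    cache = {k: np.zeros_like(t.data) for k, t in params.tensors.items()}
    rho, eps = 0.9, 1e-6
    history: list[dict] = []
    best_f, best_params = -1.0, None

    order = np.arange(len(instances))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        total_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [instances[i] for i in order[start: start + config.batch_size]]
            params.zero_grads()
            losses = []
            for inst in batch:
                logits, _ = forward(inst, params, training=True, rng=drop_rng)
                loss, _ = cross_entropy(logits, inst.label)
                losses.append(loss)
            batch_loss = sum(losses[1:], losses[0]) / len(losses)
            batch_loss.backward()
            total_loss += float(batch_loss.data) * len(batch)
            for name, t in params.tensors.items():
                if t.grad is None:
                    continue
                cache[name] = rho * cache[name] + (1 - rho) * t.grad**2
                t.data -= config.lr * t.grad / (np.sqrt(cache[name]) + eps)
        epoch_loss = total_loss / len(instances)
        record = {"epoch": epoch, "train_loss": epoch_loss}
        if dev:
            f = _dev_f_score(dev, params)
            record["dev_f"] = f
            if f > best_f:
                best_f, best_params = f, params.copy()
        history.append(record)
        logger.info("epoch %d: loss %.4f%s", epoch, epoch_loss,
                    f" dev F {record['dev_f']:.3f}" if dev else "")
    return (best_params if best_params is not None else params), history


def predict(
    instances: Sequence[TensorizedInstance],
    params: ModelParams,
) -> list[tuple[int, float, np.ndarray]]:
    """Per-instance (predicted label, P(CID), attention vector alpha).

    Inference is stateless: outputs do not depend on instance order, and the
    attention vector is exposed for inspection of which knowledge relation
    the model weighted most.
    """
    out = []
    for inst in instances:
        logits, alpha = forward(inst, params, training=False)
        _, p = cross_entropy(logits, inst.label)
        out.append((predict_label(p), float(p[1]), alpha))
    return out


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(
    params: ModelParams, path: str, vocabs: dict[str, dict[str, int]] | None = None
) -> None:
    """Single-file parameter archive with config (and vocabularies) as a
    JSON header."""
    arrays = {k: t.data for k, t in params.tensors.items()}
    header = {"config": asdict(params.config), "vocabs": vocabs or {}}
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> tuple[ModelParams, dict[str, dict[str, int]]]:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"].tobytes()))
        config = ModelConfig(**header["config"])
        tensors = {
            k: Tensor(archive[k].astype(np.float64))
            for k in archive.files
            if k != "__header__"
        }
    return ModelParams(tensors=tensors, config=config), header.get("vocabs", {})
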