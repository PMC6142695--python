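"""Vocabularies, embedding tables, and tensorization of token sequences.

Words and PoS tags each get an integer vocabulary (index 0 = PAD, 1 = UNK)
and an embedding table; a token's representation downstream is the
concatenation of its word vector (dimension l1, default 100) and PoS vector
(dimension l2, default 10).  Relation embeddings (dimension m, default 200)
use the fixed four-row relation vocabulary from :mod:`cidrex.knowledge`.

Tensorization clips/pads an article to a fixed n1 x n2 integer grid
(default 30 sentences x 120 words, head-truncated) so batching is
shape-stable regardless of content.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .knowledge import N_RELATIONS, relation_ids
from .preprocess import CandidateInstance, TokenizedDoc

PAD, UNK = "<PAD>", "<UNK>"
PAD_ID, UNK_ID = 0, 1


def build_vocab(tokens: Iterable[str], min_count: int = 1) -> dict[str, int]:
    """Frequency-sorted vocabulary with PAD/UNK prepended.

    Deterministic: ties broken lexicographically, so the same corpus always
    yields the same index assignment.
    """
    counts = Counter(tokens)
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    vocab = {PAD: PAD_ID, UNK: UNK_ID}
    for t in kept:
        vocab[t] = len(vocab)
    return vocab


@dataclass
class EmbeddingTable:
    """A vocabulary plus its |vocab| x dim embedding matrix (PAD row zero)."""

    vocab: dict[str, int]
    matrix: np.ndarray
    dim: int

    def ids(self, tokens: Sequence[str]) -> list[int]:
        return [self.vocab.get(t, UNK_ID) for t in tokens]


def init_table(
    vocab: dict[str, int],
    dim: int,
    seed: int = 0,
    pretrained: tuple[Sequence[str], np.ndarray] | None = None,
    zero_pad_row: bool = True,
) -> EmbeddingTable:
    """Initialise an embedding table, uniform(-0.05, 0.05) by default.

    Rows for tokens found in ``pretrained`` (a (vocab list, matrix) pair, as
    returned by the embedding-file loaders) are copied; everything else stays
    random.  The PAD row is zeroed so padded positions contribute nothing.
    """
    rng = np.random.default_rng(seed)
    matrix = rng.uniform(-0.05, 0.05, size=(len(vocab), dim))
    if pretrained is not None:
        pre_vocab, pre_matrix = pretrained
        if pre_matrix.shape[1] != dim:
            raise ValueError(
                f"pretrained dimension {pre_matrix.shape[1]} != requested {dim}"
            )
        index = {t: i for i, t in enumerate(pre_vocab)}
        for token, row in vocab.items():
            if token in index:
                matrix[row] = pre_matrix[index[token]]
    if zero_pad_row and PAD in vocab:
        matrix[vocab[PAD]] = 0.0
    return EmbeddingTable(vocab=dict(vocab), matrix=matrix, dim=dim)


@dataclass
class TensorizedInstance:
    """Fixed-shape integer encoding of one candidate pair in one article."""

    word_ids: np.ndarray  # (n1, n2) int32
    pos_ids: np.ndarray  # (n1, n2) int32
    title_word_ids: np.ndarray  # (n2,) int32
    title_pos_ids: np.ndarray  # (n2,) int32
    relation_ids: np.ndarray  # (4,) int32
    label: int  # 1 = CID, 0 = null
    candidate: CandidateInstance | None = None


def _pad_row(ids: list[int], n: int) -> list[int]:
    return ids[:n] + [PAD_ID] * max(0, n - len(ids))


def tensorize(
    tokdoc: TokenizedDoc,
    relation_seq: list[str],
    word_table: EmbeddingTable,
    pos_table: EmbeddingTable,
    n1: int = 30,
    n2: int = 120,
    label: int = 0,
    candidate: CandidateInstance | None = None,
) -> TensorizedInstance:
    """Clip/pad a tokenised article into the model's index grids.

    Over-long articles keep their first n1 sentences, over-long sentences
    their first n2 tokens; out-of-vocabulary tokens map to UNK.  Output
    shapes depend only on (n1, n2), never on content.
    """
    word_grid = np.full((n1, n2), PAD_ID, dtype=np.int32)
    pos_grid = np.full((n1, n2), PAD_ID, dtype=np.int32)
    for i, (sent, tags) in enumerate(zip(tokdoc.sentences, tokdoc.pos_tags)):
        if i >= n1:
            break
        word_grid[i] = _pad_row(word_table.ids(sent), n2)
        pos_grid[i] = _pad_row(pos_table.ids(tags), n2)
    title_words = np.asarray(_pad_row(word_table.ids(tokdoc.title_tokens), n2), dtype=np.int32)
    title_pos = np.asarray(_pad_row(pos_table.ids(tokdoc.title_tags), n2), dtype=np.int32)
    rel = np.asarray(relation_ids(relation_seq), dtype=np.int32)
    assert rel.shape == (N_RELATIONS,)
    return TensorizedInstance(
        word_ids=word_grid,
        pos_ids=pos_grid,
        title_word_ids=title_words,
        title_pos_ids=title_pos,
        relation_ids=rel,
        label=label,
        candidate=candidate,
    )
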