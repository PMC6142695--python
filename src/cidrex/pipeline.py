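"""End-to-end wiring: corpus -> candidates -> tensors -> model -> report.

These helpers connect the format readers, preprocessing, knowledge lookup,
embedding tables and the network into the runs the command-line interface
and the experiments perform.  Splitting is always at the document level so
no article leaks between train/dev/test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import Document, KnowledgeBase
from .embeddings import EmbeddingTable, TensorizedInstance, build_vocab, init_table, tensorize
from .knowledge import CANONICAL_ORDER, lookup_relations
from .model import ModelConfig, ModelParams, init_params, predict, train
from .posteval import EvalReport, evaluate
from .preprocess import (
    LABEL_CID,
    MARKERS,
    CandidateInstance,
    Tagger,
    build_candidates,
    substitute_mentions,
    suffix_tagger,
)

logger = logging.getLogger("cidrex")


# ---------------------------------------------------------------------------
# Corpus statistics (candidate-construction bookkeeping)
# ---------------------------------------------------------------------------

def corpus_statistics(
    documents: Sequence[Document], k: int = 4, apply_span_filter: bool = False
) -> dict:
    """Candidate-pair counts for a corpus: total pairs, gold CID pairs, and
    the inter-/intra-sentential breakdown of the gold pairs."""
    totals = {"cd_pairs": 0, "cid_pairs": 0, "inter_cid": 0, "intra_cid": 0}
    for doc in documents:
        for inst in build_candidates(doc, k=k, apply_span_filter=apply_span_filter):
            totals["cd_pairs"] += 1
            if inst.label == LABEL_CID:
                totals["cid_pairs"] += 1
                totals["inter_cid" if inst.stratum == "inter" else "intra_cid"] += 1
    return totals


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    instances: list[TensorizedInstance]  # model inputs (span-filtered out)
    candidates: list[CandidateInstance]  # all candidates incl. filtered positives
    word_table: EmbeddingTable = None
    pos_table: EmbeddingTable = None


def build_tables(
    documents: Sequence[Document],
    config: ModelConfig,
    tagger: Tagger = suffix_tagger,
    pretrained_words: tuple[Sequence[str], np.ndarray] | None = None,
) -> tuple[EmbeddingTable, EmbeddingTable]:
    """Word and PoS vocabularies + embedding tables over a document set.

    The candidate-pair boundary markers are added explicitly since they only
    appear after pair-specific substitution.
    """
    word_tokens: list[str] = list(MARKERS)
    pos_tokens: list[str] = []
    for doc in documents:
        tokdoc = substitute_mentions(doc, None, tagger=tagger)
        for sent, tags in zip(tokdoc.sentences, tokdoc.pos_tags):
            word_tokens.extend(sent)
            pos_tokens.extend(tags)
    word_vocab = build_vocab(word_tokens)
    pos_vocab = build_vocab(pos_tokens)
    word_table = init_table(word_vocab, config.l1, seed=config.seed,
                            pretrained=pretrained_words)
    pos_table = init_table(pos_vocab, config.l2, seed=config.seed + 17)
    return word_table, pos_table


def build_dataset(
    documents: Sequence[Document],
    kb: KnowledgeBase,
    word_table: EmbeddingTable,
    pos_table: EmbeddingTable,
    config: ModelConfig,
    k: int = 4,
    apply_span_filter: bool = False,
    tagger: Tagger = suffix_tagger,
) -> Dataset:
    """Tensorize every surviving candidate pair of a document set."""
    instances: list[TensorizedInstance] = []
    candidates: list[CandidateInstance] = []
    for doc in documents:
        tokdoc_plain = substitute_mentions(doc, None, tagger=tagger)
        doc_candidates = build_candidates(
            doc, k=k, apply_span_filter=apply_span_filter, tokdoc=tokdoc_plain
        )
        candidates.extend(doc_candidates)
        for cand in doc_candidates:
            if cand.filtered:
                continue  # gold positive removed by the span filter: FN only
            tokdoc = substitute_mentions(
                doc, (cand.chemical_id, cand.disease_id), tagger=tagger
            )
            relseq = lookup_relations(cand.chemical_id, cand.disease_id, kb)
            instances.append(
                tensorize(
                    tokdoc, relseq, word_table, pos_table,
                    n1=config.n1, n2=config.n2,
                    label=1 if cand.label == LABEL_CID else 0,
                    candidate=cand,
                )
            )
    return Dataset(instances=instances, candidates=candidates,
                   word_table=word_table, pos_table=pos_table)


def split_documents(
    documents: Sequence[Document],
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> tuple[list[Document], list[Document], list[Document]]:
    """Shuffle and split a document list into train/dev/test."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(documents))
    n_train = int(round(fractions[0] * len(documents)))
    n_dev = int(round(fractions[1] * len(documents)))
    docs = [documents[i] for i in order]
    return docs[:n_train], docs[n_train: n_train + n_dev], docs[n_train + n_dev:]


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    accuracy: float
    report: EvalReport
    mean_alpha_positive: dict[str, float]
    history: list[dict] = field(default_factory=list)
    params: ModelParams = None
    n_train: int = 0
    n_test: int = 0


def mean_alpha_by_type(
    instances: Sequence[TensorizedInstance],
    predictions: Sequence[tuple[int, float, np.ndarray]],
    only_positive: bool = True,
) -> dict[str, float]:
    """Average per-slot attention weight received by each relation type.

    A type's weight in one instance is the mean alpha over the slots holding
    it (the null padding can occupy several slots); instances where the type
    is absent do not contribute.  Averaged over gold-positive instances by
    default — the weight a relation attracts *when the knowledge base
    asserts it*, which is what attention-value inspection looks at.
    """
    sums = {r: 0.0 for r in CANONICAL_ORDER}
    counts = {r: 0 for r in CANONICAL_ORDER}
    for inst, (_, _, alpha) in zip(instances, predictions):
        if only_positive and inst.label != 1:
            continue
        per_type: dict[str, list[float]] = {}
        for slot, rel_id in enumerate(inst.relation_ids):
            per_type.setdefault(CANONICAL_ORDER[rel_id], []).append(float(alpha[slot]))
        for r, values in per_type.items():
            sums[r] += sum(values) / len(values)
            counts[r] += 1
    return {r: (sums[r] / counts[r] if counts[r] else 0.0) for r in CANONICAL_ORDER}


def run_experiment(
    train_docs: Sequence[Document],
    dev_docs: Sequence[Document],
    test_docs: Sequence[Document],
    kb: KnowledgeBase,
    config: ModelConfig,
    k: int = 4,
    span_filter_eval: bool = True,
) -> ExperimentResult:
    """Train on one split and measure held-out performance.

    Vocabularies come from the training documents only.  The span filter is
    applied to dev and test candidate sets (the training set keeps every
    pair), mirroring standard practice for this task.
    """
    word_table, pos_table = build_tables(train_docs, config)
    train_set = build_dataset(train_docs, kb, word_table, pos_table, config,
                              k=k, apply_span_filter=False)
    dev_set = build_dataset(dev_docs, kb, word_table, pos_table, config,
                            k=k, apply_span_filter=span_filter_eval)
    test_set = build_dataset(test_docs, kb, word_table, pos_table, config,
                             k=k, apply_span_filter=span_filter_eval)
    logger.info(
        "train/dev/test instances: %d/%d/%d",
        len(train_set.instances), len(dev_set.instances), len(test_set.instances),
    )
    params = init_params(config, len(word_table.vocab), len(pos_table.vocab),
                         word_matrix=word_table.matrix, pos_matrix=pos_table.matrix)
    params, history = train(train_set.instances, params, dev=dev_set.instances)

    preds = predict(test_set.instances, params)
    correct = sum(
        int(label == inst.label)
        for inst, (label, _, _) in zip(test_set.instances, preds)
    )
    accuracy = correct / max(len(test_set.instances), 1)
    positive_keys = [
        inst.candidate.key
        for inst, (label, _, _) in zip(test_set.instances, preds)
        if label == 1
    ]
    report = evaluate(positive_keys, test_set.candidates)
    alphas = mean_alpha_by_type(test_set.instances, preds, only_positive=True)
    return ExperimentResult(
        accuracy=accuracy,
        report=report,
        mean_alpha_positive=alphas,
        history=history,
        params=params,
        n_train=len(train_set.instances),
        n_test=len(test_set.instances),
    )
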