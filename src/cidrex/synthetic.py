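"""Synthetic corpus generator with controllable label-generating structure.

Produces PubTator-format articles, a matching knowledge table and a MeSH-tree
table entirely from a seed, so every stage of the system — parsing, candidate
construction, training, post-filtering, evaluation — is testable without any
external download.  Two independent, tunable signals connect inputs to gold
labels:

* ``knowledge_signal``: probability that a gold-positive pair carries
  ``marker/mechanism`` in the knowledge base while a gold-negative carries
  ``therapeutic`` or nothing.  At 1.0 the label is a deterministic function
  of knowledge-base content; at 0.0 the knowledge base is independent of the
  labels.
* ``text_signal``: probability that a lexical trigger token (``induced``)
  appears adjacent to the pair's mentions iff the pair is positive.  The
  trigger never occurs in filler text, so at 1.0 the label is recoverable
  from text alone.

``inter_fraction`` controls the share of positives whose entities never share
a sentence (roughly one third of real corpus relations are inter-sentential).
Entity identifiers are synthetic MeSH-like ids (``D9xxxxx``) so no real
vocabulary ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import (
    CHEMICAL,
    DISEASE,
    Document,
    KnowledgeBase,
    Mention,
    MeshTree,
    write_knowledge_table,
    write_mesh_tree,
    write_pubtator,
)

TRIGGER = "induced"


@dataclass
class SynthConfig:
    n_docs: int = 50
    sentences_per_doc: tuple[int, int] = (3, 6)
    entities_per_doc: tuple[int, int] = (2, 4)
    vocab_size: int = 50
    knowledge_signal: float = 1.0
    text_signal: float = 0.0
    inter_fraction: float = 0.3  # ~1/3 of real-corpus relations cross sentences
    label_noise: float = 0.0
    positive_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("knowledge_signal", "text_signal", "inter_fraction",
                     "label_noise", "positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if self.sentences_per_doc[0] < 2:
            raise ValueError("need at least 2 sentences per article")
        if self.entities_per_doc[0] < 2:
            raise ValueError("need at least one chemical and one disease")
        if self.entities_per_doc[1] > self.sentences_per_doc[0] * 6:
            raise ValueError("more entities than token slots: infeasible geometry")
        if self.vocab_size < 5:
            raise ValueError("vocab_size too small")


@dataclass
class SynthCorpus:
    documents: list[Document]
    kb: KnowledgeBase
    mesh_tree: MeshTree
    config: SynthConfig | None = None


def _filler(rng: np.random.Generator, vocab_size: int, n: int) -> list[str]:
    return [f"w{int(i):02d}" for i in rng.integers(0, vocab_size, size=n)]


def _assemble(
    doc_id: str,
    title_tokens: list[str],
    sentence_tokens: list[list[str]],
    entity_positions: list[tuple[int, int, str, str, str]],
) -> Document:
    """Join tokens into title/abstract text and compute mention offsets.

    ``entity_positions`` rows are (sentence index, token index, surface,
    entity type, concept id); sentence index -1 places the mention in the
    title.
    """
    title = " ".join(title_tokens)
    sent_strings = [" ".join(toks) + "." for toks in sentence_tokens]
    abstract = " ".join(sent_strings)
    text = title + " " + abstract

    # Char offset of token j in sentence i (title: i == -1).
    def offset(i: int, j: int) -> int:
        if i == -1:
            return sum(len(t) + 1 for t in title_tokens[:j])
        base = len(title) + 1 + sum(len(s) + 1 for s in sent_strings[:i])
        return base + sum(len(t) + 1 for t in sentence_tokens[i][:j])

    mentions = []
    for i, j, surface, etype, concept in entity_positions:
        start = offset(i, j)
        assert text[start: start + len(surface)] == surface
        mentions.append(
            Mention(start=start, end=start + len(surface), text=surface,
                    etype=etype, concept_id=concept)
        )
    return Document(doc_id=doc_id, title=title, abstract=abstract, mentions=mentions)


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate a corpus, knowledge base and tree table from the config seed.

    Deterministic: the same config yields byte-identical files.  Gold labels
    are drawn per candidate pair; the knowledge-base and lexical signals are
    then planted according to the config probabilities, and ``label_noise``
    finally flips gold annotations independently of the planted signals.
    """
    rng = np.random.default_rng(config.seed)
    kb = KnowledgeBase()
    tree = MeshTree()
    documents: list[Document] = []
    entity_counter = 0

    for d in range(config.n_docs):
        doc_id = str(10000 + d)
        n_sent = int(rng.integers(config.sentences_per_doc[0],
                                  config.sentences_per_doc[1] + 1))
        n_ent = int(rng.integers(config.entities_per_doc[0],
                                 config.entities_per_doc[1] + 1))
        n_chem = max(1, n_ent // 2)
        n_dis = max(1, n_ent - n_chem)

        chems, diseases = [], []
        for _ in range(n_chem):
            cid = f"D9{entity_counter:05d}"
            entity_counter += 1
            chems.append((f"chemical{cid[2:]}", cid))
        for _ in range(n_dis):
            did = f"D9{entity_counter:05d}"
            entity_counter += 1
            diseases.append((f"disease{did[2:]}", did))
            tree.tree_numbers[did] = {
                f"C{int(rng.integers(1, 99)):02d}.{int(rng.integers(100, 999)):03d}"
            }

        title_tokens = _filler(rng, config.vocab_size, int(rng.integers(3, 6)))
        sentences = [
            _filler(rng, config.vocab_size, int(rng.integers(5, 9)))
            for _ in range(n_sent)
        ]
        positions: list[tuple[int, int, str, str, str]] = []
        placed: dict[str, list[int]] = {}

        def place(surface: str, concept: str, etype: str, sent_idx: int,
                  after: str | None = None) -> None:
            toks = sentences[sent_idx]
            j = int(rng.integers(0, len(toks) + 1))
            toks.insert(j, surface)
            # shift recorded token indices in the same sentence
            fixed = []
            for (i0, j0, s0, e0, c0) in positions:
                if i0 == sent_idx and j0 >= j:
                    j0 += 1
                fixed.append((i0, j0, s0, e0, c0))
            positions.clear()
            positions.extend(fixed)
            positions.append((sent_idx, j, surface, etype, concept))
            placed.setdefault(concept, []).append(sent_idx)
            if after is not None:
                toks.insert(j + 1, after)
                fixed = []
                for (i0, j0, s0, e0, c0) in positions:
                    if i0 == sent_idx and j0 > j:
                        j0 += 1
                    fixed.append((i0, j0, s0, e0, c0))
                positions.clear()
                positions.extend(fixed)

        gold: set[tuple[str, str]] = set()
        for chem_surface, chem_id in chems:
            for dis_surface, dis_id in diseases:
                positive = rng.random() < config.positive_rate
                with_trigger = positive and rng.random() < config.text_signal
                inter = positive and rng.random() < config.inter_fraction

                if positive and inter and n_sent >= 2:
                    gap = int(rng.integers(1, min(3, n_sent - 1) + 1))
                    i = int(rng.integers(0, n_sent - gap))
                    place(chem_surface, chem_id, CHEMICAL, i,
                          after=TRIGGER if with_trigger else None)
                    place(dis_surface, dis_id, DISEASE, i + gap)
                elif positive:
                    i = int(rng.integers(0, n_sent))
                    place(chem_surface, chem_id, CHEMICAL, i,
                          after=TRIGGER if with_trigger else None)
                    place(dis_surface, dis_id, DISEASE, i)
                else:
                    if chem_id not in placed:
                        place(chem_surface, chem_id, CHEMICAL,
                              int(rng.integers(0, n_sent)))
                    if dis_id not in placed:
                        place(dis_surface, dis_id, DISEASE,
                              int(rng.integers(0, n_sent)))

                # Knowledge-base signal
                if rng.random() < config.knowledge_signal:
                    if positive:
                        kb.add(chem_id, dis_id, "marker/mechanism")
                        if rng.random() < 0.3:
                            kb.add(chem_id, dis_id, "inferred")
                    elif rng.random() < 0.5:
                        kb.add(chem_id, dis_id, "therapeutic")
                else:
                    for rel in ("marker/mechanism", "therapeutic", "inferred"):
                        if rng.random() < 0.25:
                            kb.add(chem_id, dis_id, rel)

                annotated = positive
                if rng.random() < config.label_noise:
                    annotated = not annotated
                if annotated:
                    gold.add((chem_id, dis_id))

        doc = _assemble(doc_id, title_tokens, sentences, positions)
        doc.gold_relations = gold
        documents.append(doc)

    return SynthCorpus(documents=documents, kb=kb, mesh_tree=tree, config=config)


def generate_hypernym_case(
    seed: int, n_docs: int = 8
) -> tuple[list[Document], MeshTree, set[tuple[str, str, str]]]:
    """Articles exercising the hypernymy post-filter, with the expected
    demotion set computable in closed form.

    Each article mentions one chemical, a general disease and a strict
    MeSH-tree descendant of it.  In even-numbered articles the general
    disease also appears in the title and must survive the filter; in
    odd-numbered ones it does not and a positive prediction for
    (chemical, general disease) must be demoted.
    """
    rng = np.random.default_rng(seed)
    tree = MeshTree()
    documents: list[Document] = []
    expected_demoted: set[tuple[str, str, str]] = set()

    for d in range(n_docs):
        doc_id = str(90000 + d)
        chem_id, gen_id, spec_id = (
            f"D95{d:04d}", f"D96{d:04d}", f"D97{d:04d}"
        )
        chem_s, gen_s, spec_s = f"chemical{d}", f"generaldis{d}", f"specificdis{d}"
        branch = f"C{int(rng.integers(1, 99)):02d}.{int(rng.integers(100, 999)):03d}"
        tree.tree_numbers[gen_id] = {branch}
        tree.tree_numbers[spec_id] = {f"{branch}.{int(rng.integers(100, 999)):03d}"}

        in_title = d % 2 == 0
        title_tokens = ["study", "of", gen_s, "outcomes"] if in_title \
            else ["study", "of", "treatment", "outcomes"]
        sentences = [
            ["patients", "received", chem_s, "daily"],
            ["several", "developed", spec_s, "afterwards"],
            ["history", "of", gen_s, "was", "common"],
        ]
        positions = [
            (0, 2, chem_s, CHEMICAL, chem_id),
            (1, 2, spec_s, DISEASE, spec_id),
            (2, 2, gen_s, DISEASE, gen_id),
        ]
        if in_title:
            positions.append((-1, 2, gen_s, DISEASE, gen_id))
        doc = _assemble(doc_id, title_tokens, sentences, positions)
        doc.gold_relations = {(chem_id, spec_id)}
        documents.append(doc)
        if not in_title:
            expected_demoted.add((doc_id, chem_id, gen_id))

    return documents, tree, expected_demoted


def write_corpus(corpus: SynthCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write corpus.pubtator, knowledge.tsv and mesh_tree.tsv into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": outdir / "corpus.pubtator",
        "knowledge": outdir / "knowledge.tsv",
        "mesh_tree": outdir / "mesh_tree.tsv",
    }
    with open(paths["corpus"], "w") as fh:
        write_pubtator(corpus.documents, fh)
    with open(paths["knowledge"], "w") as fh:
        write_knowledge_table(corpus.kb, fh)
    with open(paths["mesh_tree"], "w") as fh:
        write_mesh_tree(corpus.mesh_tree, fh)
    return paths
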