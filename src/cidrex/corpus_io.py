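"""Readers and writers for the file formats around chemical-disease relation extraction.

The corpus format is PubTator: per-article blocks of a ``|t|`` title line and an
``|a|`` abstract line, followed by tab-separated mention lines (six columns:
doc id, start, end, surface text, entity type, MeSH concept id) and relation
lines (four columns: doc id, ``CID``, chemical id, disease id), with blank
lines between articles.  Character offsets are 0-based half-open over the
concatenation ``title + " " + abstract``.

Also handled here: the chemical-disease knowledge table (a flat dump of
curated (chemical, disease) -> relation-type rows), the MeSH tree-number
table used by the hypernymy post-filter, and plain-text embedding files
(word2vec text format for words/PoS, labelled rows for relation vectors).

All MeSH identifiers are normalised identically on every read path: the
``MESH:`` prefix is stripped and the id upper-cased, so corpus, knowledge
table and tree table agree on pair keys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

logger = logging.getLogger("cidrex")

#: Relation types a chemical-disease pair may carry in the knowledge base.
#: "null" is a padding symbol used downstream, never stored in the table.
RELATION_TYPES = ("marker/mechanism", "therapeutic", "inferred")
NULL_RELATION = "null"

CHEMICAL = "Chemical"
DISEASE = "Disease"


class ParseError(ValueError):
    """Raised for malformed input lines; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


def normalize_mesh_id(raw: str) -> str:
    """Strip a ``MESH:`` prefix and upper-case a MeSH identifier."""
    raw = raw.strip()
    if raw.upper().startswith("MESH:"):
        raw = raw[5:]
    return raw.upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mention:
    """One annotated entity mention inside an article."""

    start: int
    end: int
    text: str
    etype: str  # CHEMICAL or DISEASE
    concept_id: str  # normalised MeSH id, or "-1" when unmapped

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad mention span [{self.start}, {self.end})")
        if self.etype not in (CHEMICAL, DISEASE):
            raise ValueError(f"unknown entity type {self.etype!r}")


@dataclass
class Document:
    """One article: title, abstract, gold mentions and gold CID relations."""

    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    gold_relations: set[tuple[str, str]] = field(default_factory=set)

    @property
    def text(self) -> str:
        """Title and abstract joined by one space; mention offsets index this."""
        return self.title + " " + self.abstract


@dataclass
class KnowledgeBase:
    """Map (chemical MeSH id, disease MeSH id) -> set of relation types."""

    entries: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def relations_for(self, chemical_id: str, disease_id: str) -> set[str]:
        key = (normalize_mesh_id(chemical_id), normalize_mesh_id(disease_id))
        return set(self.entries.get(key, ()))

    def add(self, chemical_id: str, disease_id: str, relation: str) -> None:
        if relation not in RELATION_TYPES:
            raise ValueError(f"unknown relation type {relation!r}")
        key = (normalize_mesh_id(chemical_id), normalize_mesh_id(disease_id))
        self.entries.setdefault(key, set()).add(relation)


@dataclass
class MeshTree:
    """MeSH id -> set of dot-delimited tree numbers (e.g. ``C12.777.419``)."""

    tree_numbers: dict[str, set[str]] = field(default_factory=dict)

    def numbers_for(self, mesh_id: str) -> set[str]:
        return set(self.tree_numbers.get(normalize_mesh_id(mesh_id), ()))


def is_tree_number(s: str) -> bool:
    """A tree number is a letter + digits head with dot-separated numeric tails."""
    parts = s.split(".")
    head = parts[0]
    if len(head) < 2 or not head[0].isalpha() or not head[1:].isdigit():
        return False
    return all(p.isdigit() for p in parts[1:])


# ---------------------------------------------------------------------------
# PubTator corpus
# ---------------------------------------------------------------------------

def _split_concept_ids(raw: str) -> list[str]:
    # Composite ids like "D001|D002" become separate mentions sharing the span.
    return [normalize_mesh_id(p) for p in raw.replace("+", "|").split("|") if p.strip()]


def read_pubtator(stream: Iterable[str]) -> list[Document]:
    """Parse a PubTator-format stream into :class:`Document` objects.

    Malformed lines (wrong column count, non-integer offsets, unknown entity
    type) raise :class:`ParseError` naming the line.  A mention whose span
    does not match the article text is kept but logged as a warning.
    """
    docs: list[Document] = []
    current: Document | None = None

    def flush():
        nonlocal current
        if current is not None:
            _check_offsets(current)
            docs.append(current)
            current = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            flush()
            continue
        if "|t|" in line or "|a|" in line:
            doc_id, kind, text = line.split("|", 2)
            if current is not None and current.doc_id != doc_id:
                flush()
            if current is None:
                current = Document(doc_id=doc_id, title="", abstract="")
            if kind == "t":
                current.title = text
            elif kind == "a":
                current.abstract = text
            else:
                raise ParseError(f"unknown section {kind!r}", lineno)
            continue
        fields = line.split("\t")
        if current is None:
            raise ParseError("annotation line before any title line", lineno)
        if len(fields) == 4 and fields[1] == "CID":
            _, _, chem, dis = fields
            current.gold_relations.add((normalize_mesh_id(chem), normalize_mesh_id(dis)))
        elif len(fields) == 6:
            doc_id, start_s, end_s, text, etype, concept = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"non-integer offsets {start_s!r}/{end_s!r}", lineno)
            if etype not in (CHEMICAL, DISEASE):
                raise ParseError(f"unknown entity type {etype!r}", lineno)
            ids = _split_concept_ids(concept) or ["-1"]
            for cid in ids:
                current.mentions.append(
                    Mention(start=start, end=end, text=text, etype=etype, concept_id=cid)
                )
        else:
            raise ParseError(
                f"expected 6 mention columns or 4 relation columns, got {len(fields)}",
                lineno,
            )
    flush()
    return docs


def _check_offsets(doc: Document) -> None:
    text = doc.text
    for m in doc.mentions:
        if m.end > len(text) or text[m.start:m.end] != m.text:
            logger.warning(
                "doc %s: mention %r at [%d,%d) does not match article text",
                doc.doc_id, m.text, m.start, m.end,
            )
    known = {m.concept_id for m in doc.mentions}
    for chem, dis in doc.gold_relations:
        if chem not in known or dis not in known:
            logger.warning(
                "doc %s: gold relation (%s, %s) references unseen concept id",
                doc.doc_id, chem, dis,
            )


def write_pubtator(
    documents: Iterable[Document],
    stream: IO[str],
    include_relations: bool = True,
) -> None:
    """Serialise documents back to PubTator text (inverse of :func:`read_pubtator`)."""
    for doc in documents:
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in doc.mentions:
            stream.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}\t{m.etype}\t{m.concept_id}\n"
            )
        if include_relations:
            for chem, dis in sorted(doc.gold_relations):
                stream.write(f"{doc.doc_id}\tCID\t{chem}\t{dis}\n")
        stream.write("\n")


def write_predictions(
    documents: Iterable[Document],
    predictions: Iterable[tuple],
    stream: IO[str],
) -> None:
    """Emit predicted-positive pairs as PubTator relation lines.

    ``predictions`` rows are ``(doc_id, chemical_id, disease_id, label, score)``
    where a truthy / ``"CID"`` label marks a positive.  Output round-trips
    through :func:`read_pubtator`.
    """
    by_doc: dict[str, set[tuple[str, str]]] = {}
    for doc_id, chem, dis, label, *_ in predictions:
        if label in (1, True, "CID"):
            by_doc.setdefault(str(doc_id), set()).add(
                (normalize_mesh_id(chem), normalize_mesh_id(dis))
            )
    for doc in documents:
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in doc.mentions:
            stream.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}\t{m.etype}\t{m.concept_id}\n"
            )
        for chem, dis in sorted(by_doc.get(doc.doc_id, ())):
            stream.write(f"{doc.doc_id}\tCID\t{chem}\t{dis}\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Knowledge table
# ---------------------------------------------------------------------------

def read_knowledge_table(
    stream: Iterable[str],
    chemical_col: int = 0,
    disease_col: int = 1,
    relation_col: int = 2,
) -> KnowledgeBase:
    """Read a flat chemical-disease relation table into a :class:`KnowledgeBase`.

    Rows are tab- or comma-separated.  The relation column mirrors the curated
    dump's direct-evidence field: ``marker/mechanism`` and ``therapeutic`` map
    to themselves; an empty value (a curated pair without direct evidence)
    maps to ``inferred``.  Duplicate rows are idempotent.  Lines starting with
    ``#`` are comments.
    """
    kb = KnowledgeBase()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(",")
        needed = max(chemical_col, disease_col, relation_col)
        if len(fields) <= max(chemical_col, disease_col):
            raise ParseError(f"expected at least {needed + 1} columns", lineno)
        chem = fields[chemical_col]
        dis = fields[disease_col]
        rel = fields[relation_col].strip().lower() if len(fields) > relation_col else ""
        if rel in ("", "inferred", "infered"):
            rel = "inferred"
        elif rel not in RELATION_TYPES:
            raise ParseError(f"unknown relation label {fields[relation_col]!r}", lineno)
        kb.add(chem, dis, rel)
    return kb


def write_knowledge_table(kb: KnowledgeBase, stream: IO[str]) -> None:
    for (chem, dis), rels in sorted(kb.entries.items()):
        for rel in sorted(rels):
            stream.write(f"{chem}\t{dis}\t{rel}\n")


# ---------------------------------------------------------------------------
# MeSH tree numbers
# ---------------------------------------------------------------------------

def read_mesh_tree(stream: Iterable[str]) -> MeshTree:
    """Read a two-column (MeSH id, tree number) table; ids may repeat."""
    tree = MeshTree()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(",")
        if len(fields) != 2:
            raise ParseError(f"expected 2 columns, got {len(fields)}", lineno)
        mesh_id, number = normalize_mesh_id(fields[0]), fields[1].strip()
        if not is_tree_number(number):
            raise ParseError(f"malformed tree number {number!r}", lineno)
        tree.tree_numbers.setdefault(mesh_id, set()).add(number)
    return tree


def write_mesh_tree(tree: MeshTree, stream: IO[str]) -> None:
    for mesh_id, numbers in sorted(tree.tree_numbers.items()):
        for n in sorted(numbers):
            stream.write(f"{mesh_id}\t{n}\n")


# ---------------------------------------------------------------------------
# Embedding files
# ---------------------------------------------------------------------------

def load_word_vectors(stream: Iterable[str]) -> tuple[list[str], np.ndarray]:
    """Load a word2vec-text-format file: header ``count dim``, then one
    ``token v1 ... v_dim`` row per line.  Returns (vocab, count x dim matrix)."""
    it: Iterator[str] = iter(stream)
    try:
        header = next(it)
    except StopIteration:
        raise ParseError("empty embedding file")
    parts = header.split()
    if len(parts) != 2 or not all(p.isdigit() for p in parts):
        raise ParseError(f"bad word2vec header {header.strip()!r}", 1)
    count, dim = int(parts[0]), int(parts[1])
    vocab: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(it, start=2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != dim + 1:
            raise ParseError(
                f"expected {dim} values for token {fields[0]!r}, got {len(fields) - 1}",
                lineno,
            )
        vocab.append(fields[0])
        rows.append([float(x) for x in fields[1:]])
    if len(vocab) != count:
        raise ParseError(f"header promised {count} rows, found {len(vocab)}")
    return vocab, np.asarray(rows, dtype=np.float64).reshape(len(vocab), dim)


def load_relation_vectors(stream: Iterable[str]) -> tuple[list[str], np.ndarray]:
    """Load relation embedding vectors: one labelled row per relation type.

    All four types (marker/mechanism, therapeutic, inferred, null) must be
    present; rows are returned in canonical order regardless of file order.
    """
    vectors: dict[str, list[float]] = {}
    dim: int | None = None
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        fields = line.split()
        name = fields[0].lower()
        values = [float(x) for x in fields[1:]]
        if dim is None:
            dim = len(values)
        elif len(values) != dim:
            raise ParseError(f"inconsistent dimensionality for {name!r}", lineno)
        vectors[name] = values
    order = list(RELATION_TYPES) + [NULL_RELATION]
    missing = [r for r in order if r not in vectors]
    if missing:
        raise ParseError(f"relation vector file missing type(s): {', '.join(missing)}")
    matrix = np.asarray([vectors[r] for r in order], dtype=np.float64)
    return order, matrix
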