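"""Resolve a candidate pair against the knowledge base.

A chemical-disease pair carries at most four relation types in the curated
knowledge base: ``marker/mechanism``, ``therapeutic``, ``inferred``, and the
padding type ``null``.  The model consumes a fixed-length sequence of exactly
four relation identifiers, so lookups are canonically ordered and right-padded
with ``null``.  The canonical order below makes the concatenating aggregation
variant well-defined (slot k always holds the same type when present).
"""

from __future__ import annotations

from .corpus_io import KnowledgeBase, NULL_RELATION, RELATION_TYPES

#: Fixed sequence length n3.
N_RELATIONS = 4

#: Canonical slot order for the relation sequence.
CANONICAL_ORDER: tuple[str, ...] = RELATION_TYPES + (NULL_RELATION,)

#: Relation type -> embedding-row index (stable across the whole system).
RELATION_INDEX: dict[str, int] = {r: i for i, r in enumerate(CANONICAL_ORDER)}


def lookup_relations(
    chemical_id: str, disease_id: str, kb: KnowledgeBase
) -> list[str]:
    """Return the pair's relation types, canonically ordered, padded to 4.

    A pair absent from the knowledge base yields ``[null, null, null, null]``
    (a perfectly valid input: most candidate pairs are uncurated).
    """
    present = kb.relations_for(chemical_id, disease_id)
    seq = [r for r in RELATION_TYPES if r in present]
    seq += [NULL_RELATION] * (N_RELATIONS - len(seq))
    return seq


def relation_ids(seq: list[str]) -> list[int]:
    """Map a relation sequence to embedding-row indices."""
    return [RELATION_INDEX[r] for r in seq]
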