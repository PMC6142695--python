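"""Text processing: from an annotated article to candidate-pair token sequences.

The pipeline mirrors how document-level relation extractors prepare input:

* numbers (integers/decimals containing no letters) are masked to ``NUM``;
* every entity mention is replaced by a type-prefixed concept-id token
  (``ch_d014148`` / ``ds_d062787``), and mentions of the two *candidate*
  entities are additionally bracketed with ``ch_start .. ch_end`` /
  ``ds_start .. ds_end`` marker tokens so the model can tell the pair under
  consideration apart from other entities;
* the article is split into sentences and PoS-tagged; marker and concept-id
  tokens receive the reserved tag ``ENT``.

Candidate pairs are all (chemical id, disease id) combinations co-occurring
in one article, labelled positive iff annotated as a gold CID relation.  An
optional span filter discards pairs whose closest mentions are K or more
sentences apart; gold positives removed this way are kept, flagged
``filtered``, so evaluation can count them as false negatives.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .corpus_io import CHEMICAL, DISEASE, Document, Mention

logger = logging.getLogger("cidrex")

NUM_TOKEN = "NUM"
ENT_TAG = "ENT"
MARKERS = ("ch_start", "ch_end", "ds_start", "ds_end")

_NUMBER_RE = re.compile(r"[+-]?\d+(?:[.,]\d+)*")
_EDGE_PUNCT = ".,;:!?()[]{}\"'`"

LABEL_CID = "CID"
LABEL_NULL = "null"
INTRA = "intra"
INTER = "inter"


# ---------------------------------------------------------------------------
# Token-level operations
# ---------------------------------------------------------------------------

def mask_numbers(tokens: Sequence[str]) -> list[str]:
    """Replace purely numeric tokens (no letters) with the ``NUM`` token."""
    return [NUM_TOKEN if _NUMBER_RE.fullmatch(t) else t for t in tokens]


def tokenize(text: str) -> list[str]:
    """Whitespace tokenisation with edge punctuation split off as own tokens.

    Internal punctuation is preserved (``IL-2``, ``12.5`` stay whole), so
    number masking sees decimals intact.
    """
    out: list[str] = []
    for chunk in text.split():
        head: list[str] = []
        tail: list[str] = []
        while chunk and chunk[0] in _EDGE_PUNCT:
            head.append(chunk[0])
            chunk = chunk[1:]
        while chunk and chunk[-1] in _EDGE_PUNCT:
            tail.append(chunk[-1])
            chunk = chunk[:-1]
        out.extend(head)
        if chunk:
            out.append(chunk)
        out.extend(reversed(tail))
    return out


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Deterministic rule-based splitting: a sentence ends at ``. ! ?``
    followed by whitespace (or end of text).  Returns char spans."""
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    n = len(text)
    while i < n:
        if text[i] in ".!?" and (i + 1 == n or text[i + 1].isspace()):
            spans.append((start, i + 1))
            i += 1
            while i < n and text[i].isspace():
                i += 1
            start = i
        else:
            i += 1
    if start < n and text[start:].strip():
        spans.append((start, n))
    return spans


# ---------------------------------------------------------------------------
# PoS tagging (pluggable; the reference tagger of the original system is a
# patched CoreNLP, unavailable here, so a deterministic suffix tagger stands in)
# ---------------------------------------------------------------------------

Tagger = Callable[[Sequence[str]], list[str]]


def suffix_tagger(tokens: Sequence[str]) -> list[str]:
    tags = []
    for t in tokens:
        if t == NUM_TOKEN or (t and t[0].isdigit()):
            tags.append("CD")
        elif len(t) == 1 and not t.isalnum():
            tags.append("PUNCT")
        elif t.endswith("ing"):
            tags.append("VBG")
        elif t.endswith("ed"):
            tags.append("VBD")
        elif t.endswith("ly"):
            tags.append("RB")
        elif t.endswith(("ous", "ful", "ive", "al", "ic")):
            tags.append("JJ")
        elif t.endswith("s") and len(t) > 3:
            tags.append("NNS")
        elif t[:1].isupper():
            tags.append("NNP")
        else:
            tags.append("NN")
    return tags


TAGGERS: dict[str, Tagger] = {"suffix": suffix_tagger}


def _apply_tags(tokens: Sequence[str], tagger: Tagger) -> list[str]:
    tags = tagger(tokens)
    for i, t in enumerate(tokens):
        if t in MARKERS or t.startswith(("ch_", "ds_")):
            tags[i] = ENT_TAG
    return tags


# ---------------------------------------------------------------------------
# Mention substitution and document tokenisation
# ---------------------------------------------------------------------------

@dataclass
class TokenizedDoc:
    """A substituted, sentence-split, tagged article.

    ``sentences[0]`` is the title (also exposed as ``title_tokens`` for the
    separate theme encoder); mentions are indexed by the sentence containing
    their replacement token.
    """

    doc_id: str
    sentences: list[list[str]]
    pos_tags: list[list[str]]
    title_tokens: list[str]
    title_tags: list[str]
    sentence_index_of_mention: dict[Mention, int] = field(default_factory=dict)

    def sentence_indices(self, concept_id: str, etype: str | None = None) -> set[int]:
        return {
            idx
            for m, idx in self.sentence_index_of_mention.items()
            if m.concept_id == concept_id and (etype is None or m.etype == etype)
        }


def _id_token(m: Mention) -> str:
    prefix = "ch" if m.etype == CHEMICAL else "ds"
    return f"{prefix}_{m.concept_id.lower()}"


def _select_spans(mentions: Sequence[Mention]) -> list[tuple[int, int, list[Mention]]]:
    """Group mentions by span, then resolve overlaps keeping the longer span."""
    by_span: dict[tuple[int, int], list[Mention]] = {}
    for m in mentions:
        by_span.setdefault((m.start, m.end), []).append(m)
    spans = sorted(by_span, key=lambda s: (s[0], -(s[1] - s[0])))
    kept: list[tuple[int, int, list[Mention]]] = []
    last_end = -1
    for start, end in spans:
        if start < last_end:
            logger.warning(
                "dropping mention span [%d,%d) overlapping a longer/earlier one",
                start, end,
            )
            continue
        kept.append((start, end, by_span[(start, end)]))
        last_end = end
    return kept


def _replacement_for(
    group: list[Mention], candidate: tuple[str, str] | None
) -> tuple[str, str]:
    """Pick the representative mention of a span group and build its
    replacement string (bracketed when it is one of the candidate entities)."""
    rep = group[0]
    for m in group:
        if candidate is not None and (
            (m.etype == CHEMICAL and m.concept_id == candidate[0])
            or (m.etype == DISEASE and m.concept_id == candidate[1])
        ):
            rep = m
            break
    token = _id_token(rep)
    is_cand = candidate is not None and (
        (rep.etype == CHEMICAL and rep.concept_id == candidate[0])
        or (rep.etype == DISEASE and rep.concept_id == candidate[1])
    )
    if is_cand:
        prefix = "ch" if rep.etype == CHEMICAL else "ds"
        return token, f"{prefix}_start {token} {prefix}_end"
    return token, token


def substitute_mentions(
    document: Document,
    candidate: tuple[str, str] | None,
    tagger: Tagger = suffix_tagger,
) -> TokenizedDoc:
    """Replace mentions by id tokens, bracket the candidate pair, tokenise.

    ``candidate`` is a (chemical id, disease id) pair; every mention of the
    two candidate entities is wrapped in its start/end markers.  With
    ``candidate=None`` no brackets are added (used for pair-independent
    sentence indexing).  Raises ``ValueError`` if a candidate entity has no
    mention in the article.
    """
    if candidate is not None:
        present = {(m.etype, m.concept_id) for m in document.mentions}
        chem_id, dis_id = candidate
        if (CHEMICAL, chem_id) not in present or (DISEASE, dis_id) not in present:
            raise ValueError(
                f"candidate entity absent from document {document.doc_id}: "
                f"({chem_id}, {dis_id})"
            )

    text = document.text
    title_len = len(document.title)
    groups = _select_spans(document.mentions)

    # Rebuild the text left-to-right, recording where each id token lands.
    parts: list[str] = []
    length = 0
    cursor = 0
    new_title_len = title_len
    positions: list[tuple[int, list[Mention], bool]] = []  # (new pos, group, in title)
    for start, end, group in groups:
        token, replacement = _replacement_for(group, candidate)
        parts.append(text[cursor:start])
        length += start - cursor
        positions.append((length + replacement.find(token), group, start < title_len))
        parts.append(replacement)
        length += len(replacement)
        if end <= title_len:
            new_title_len += len(replacement) - (end - start)
        cursor = end
    parts.append(text[cursor:])
    new_text = "".join(parts)

    new_title = new_text[:new_title_len]
    new_abstract = new_text[new_title_len + 1:]

    title_tokens = mask_numbers(tokenize(new_title))
    sent_spans = split_sentences(new_abstract)
    sentence_tokens = [
        mask_numbers(tokenize(new_abstract[a:b])) for a, b in sent_spans
    ]
    sentences = [title_tokens] + sentence_tokens
    tags = [_apply_tags(s, tagger) for s in sentences]

    # Map mentions to sentence index (title == sentence 0).
    mention_sentence: dict[Mention, int] = {}
    abs_offset = len(new_title) + 1
    for idx, group, in_title in positions:
        if in_title:
            s_idx = 0
        else:
            pos_in_abs = idx - abs_offset
            s_idx = 0
            for k, (a, b) in enumerate(sent_spans):
                if a <= pos_in_abs < max(b, a + 1):
                    s_idx = k + 1
                    break
            else:
                s_idx = len(sent_spans)
        for m in group:
            mention_sentence[m] = s_idx

    return TokenizedDoc(
        doc_id=document.doc_id,
        sentences=sentences,
        pos_tags=tags,
        title_tokens=title_tokens,
        title_tags=tags[0],
        sentence_index_of_mention=mention_sentence,
    )


def split_and_tag(text: str, tagger: Tagger = suffix_tagger) -> tuple[list[list[str]], list[list[str]]]:
    """Sentence-split, tokenise, number-mask and PoS-tag a text body."""
    sentences = [
        mask_numbers(tokenize(text[a:b])) for a, b in split_sentences(text)
    ]
    tags = [_apply_tags(s, tagger) for s in sentences]
    return sentences, tags


# ---------------------------------------------------------------------------
# Candidate construction
# ---------------------------------------------------------------------------

@dataclass
class CandidateInstance:
    """One (chemical id, disease id) pair within one article."""

    doc_id: str
    chemical_id: str
    disease_id: str
    label: str  # LABEL_CID or LABEL_NULL
    min_span: int
    stratum: str  # INTRA or INTER
    filtered: bool = False  # gold positive removed by the span filter

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.doc_id, self.chemical_id, self.disease_id)


def min_sentence_span(
    tokdoc: TokenizedDoc, chemical_id: str, disease_id: str
) -> int:
    """Smallest sentence-index distance over all mention pairs of the two ids."""
    chem_sents = tokdoc.sentence_indices(chemical_id, CHEMICAL)
    dis_sents = tokdoc.sentence_indices(disease_id, DISEASE)
    return min(abs(i - j) for i in chem_sents for j in dis_sents)


def build_candidates(
    document: Document,
    k: int = 4,
    apply_span_filter: bool = False,
    tokdoc: TokenizedDoc | None = None,
    tagger: Tagger = suffix_tagger,
) -> list[CandidateInstance]:
    """All distinct (chemical, disease) id pairs of one article, labelled.

    A pair is positive iff annotated as a gold CID relation.  With the span
    filter on, pairs whose closest mentions sit ``k`` or more sentences apart
    ("within k consecutive sentences" admits distances 0..k-1) are removed:
    negatives silently, gold positives flagged ``filtered`` and kept for
    false-negative accounting.  Unmapped ``-1`` ids never form candidates.
    """
    if tokdoc is None:
        tokdoc = substitute_mentions(document, None, tagger=tagger)
    chem_ids = sorted(
        {m.concept_id for m in document.mentions if m.etype == CHEMICAL and m.concept_id != "-1"}
    )
    dis_ids = sorted(
        {m.concept_id for m in document.mentions if m.etype == DISEASE and m.concept_id != "-1"}
    )
    out: list[CandidateInstance] = []
    for chem in chem_ids:
        for dis in dis_ids:
            span = min_sentence_span(tokdoc, chem, dis)
            label = LABEL_CID if (chem, dis) in document.gold_relations else LABEL_NULL
            filtered = False
            if apply_span_filter and span >= k:
                if label == LABEL_NULL:
                    continue
                filtered = True
            out.append(
                CandidateInstance(
                    doc_id=document.doc_id,
                    chemical_id=chem,
                    disease_id=dis,
                    label=label,
                    min_span=span,
                    stratum=INTRA if span == 0 else INTER,
                    filtered=filtered,
                )
            )
    return out
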