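"""Hypernymy post-filter and entity-level evaluation.

The corpus annotates relations against the *most specific* disease discussed:
when an article mentions both a general disease (say, kidney disease) and one
of its descendants in the MeSH hierarchy (chronic kidney failure), the
general disease is usually not annotated unless it carries the article's
focus — which shows up as a title mention.  The post-filter therefore demotes
a predicted positive (chemical, d_i) when some other disease in the same
article is a strict MeSH-tree descendant of d_i and d_i never appears in the
title.

Evaluation is entity-level: predicted (chemical id, disease id) pairs per
article are scored against gold relations, overall and stratified into
intra-sentential (the entities co-occur in some sentence) and
inter-sentential pairs.  Gold positives removed by the candidate span filter
count toward POS (they are unreachable false negatives) but can never be
true positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus_io import DISEASE, Document, MeshTree
from .preprocess import INTER, INTRA, LABEL_CID, CandidateInstance

Prediction = tuple[str, str, str]  # (doc_id, chemical_id, disease_id)


# ---------------------------------------------------------------------------
# Hypernymy filter
# ---------------------------------------------------------------------------

def is_strict_descendant(specific: str, general: str) -> bool:
    """True iff ``specific`` extends ``general`` at a dot boundary
    (``C12.777.419`` descends from ``C12.777`` but not from ``C12.7``)."""
    return specific.startswith(general + ".")


def _disease_in_title(document: Document, disease_id: str) -> bool:
    title_len = len(document.title)
    return any(
        m.etype == DISEASE and m.concept_id == disease_id and m.start < title_len
        for m in document.mentions
    )


def hypernym_filter(
    predictions: Iterable[Prediction],
    documents: Mapping[str, Document],
    mesh_tree: MeshTree,
) -> list[Prediction]:
    """Demote positives whose disease has a more specific sibling in the article.

    A prediction (doc, c, d_i) is dropped iff some other disease d_j mentioned
    in the same article has a tree number strictly descending from one of
    d_i's, and d_i has no mention inside the title.  Diseases without tree
    numbers are never touched.  Monotone: never adds predictions.
    """
    kept: list[Prediction] = []
    for doc_id, chem, dis in predictions:
        doc = documents.get(doc_id)
        if doc is None:
            kept.append((doc_id, chem, dis))
            continue
        own_numbers = mesh_tree.numbers_for(dis)
        if not own_numbers or _disease_in_title(doc, dis):
            kept.append((doc_id, chem, dis))
            continue
        others = {
            m.concept_id for m in doc.mentions
            if m.etype == DISEASE and m.concept_id != dis
        }
        more_specific = any(
            is_strict_descendant(num_j, num_i)
            for other in others
            for num_j in mesh_tree.numbers_for(other)
            for num_i in own_numbers
        )
        if not more_specific:
            kept.append((doc_id, chem, dis))
    return kept


# ---------------------------------------------------------------------------
# Entity-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class StratumScores:
    tp: int
    fp: int
    pos: int

    @property
    def precision(self) -> float:
        return round(100.0 * self.tp / (self.tp + self.fp), 1) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return round(100.0 * self.tp / self.pos, 1) if self.pos else 0.0

    @property
    def f_score(self) -> float:
        p = 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        r = 100.0 * self.tp / self.pos if self.pos else 0.0
        return round(2 * p * r / (p + r), 1) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall, "f": self.f_score,
            "tp": self.tp, "fp": self.fp, "pos": self.pos,
        }


@dataclass
class EvalReport:
    overall: StratumScores
    inter: StratumScores
    intra: StratumScores

    def as_dict(self) -> dict:
        return {
            "overall": self.overall.as_dict(),
            "inter": self.inter.as_dict(),
            "intra": self.intra.as_dict(),
        }

    def table(self) -> str:
        rows = [f"{'stratum':<10}{'P(%)':>7}{'R(%)':>7}{'F(%)':>7}{'TP':>6}{'FP':>6}{'POS':>6}"]
        for name in ("overall", "inter", "intra"):
            s: StratumScores = getattr(self, name)
            rows.append(
                f"{name:<10}{s.precision:>7.1f}{s.recall:>7.1f}{s.f_score:>7.1f}"
                f"{s.tp:>6d}{s.fp:>6d}{s.pos:>6d}"
            )
        return "\n".join(rows)


def prf(tp: int, fp: int, pos: int) -> tuple[float, float, float]:
    """Precision/recall/F in percent, one decimal, from raw counts."""
    s = StratumScores(tp=tp, fp=fp, pos=pos)
    return s.precision, s.recall, s.f_score


def evaluate(
    predictions: Iterable[Prediction],
    gold_instances: Sequence[CandidateInstance],
) -> EvalReport:
    """Score predicted-positive pairs against gold candidate instances.

    ``gold_instances`` must include span-filtered gold positives (their
    ``filtered`` flag keeps them out of TP while counting toward POS).
    Duplicate prediction keys are an error.  Predictions on unknown keys are
    false positives counted in the overall stratum only.
    """
    preds = list(predictions)
    if len(preds) != len(set(preds)):
        raise ValueError("duplicate prediction keys")
    by_key = {inst.key: inst for inst in gold_instances}

    counts = {name: {"tp": 0, "fp": 0, "pos": 0} for name in ("overall", INTER, INTRA)}
    for inst in gold_instances:
        if inst.label == LABEL_CID:
            counts["overall"]["pos"] += 1
            counts[inst.stratum]["pos"] += 1
    pred_set = set(preds)
    for key in pred_set:
        inst = by_key.get(key)
        if inst is None:
            counts["overall"]["fp"] += 1
        elif inst.label == LABEL_CID and not inst.filtered:
            counts["overall"]["tp"] += 1
            counts[inst.stratum]["tp"] += 1
        else:
            counts["overall"]["fp"] += 1
            counts[inst.stratum]["fp"] += 1

    return EvalReport(
        overall=StratumScores(**counts["overall"]),
        inter=StratumScores(**counts[INTER]),
        intra=StratumScores(**counts[INTRA]),
    )
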