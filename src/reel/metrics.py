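"""Micro-averaged linking evaluation.

Within each document, repeated instances of a mention with the same
surface form count as a single evaluation unit (case-folded); a
composite annotation whose one span carries two gold ids contributes
two units.  A unit is a true positive when the predicted id equals the
gold id, a false positive when it differs, and a false negative when
the model declines to link (NIL).  Precision, recall and F1 are
micro-averaged over the pooled counts and reported on a 0–100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import Document
from .ppr import LinkingResult


@dataclass
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "Metrics") -> "Metrics":
        return Metrics(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    def row(self) -> str:
        return f"{self.precision:.1f}\t{self.recall:.1f}\t{self.f1:.1f}"


def dedup_unique_mentions(document: Document) -> list[tuple[str, str, int]]:
    """Unique (folded surface, gold id, first mention index) units of a document.

    Instances sharing a case-folded surface and gold id collapse to one
    unit keyed by their first occurrence; a surface annotated with two
    distinct gold ids yields two units.  Mentions without a gold id are
    not evaluation units.
    """
    seen: dict[tuple[str, str], int] = {}
    for idx, mention in enumerate(document.mentions):
        if mention.gold_id is None:
            continue
        key = (mention.surface.casefold(), mention.gold_id)
        seen.setdefault(key, idx)
    return [(surface, gold, idx) for (surface, gold), idx in sorted(seen.items(), key=lambda kv: kv[1])]


def evaluate(predictions: list[LinkingResult], documents: list[Document]) -> Metrics:
    """Micro-averaged precision/recall/F1 of a model run against gold.

    Every document needs a prediction record (NIL-filled is fine);
    predictions for unknown documents are an error.  The prediction for
    a unit is the one attached to its first mention instance.
    """
    by_doc = {}
    for result in predictions:
        by_doc[result.doc_id] = result
    known = {d.doc_id for d in documents}
    for doc_id in by_doc:
        if doc_id not in known:
            raise ValueError(f"prediction for unknown document {doc_id}")

    tp = fp = fn = 0
    for doc in documents:
        result = by_doc.get(doc.doc_id)
        for _surface, gold, idx in dedup_unique_mentions(doc):
            pred = result.assignments.get(idx) if result is not None else None
            if pred is None:
                fn += 1
            elif pred == gold:
                tp += 1
            else:
                fp += 1
    return Metrics(tp, fp, fn)


def evaluation_table(metrics_by_model: dict[str, Metrics]) -> str:
    """Model × P/R/F1 table, one decimal place."""
    lines = ["Model\tP\tR\tF1"]
    for model, m in metrics_by_model.items():
        lines.append(f"{model}\t{m.row()}")
    return "\n".join(lines)
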