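"""Span-level nested-NER evaluation.

A prediction counts as correct only if its entity type and both
character boundaries exactly equal a gold span's, with all nesting
levels pooled — the shared-task convention for nested NER. Per-class
precision, recall and F1 are

    P = TP / (TP + FP),   R = TP / (TP + FN),   F1 = 2 P R / (P + R)

with the zero-denominator convention that a metric is 0 when its
denominator is 0. Micro scores pool TP/FP/FN over all classes; macro F1
is the unweighted mean of the per-class F1 over the eight classes,
including classes with zero F1 (rare classes therefore depress it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from nestner.corpus import ENTITY_TYPES, EntitySpan


@dataclass
class EvalCounts:
    """Per-entity-type true positive / false positive / false negative tallies."""

    tp: dict[str, int] = field(default_factory=dict)
    fp: dict[str, int] = field(default_factory=dict)
    fn: dict[str, int] = field(default_factory=dict)

    def total(self) -> tuple[int, int, int]:
        return (
            sum(self.tp.values()),
            sum(self.fp.values()),
            sum(self.fn.values()),
        )

    def add(self, other: "EvalCounts") -> None:
        for etype in ENTITY_TYPES:
            self.tp[etype] = self.tp.get(etype, 0) + other.tp.get(etype, 0)
            self.fp[etype] = self.fp.get(etype, 0) + other.fp.get(etype, 0)
            self.fn[etype] = self.fn.get(etype, 0) + other.fn.get(etype, 0)


@dataclass
class EvalReport:
    """Per-class and overall precision/recall/F1 plus macro F1."""

    per_class: dict[str, tuple[float, float, float]]
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_f1: float
    n_classes: int = len(ENTITY_TYPES)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                etype: {"precision": p, "recall": r, "f1": f}
                for etype, (p, r, f) in self.per_class.items()
            },
            "micro": {
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
            },
            "macro_f1": self.macro_f1,
            "n_classes": self.n_classes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def confusion_counts(
    gold: Iterable[EntitySpan], pred: Iterable[EntitySpan]
) -> EvalCounts:
    """Exact-match (type + both boundaries) confusion tallies per class.

    Both collections are deduplicated on (etype, start, end); all
    nesting levels are pooled.
    """
    gold_keys = {s.key() for s in gold}
    pred_keys = {s.key() for s in pred}
    counts = EvalCounts()
    for etype in ENTITY_TYPES:
        g = {k for k in gold_keys if k[0] == etype}
        p = {k for k in pred_keys if k[0] == etype}
        counts.tp[etype] = len(g & p)
        counts.fp[etype] = len(p - g)
        counts.fn[etype] = len(g - p)
    return counts


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def score(counts: EvalCounts) -> EvalReport:
    """Compute per-class, micro and macro metrics from confusion counts."""
    per_class = {}
    for etype in ENTITY_TYPES:
        per_class[etype] = _prf(
            counts.tp.get(etype, 0), counts.fp.get(etype, 0), counts.fn.get(etype, 0)
        )
    micro_p, micro_r, micro_f = _prf(*counts.total())
    macro_f1 = sum(f for (_, _, f) in per_class.values()) / len(ENTITY_TYPES)
    return EvalReport(
        per_class=per_class,
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=micro_f,
        macro_f1=macro_f1,
    )


def evaluate(gold: Iterable[EntitySpan], pred: Iterable[EntitySpan]) -> EvalReport:
    """Convenience wrapper: confusion counts then scoring."""
    return score(confusion_counts(gold, pred))


def format_report(report: EvalReport) -> str:
    """Render a report as a percentage table (2 decimals).

    Columns: Precision / Recall / F1 / Macro F1, one row per class plus
    an overall (micro) row.
    """
    header = f"{'Class':<18}{'Precision (%)':>15}{'Recall (%)':>13}{'F1 (%)':>10}"
    lines = [header, "-" * len(header)]
    for etype in ENTITY_TYPES:
        p, r, f = report.per_class[etype]
        lines.append(f"{etype:<18}{100 * p:>15.2f}{100 * r:>13.2f}{100 * f:>10.2f}")
    lines.append("-" * len(header))
    lines.append(
        f"{'Overall (micro)':<18}{100 * report.micro_precision:>15.2f}"
        f"{100 * report.micro_recall:>13.2f}{100 * report.micro_f1:>10.2f}"
    )
    lines.append(f"{'Macro F1 (%)':<18}{100 * report.macro_f1:>15.2f}")
    return "\n".join(lines)
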