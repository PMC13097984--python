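"""Span-level nested-NER scoring with exact-match criterion.

Gold and predicted span sets disagree on one boundary and miss one
entity; the report shows per-class precision/recall/F1, the pooled
micro scores, and macro F1 averaged over all eight classes (classes
absent from both sets contribute zero, depressing the macro score).
"""

from nestner import EntitySpan, confusion_counts, score
from nestner.evaluation import format_report

gold = [
    EntitySpan("T1", "DISO", 0, 12, "hypertension"),
    EntitySpan("T2", "DISO", 20, 26, "anemia"),
    EntitySpan("T3", "ANATOMY", 30, 35, "serum"),
    EntitySpan("T4", "CHEM", 40, 47, "insulin"),
]
pred = [
    EntitySpan("P1", "DISO", 0, 12, "hypertension"),
    EntitySpan("P2", "DISO", 20, 27, "anemia,"),   # boundary off by one
    EntitySpan("P3", "ANATOMY", 30, 35, "serum"),  # exact
    # CHEM missed entirely
]

counts = confusion_counts(gold, pred)
report = score(counts)
print(format_report(report))
print(
    f"\nmicro F1 {100 * report.micro_f1:.2f}% pools TP/FP/FN over classes; "
    f"macro F1 {100 * report.macro_f1:.2f}% averages all 8 per-class F1s."
)
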