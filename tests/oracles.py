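"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own scanning/counting code paths:
the evaluator oracle tallies by pairwise comparison over explicit lists,
and the matcher oracle enumerates every substring of the text.
"""

from __future__ import annotations

import re

from nestner.corpus import ENTITY_TYPES


def brute_force_metrics(gold_keys, pred_keys):
    """Per-class and pooled P/R/F1 by explicit pairwise matching.

    ``gold_keys``/``pred_keys`` are iterables of (etype, start, end).
    Returns (per_class, micro, macro_f1) where per_class maps type to
    (p, r, f1) and micro is (p, r, f1).
    """
    gold = list(set(gold_keys))
    pred = list(set(pred_keys))
    per_class = {}
    total_tp = total_fp = total_fn = 0
    for etype in ENTITY_TYPES:
        g = [k for k in gold if k[0] == etype]
        p = [k for k in pred if k[0] == etype]
        matched = set()
        tp = 0
        for pk in p:
            for i, gk in enumerate(g):
                if i not in matched and pk == gk:
                    matched.add(i)
                    tp += 1
                    break
        fp = len(p) - tp
        fn = len(g) - tp
        total_tp += tp
        total_fp += fp
        total_fn += fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[etype] = (prec, rec, f1)
    mp = total_tp / (total_tp + total_fp) if total_tp + total_fp else 0.0
    mr = total_tp / (total_tp + total_fn) if total_tp + total_fn else 0.0
    mf = 2 * mp * mr / (mp + mr) if mp + mr else 0.0
    macro = sum(f for (_, _, f) in per_class.values()) / len(ENTITY_TYPES)
    return per_class, (mp, mr, mf), macro


_WORD_CHAR = re.compile(r"\w")


def _is_word_char(ch: str) -> bool:
    return bool(_WORD_CHAR.match(ch))


def brute_force_match(text: str, terms_by_type: dict, min_length: int = 3):
    """All-substrings dictionary matching with the stated rules.

    Enumerates every substring that starts at the start of a word and
    ends at the end of a word, normalizes it (casefold, collapsed
    whitespace), keeps those in the type's term set with at least
    ``min_length`` characters, and resolves overlaps within a type
    longest-first then leftmost. Returns a set of (etype, start, end).
    """
    out = set()
    n = len(text)
    for etype, term_set in terms_by_type.items():
        candidates = []
        for i in range(n):
            if not _is_word_char(text[i]) or (i > 0 and _is_word_char(text[i - 1])):
                continue
            for j in range(i + 1, n + 1):
                if not _is_word_char(text[j - 1]):
                    continue
                if j < n and _is_word_char(text[j]):
                    continue
                cand = " ".join(text[i:j].casefold().split())
                if len(cand) >= min_length and cand in term_set:
                    candidates.append((i, j))
        candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
        accepted = []
        for s, e in candidates:
            if not any(s < ae and as_ < e for as_, ae in accepted):
                accepted.append((s, e))
        out.update((etype, s, e) for s, e in accepted)
    return out
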