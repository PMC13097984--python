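"""Build typed term dictionaries from an MRCONSO-style file and match.

A small in-memory MRCONSO.RRF fixture maps two concepts to terms; the
concept map assigns each concept an entity type, and a parent->child
relation pulls in a descendant's terms. Matched spans are then merged
with (mock) model predictions: the model span wins the same-type
overlap, the cross-type nested span is kept.
"""

from nestner import ConceptMap, EntitySpan, match_terms, merge_predictions, parse_mrconso


def rrf_row(cui, term, lang="ENG"):
    cols = [""] * 18
    cols[0], cols[1], cols[14] = cui, lang, term
    return "|".join(cols)


mrconso = "\n".join([
    rrf_row("C1268086", "serum"),          # anatomy root concept
    rrf_row("C0001001", "blood plasma"),   # its descendant
    rrf_row("C0220806", "interleukin"),    # chemical root concept
])
concept_map = ConceptMap.from_csv("ANATOMY,C1268086\nCHEM,C0220806")
relations = "C1268086|C0001001"

dictionary = parse_mrconso(mrconso, concept_map, relations)
for etype in ("ANATOMY", "CHEM"):
    print(f"{etype}: {sorted(dictionary.get(etype))}")

text = "Serum and blood plasma interleukin levels rose."
dict_spans = match_terms(text, dictionary)
print(f"\ndictionary matches in {text!r}:")
for s in dict_spans:
    print(f"  {s.etype:<8}[{s.start},{s.end})  {s.surface!r}")

model_spans = [EntitySpan("M1", "ANATOMY", 10, 22, "blood plasma")]
merged = merge_predictions(model_spans, dict_spans)
print("\nafter merging with a model span ANATOMY[10,22):")
for s in merged:
    print(f"  {s.etype:<8}[{s.start},{s.end})  {s.surface!r}")
print("(the model's boundary decision wins the same-type overlap; "
      "merging only adds spans, so recall can only go up)")
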