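"""Layered BIO tagging of one nested sentence.

A finding span contains an anatomy span and a chemical span. Layer
assignment puts the outer span in layer 1 and the nested ones in layer
2; encoding yields one BIO sequence per layer, and decoding recovers
the original span set exactly.
"""

from nestner import (
    EntitySpan,
    assign_layers,
    decode_bio,
    encode_bio,
    tokenize_sentence,
)

text = "decrease in serum level of soluble interleukin receptor"
spans = [
    EntitySpan("T1", "FINDING", 0, len(text), text),
    EntitySpan("T2", "ANATOMY", 12, 17, "serum"),
    EntitySpan("T3", "CHEM", 35, 46, "interleukin"),
]

tokens = tokenize_sentence(text)
layered = assign_layers(spans)
for li in (1, 2):
    print(f"layer {li}: {[f'{s.etype}[{s.start},{s.end})' for s in layered[li]]}")

tags = encode_bio(tokens, layered)
print(f"\n{'token':<14}layer1          layer2")
for i, tok in enumerate(tokens):
    print(f"{tok.text:<14}{tags.tags[0][i]:<16}{tags.tags[1][i]}")

recovered = decode_bio(tokens, tags, text=text)
assert sorted(s.key() for s in recovered) == sorted(s.key() for s in spans)
print(f"\ndecode(encode(...)) recovered all {len(recovered)} spans exactly")
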