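"""Encode aligned gRNA–target pairs into the 25-token integer vocabulary.

Each of the 23 alignment positions forms an ordered (guide, target) symbol
pair over {A,C,G,T,-}; the token table maps all 25 such pairs to integers
0–24, which feed the network's embedding layer.
"""

from crisprhw import GuideTargetPair, default_token_table, encode_pair

table = default_token_table()

# a perfect on-target match, a 2-mismatch site and a DNA-bulge site
examples = {
    "perfect match": GuideTargetPair(
        "GACGTACGTACGTACGTACGTGG", "GACGTACGTACGTACGTACGTGG", 1
    ),
    "two mismatches": GuideTargetPair(
        "GACGTACGTACGTACGTACGTGG", "GTCGTACGTACGTACATACGTGG", 1
    ),
    "DNA bulge at position 12": GuideTargetPair(
        "GACGTACGTACGTACGTACGTGG", "GACGTACGTAC-TACGTACGTGG", 0
    ),
}

print("anchor tokens: AA->%d  TA->%d  C- ->%d  GA->%d  -A ->%d\n" % (
    table[("A", "A")], table[("T", "A")], table[("C", "-")],
    table[("G", "A")], table[("-", "A")],
))

for name, pair in examples.items():
    tokens = encode_pair(pair, table)
    print(f"{name}:")
    print(f"  guide  {pair.guide}")
    print(f"  target {pair.target}")
    print(f"  tokens {' '.join(f'{t:2d}' for t in tokens)}")
    print()

print(
    "Identical bases encode to the 'match' diagonal tokens; mismatched and\n"
    "bulged positions receive their own tokens, so the network sees the\n"
    "type AND orientation of every perturbation at every position."
)
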