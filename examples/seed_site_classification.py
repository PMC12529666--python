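"""Classify the degenerate RBNS target library against the miR-122 seed.

The library is every expansion of the purine/pyrimidine pattern RYRYYYYR
(256 8-mers).  Exactly one member pairs perfectly with the miR-122 seed
plus a 3' A (the 8mer site); one member each falls in the weaker canonical
classes (7mer-m8, 7mer-A1, 6mer); the other 252 carry no seed match.
"""

from collections import Counter

from agodyn import LibraryMember, classify_library, expand_degenerate, seed_region
from agodyn.simulate import MIR122_GUIDE

members = [LibraryMember(v) for v in expand_degenerate("RYRYYYYR")]
classes = classify_library(members, MIR122_GUIDE)

print(f"guide {MIR122_GUIDE.name}, seed g2-g8 = {seed_region(MIR122_GUIDE)}")
print(f"library size: {len(members)}")
for label, n in Counter(c.label for c in classes.values()).most_common():
    print(f"  {label:>8}: {n} member(s)")
eight = [v for v, c in classes.items() if c.label == "8mer"]
print(f"the perfect 8mer target: {eight[0]}")
# The class counts show the library design: a single perfect seed match
# among 255 mismatched variants, with one member per weaker site type.
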