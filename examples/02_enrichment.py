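"""Hypergeometric over-representation of a marker set with BH-FDR control.

Ten query genes exactly matching a 10-gene term in a 20-gene annotated
universe attain the smallest possible p = 1/C(20,10) = 5.4e-6; background
terms with no overlap are never tested, so they do not inflate the
correction burden.
"""

import math

from heartomics import enrich
from heartomics.io import AnnotationDatabase

query = {f"Q{i}" for i in range(10)}
db = AnnotationDatabase(
    source="toy",
    terms={
        "CARDIAC_PROGRAM": ("planted program", frozenset(query)),
        "BG1": ("unrelated", frozenset({f"O{i}" for i in range(5)})),
        "BG2": ("unrelated", frozenset({f"O{i}" for i in range(5, 10)})),
    },
)
result = enrich(query, db)
print(result[["source", "term", "k", "K", "n", "N", "p", "q", "significant"]])
print(f"\nminimum possible p = 1/C(20,10) = {1 / math.comb(20, 10):.3e}")
# k = K = n = 10 of N = 20: the planted term is flagged at q < 0.001; the
# zero-overlap background terms are absent from the output.
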