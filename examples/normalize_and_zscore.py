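"""Median-of-ratios normalization and heat-map-style row z-scores.

Builds a count matrix whose samples are scaled copies of one expression
profile plus noise, estimates size factors, and standardizes each gene
row of the normalized matrix.
"""

import numpy as np
import pandas as pd

from stemstat import CountMatrix, normalize_counts, row_zscore

rng = np.random.default_rng(3)
profile = rng.integers(5, 500, size=8).astype(float)
depth = np.array([0.5, 1.0, 2.0, 4.0])  # library-size differences
counts = np.rint(np.outer(profile, depth) * rng.uniform(0.9, 1.1, size=(8, 4)))

cm = CountMatrix(pd.DataFrame(
    counts, index=[f"g{i}" for i in range(8)], columns=list("abcd")
))
norm = normalize_counts(cm)
print("size factors:")
print(norm.size_factors.round(3).to_string())

z = row_zscore(norm.values)
print("\nrow z-scores (each gene: mean 0, sd 1 across samples):")
print(z.round(2).to_string())

# The size factors recover the relative sequencing depths (up to a common
# scale); the z-scored matrix is what a clustered expression heat map
# would display.
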