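"""Independent brute-force oracles used by the test suites."""

import numpy as np
from scipy.stats import chi2


def kruskal_oracle(samples_by_group):
    """From-scratch Kruskal-Wallis: mid-ranks, tie correction, chi-square p."""
    pooled = np.concatenate(samples_by_group)
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    while i < n:  # assign average ranks over tied runs
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    start = 0
    for grp in samples_by_group:
        r = ranks[start:start + len(grp)]
        h += len(grp) * (r.mean() - (n + 1) / 2) ** 2
        start += len(grp)
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    if correction == 0:
        return 0.0, 1.0
    h /= correction
    return h, chi2.sf(h, len(samples_by_group) - 1)
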