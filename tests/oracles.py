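"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_force_hpd(samples, level):
    """Exhaustive shortest-window scan over the sorted samples."""
    s = np.sort(samples)
    m = int(np.ceil(level * s.size))
    best = (np.inf, None)
    for j in range(s.size - m + 1):
        width = s[j + m - 1] - s[j]
        if width < best[0]:
            best = (width, (s[j], s[j + m - 1]))
    return best[1]


def pairwise_auroc(scores, labels):
    """O(n^2) pairwise comparison count with half credit for ties."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)
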