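"""Independent brute-force oracles the fast implementations are held to."""

from collections import Counter

import numpy as np


def brute_force_mean_neighbor_count(pos_a, pos_b, radius, same_points=False):
    """O(n^2) double loop over all (a, b) pairs, squared-distance comparison."""
    pos_a = np.asarray(pos_a, dtype=float).reshape(-1, 2)
    pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 2)
    r2 = radius * radius
    total = 0
    for i in range(len(pos_a)):
        for j in range(len(pos_b)):
            if same_points and i == j:
                continue
            dx = pos_a[i, 0] - pos_b[j, 0]
            dy = pos_a[i, 1] - pos_b[j, 1]
            if dx * dx + dy * dy <= r2:
                total += 1
    return total / len(pos_a)


def brute_force_confusion_tally(expected, predicted):
    """Plain dict tally of (expected, predicted) label pairs."""
    return Counter(zip(expected, predicted))
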