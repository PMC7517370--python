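"""Independent straight-line oracles used by the unit and acceptance tests.

These deliberately re-derive the statistics with plain Python loops so they
share no code path with the package implementation.
"""

import math

import numpy as np

TWO_PI = 2.0 * math.pi


def straight_line_phen(values, k, degrees=False):
    """Per-index re-implementation of the whole Phase Entropy chain.

    Plain loops: first differences, four-quadrant angles, sector
    assignment, angle sums, total-sum probabilities, normalized Shannon
    entropy.  ``degrees=True`` accumulates the angle sums in degrees, which
    must not change the result (the probability ratio cancels the unit).
    """
    thetas = []
    for n in range(len(values) - 2):
        x = values[n + 1] - values[n]
        y = values[n + 2] - values[n + 1]
        if x == 0.0 and y == 0.0:
            continue
        t = math.atan2(y, x)
        if t < 0.0:
            t += TWO_PI
        if t >= TWO_PI:
            t = 0.0
        thetas.append(t)
    unit = 180.0 / math.pi if degrees else 1.0
    s = [0.0] * k
    for t in thetas:
        i = min(int(math.floor(t * (k / TWO_PI))), k - 1)
        s[i] += t * unit
    total = sum(s)
    h = 0.0
    for si in s:
        if si > 0.0:
            p = si / total
            h -= p * math.log(p)
    return h / math.log(k)


def brute_force_sampen(x, m, r):
    """Exhaustive O(N^2) pairwise template-count Sample Entropy oracle."""
    n = len(x) - m
    a = b = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if max(abs(x[i + t] - x[j + t]) for t in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)
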