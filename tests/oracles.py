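"""Independent brute-force oracles shared across test modules."""

import math

import numpy as np

from eggsense.features import sampen_cap


def sampen_counts_brute(x, m, r):
    """Exhaustive ordered-pair template match counts (A at m+1, B at m)."""
    n = len(x)
    nt = n - m

    def matches(length):
        c = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    return matches(m + 1), matches(m)


def sampen_brute(x, m, r):
    a, b = sampen_counts_brute(x, m, r)
    if a == 0 or b == 0:
        return sampen_cap(len(x), m)
    return -math.log(a / b)


def autocorr_brute(x, fs):
    x = np.asarray(x, float)
    xc = x - x.mean()
    denom = np.sum(xc * xc)
    for k in range(1, len(x)):
        if np.sum(xc[: len(x) - k] * xc[k:]) / denom <= 0:
            return k / fs
    return (len(x) - 1) / fs
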