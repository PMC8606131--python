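"""Independent brute-force oracles, kept deliberately naive.

Each function re-derives an expected value from first principles with
plain Python loops (or the standard library), so the vectorized package
implementations are checked against a separate computational path.
"""

import colorsys
import math


def liv_literal(series):
    """Population variance of a 1D dB series, literal two-pass transcription."""
    n = len(series)
    mean = sum(series) / n
    return sum((v - mean) ** 2 for v in series) / n


def pooled_acf_literal(patch, i_max):
    """Kernel-pooled autocorrelation of a (k, l, N) patch, triple-loop.

    For each lag, gathers the leading/lagged pooled samples over every
    kernel pixel and every overlapping time pair, subtracts the pooled
    per-lag means, and normalizes by the geometric mean of the two
    pooled variances.
    """
    k = len(patch)
    l = len(patch[0])
    n = len(patch[0][0])
    rho = []
    for i in range(i_max + 1):
        a, b = [], []
        for p in range(k):
            for q in range(l):
                for t in range(n - i):
                    a.append(patch[p][q][t])
                    b.append(patch[p][q][t + i])
        ma = sum(a) / len(a)
        mb = sum(b) / len(b)
        num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        va = sum((x - ma) ** 2 for x in a)
        vb = sum((y - mb) ** 2 for y in b)
        rho.append(1.0 if i == 0 else num / math.sqrt(va * vb))
    return rho


def ols_slope_literal(x, y):
    """Least-squares slope with intercept, closed form."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = sum((a - mx) ** 2 for a in x)
    return num / den


def hsv_to_rgb_literal(h, s, v):
    """Reference HSV -> RGB via the standard library."""
    return colorsys.hsv_to_rgb(h, s, v)


def sphere_lattice_count(radius, shape, center, pitches):
    """Count lattice points within ``radius`` µm of ``center``, brute force."""
    count = 0
    for iy in range(shape[0]):
        for iz in range(shape[1]):
            for ix in range(shape[2]):
                d2 = ((iy * pitches[0] - center[0]) ** 2
                      + (iz * pitches[1] - center[1]) ** 2
                      + (ix * pitches[2] - center[2]) ** 2)
                if d2 <= radius ** 2:
                    count += 1
    return count
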