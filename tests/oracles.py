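"""Brute-force reference implementations, kept deliberately naive.

Plain double loops over taxa, no vectorization, independent of the package's
code paths; used to validate MNTD and betaMNTD on small cases.
"""

import numpy as np


def brute_mntd(x, d, weighted):
    present = [i for i in range(len(x)) if x[i] > 0]
    nearest = []
    for i in present:
        best = np.inf
        for j in present:
            if j != i and d[i][j] < best:
                best = d[i][j]
        nearest.append(best)
    if weighted:
        total = sum(x[i] for i in present)
        return sum(n * x[i] / total for n, i in zip(nearest, present))
    return sum(nearest) / len(nearest)


def brute_beta_mntd(xa, xb, d, weighted):
    pa = [i for i in range(len(xa)) if xa[i] > 0]
    pb = [j for j in range(len(xb)) if xb[j] > 0]
    near_a = []
    for i in pa:
        best = np.inf
        for j in pb:
            if d[i][j] < best:
                best = d[i][j]
        near_a.append(best)
    near_b = []
    for j in pb:
        best = np.inf
        for i in pa:
            if d[i][j] < best:
                best = d[i][j]
        near_b.append(best)
    if weighted:
        ta = sum(xa[i] for i in pa)
        tb = sum(xb[j] for j in pb)
        sa = sum(n * xa[i] / ta for n, i in zip(near_a, pa))
        sb = sum(n * xb[j] / tb for n, j in zip(near_b, pb))
    else:
        sa = sum(near_a) / len(pa)
        sb = sum(near_b) / len(pb)
    return 0.5 * (sa + sb)


def brute_bray_curtis(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den
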