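"""Independent slow-path implementations used as oracles by the tests.

These deliberately avoid the package's code paths: explicit double loops,
exact integer Stirling numbers, and direct formula evaluation.
"""

import itertools
import math


def pairwise_k(seqs):
    n = len(seqs)
    tot = sum(
        sum(a != b for a, b in zip(seqs[i], seqs[j]))
        for i, j in itertools.combinations(range(n), 2)
    )
    return tot / (n * (n - 1) / 2)


def segregating(seqs):
    return sum(len({s[j] for s in seqs}) > 1 for j in range(len(seqs[0])))


def tajima_oracle(seqs):
    n, S = len(seqs), segregating(seqs)
    k = pairwise_k(seqs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return (k - S / a1) / math.sqrt(c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1))


def fs_oracle(seqs):
    """Fu's Fs from exact integer Stirling numbers and the Ewens formula."""
    n = len(seqs)
    k_obs = len(set(seqs))
    theta = pairwise_k(seqs)
    table = [[0] * (n + 1) for _ in range(n + 1)]
    table[0][0] = 1
    for m in range(1, n + 1):
        for k in range(1, m + 1):
            table[m][k] = table[m - 1][k - 1] + (m - 1) * table[m - 1][k]
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    probs = [table[n][k] * theta**k / rising for k in range(1, n + 1)]
    sp = sum(probs[k_obs - 1 :])
    return math.log(sp / (1 - sp))


def r2_oracle(seqs):
    n, S = len(seqs), segregating(seqs)
    k = pairwise_k(seqs)
    U = []
    for s in seqs:
        u = 0
        for j in range(len(s)):
            col = [t[j] for t in seqs]
            if col.count(s[j]) == 1 and len(set(col)) > 1:
                u += 1
        U.append(u)
    return math.sqrt(sum((u - k / 2) ** 2 for u in U) / n) / S
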