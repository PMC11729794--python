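"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def enumerate_partitions(n: int):
    """All set partitions of {0..n-1} as restricted-growth label lists."""
    codes = [0] * n
    while True:
        yield list(codes)
        for i in range(n - 1, 0, -1):
            if codes[i] <= max(codes[:i]):
                codes[i] += 1
                for j in range(i + 1, n):
                    codes[j] = 0
                break
        else:
            return


def brute_force_minimum(points: np.ndarray, lam: float) -> float:
    """Global minimum of within-cluster squared error + lam*K over every
    set partition of the points."""
    n = len(points)
    best = np.inf
    for codes in enumerate_partitions(n):
        k = max(codes) + 1
        loss = 0.0
        for c in range(k):
            grp = points[[i for i in range(n) if codes[i] == c]]
            loss += ((grp - grp.mean(0)) ** 2).sum()
        best = min(best, loss + lam * k)
    return best
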