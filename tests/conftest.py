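import numpy as np
import pytest

from telifecycle.io import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20140402)


def random_alignment(rng, n=None, L=None, alphabet="ACGT"):
    n = n if n is not None else int(rng.integers(2, 9))
    L = L if L is not None else int(rng.integers(1, 31))
    rows = ["".join(rng.choice(list(alphabet), size=L)) for _ in range(n)]
    return Alignment([f"s{i}" for i in range(n)], rows)


def brute_force_pi_k_S(aln):
    """Independent recomputation of pi, k, S by explicit column counting
    under complete deletion (route differs from the implementation: per-column
    pair counts rather than per-pair site sums)."""
    cols = []
    for j in range(aln.length):
        col = aln.column(j)
        if any(c in "N-" for c in col):
            continue
        cols.append(col)
    L = len(cols)
    if L == 0:
        return None
    n = aln.n
    npairs = n * (n - 1) // 2
    total_diffs = 0
    S = 0
    for col in cols:
        same = 0
        for b in set(col):
            c = col.count(b)
            same += c * (c - 1) // 2
        total_diffs += npairs - same
        if len(set(col)) >= 2:
            S += 1
    k = total_diffs / npairs
    return k / L, k, S, L


def direct_tajima_d(k, S, n):
    """Direct evaluation of the D formula, term by term."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
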