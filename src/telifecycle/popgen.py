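"""Per-family diversity and activity statistics.

Nucleotide diversity pi (average pairwise difference per site), segregating
sites S, Tajima's D with its beta-approximation significance, counts of
identical paralogous copies, and FLE/solo-partitioned diversity for LTR
retrotransposon families.

Gap handling follows the complete-deletion convention by default: every
alignment column containing a gap or N in any row is excluded before any
statistic is computed, so pi and S are always taken over the same site set.
A pairwise-deletion variant is available for pi only.  An alignment whose
every column is gapped somewhere yields an "insufficient sites" signal and
the statistics are reported as not applicable rather than zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import Alignment, revcomp

GAPLIKE = frozenset("N-")


class InsufficientSitesError(ValueError):
    """No usable alignment columns under the requested gap policy."""


@dataclass
class TajimaIntermediates:
    """The constants of Tajima's D for sample size n."""

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaIntermediates":
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class PopGenSummary:
    """Diversity summary for one family (or one FLE/solo partition)."""

    family: str
    partition: str  # {all, FLE, solo}
    n: int
    L_used: int
    S: int
    k: float
    pi: float
    intermediates: TajimaIntermediates | None = None
    D: float | None = None
    p_two_tailed: float | None = None
    sig_code: str = "ns"
    identical_copies: int = 0


def usable_sites(aln: Alignment, policy: str = "complete_deletion") -> list[int]:
    """Column indices usable under the gap policy.

    complete_deletion drops every column with a gap or N in any row and
    raises InsufficientSitesError when none survive (the situation in which
    too many overlapping indels make D incalculable).
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    if policy not in ("complete_deletion", "pairwise_deletion"):
        raise ValueError(f"unknown gap policy {policy!r}")
    if policy == "pairwise_deletion":
        return list(range(aln.length))
    cols = [j for j in range(aln.length) if not (set(aln.column(j)) & GAPLIKE)]
    if not cols:
        raise InsufficientSitesError("every column is gapped or ambiguous in at least one row")
    return cols


def _matrix(aln: Alignment) -> np.ndarray:
    return np.frombuffer("".join(aln.rows).encode(), dtype="S1").reshape(aln.n, aln.length)


def nucleotide_diversity(
    aln: Alignment, policy: str = "complete_deletion"
) -> tuple[float, float, int, int, int]:
    """Return (pi, k, S, n, L_used).

    k is the mean pairwise difference count over all n(n-1)/2 pairs on the
    usable sites; pi is k / L_used under complete deletion, or the mean of
    per-pair per-site distances under pairwise deletion.
    """
    n = aln.n
    if n < 2:
        raise ValueError("need at least 2 sequences")
    mat = _matrix(aln)
    if policy == "complete_deletion":
        cols = usable_sites(aln, policy)
        sub = mat[:, cols]
        L_used = len(cols)
        total = 0
        for i, j in combinations(range(n), 2):
            total += int(np.sum(sub[i] != sub[j]))
        npairs = n * (n - 1) // 2
        k = total / npairs
        pi = k / L_used
        S = sum(1 for c in range(L_used) if len(set(sub[:, c].tobytes())) >= 2)
        return pi, k, S, n, L_used
    # pairwise deletion (pi only; S and L_used refer to completely ungapped columns
    # when any exist, else 0)
    gaplike = (mat == b"-") | (mat == b"N")
    dists = []
    diffs = []
    for i, j in combinations(range(n), 2):
        ok = ~(gaplike[i] | gaplike[j])
        L_ij = int(ok.sum())
        if L_ij == 0:
            raise InsufficientSitesError(f"pair ({i},{j}) shares no usable sites")
        d_ij = int(np.sum(mat[i, ok] != mat[j, ok]))
        dists.append(d_ij / L_ij)
        diffs.append(d_ij)
    pi = float(np.mean(dists))
    k = float(np.mean(diffs))
    full = ~gaplike.any(axis=0)
    L_used = int(full.sum())
    S = 0
    if L_used:
        sub = mat[:, full]
        S = sum(1 for c in range(L_used) if len(set(sub[:, c].tobytes())) >= 2)
    return pi, k, S, n, L_used


def tajima_d_confidence(D: float, n: int) -> float:
    """Two-tailed p-value for Tajima's D under the beta approximation.

    D rescaled to its attainable range (Dmin, Dmax) is treated as a beta
    variate whose rescaled distribution has mean 0 and variance 1.
    """
    t = TajimaIntermediates.for_n(n)
    dmin = (2.0 / n - 1.0 / t.a1) / math.sqrt(t.e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / t.a1) / math.sqrt(t.e2)
    tmp = 1.0 + dmin * dmax
    rng_ = dmax - dmin
    alpha = -tmp * dmax / rng_
    beta = tmp * dmin / rng_
    x = (D - dmin) / rng_
    x = min(max(x, 0.0), 1.0)
    p = float(stats.beta.cdf(x, beta, alpha))
    return 2 * min(p, 1 - p)


def tajima_d_simulated_p(
    D: float, n: int, S: int, n_reps: int = 10_000, seed: int = 0
) -> float:
    """Two-tailed p-value from seeded neutral-coalescent simulation.

    Simulates standard n-coalescent genealogies, drops S mutations on
    branches proportionally to length, and recomputes D from the implied
    site-frequency spectrum.
    """
    rng = np.random.default_rng(seed)
    t = TajimaIntermediates.for_n(n)
    null = np.empty(n_reps)
    for rep in range(n_reps):
        # Kingman coalescent: track the number of leaves under each lineage.
        sizes = [1] * n
        branch_sz: list[int] = []
        branch_len: list[float] = []
        j = n
        while j > 1:
            t_j = rng.exponential(2.0 / (j * (j - 1)))
            for sz in sizes:
                branch_sz.append(sz)
                branch_len.append(t_j)
            a, b = rng.choice(j, size=2, replace=False)
            merged = sizes[a] + sizes[b]
            sizes = [s for idx, s in enumerate(sizes) if idx not in (a, b)] + [merged]
            j -= 1
        # Lineages persist across epochs: accumulate lengths per interval above.
        w = np.array(branch_len)
        probs = w / w.sum()
        muts = rng.multinomial(S, probs)
        sfs = np.zeros(n, dtype=int)  # index = derived-allele count
        for cnt, sz in zip(muts, branch_sz):
            if cnt and sz < n:
                sfs[sz] += cnt
        i = np.arange(1, n)
        k_hat = float(np.sum(sfs[1:] * i * (n - i)) / (n * (n - 1) / 2.0))
        S_eff = int(sfs[1:].sum())
        if S_eff == 0:
            null[rep] = 0.0
            continue
        null[rep] = (k_hat - S_eff / t.a1) / math.sqrt(
            t.e1 * S_eff + t.e2 * S_eff * (S_eff - 1)
        )
    lo = float(np.mean(null <= D))
    hi = float(np.mean(null >= D))
    return min(1.0, 2 * min(lo, hi))


def sig_code(p: float | None) -> str:
    if p is None:
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def tajimas_d(
    aln: Alignment,
    policy: str = "complete_deletion",
    family: str = "",
    partition: str = "all",
) -> PopGenSummary:
    """Full diversity summary with Tajima's D.

    D is defined only when n >= 4 and S >= 1; otherwise it is reported as
    None (never 0).
    """
    pi, k, S, n, L_used = nucleotide_diversity(aln, policy)
    summary = PopGenSummary(family, partition, n, L_used, S, k, pi)
    if n >= 4:
        summary.intermediates = TajimaIntermediates.for_n(n)
    if n < 4 or S < 1:
        return summary
    t = summary.intermediates
    D = (k - S / t.a1) / math.sqrt(t.e1 * S + t.e2 * S * (S - 1))
    summary.D = D
    summary.p_two_tailed = tajima_d_confidence(D, n)
    summary.sig_code = sig_code(summary.p_two_tailed)
    return summary


def identical_copy_count(seqs: list[str], strand_normalize: bool = True) -> int:
    """Number of sequences in any exact-identity group of size >= 2.

    Sequences are uppercased and, by default, strand-normalized (a sequence
    and its reverse complement are the same copy) so identity counting does
    not split reverse-complement pairs.
    """
    canon: dict[str, int] = {}
    for s in seqs:
        s = s.upper()
        key = min(s, revcomp(s)) if strand_normalize else s
        canon[key] = canon.get(key, 0) + 1
    return sum(c for c in canon.values() if c >= 2)


def partitioned_diversity(
    ltr_seqs: dict[str, list[str]],
    policy: str = "complete_deletion",
    family: str = "",
) -> dict[str, PopGenSummary | None]:
    """pi for {all, FLE, solo} partitions of one-LTR-per-insert sequences.

    ``ltr_seqs`` maps partition labels "FLE" and "solo" to equal-length LTR
    sequences (the 5' LTR for FLEs, the surviving LTR for solos).  Tajima's
    D is computed on the pooled partition only; a partition with fewer than
    2 sequences is reported as None.
    """
    fle = ltr_seqs.get("FLE", [])
    solo = ltr_seqs.get("solo", [])
    pooled = fle + solo
    out: dict[str, PopGenSummary | None] = {}
    for label, seqs in (("all", pooled), ("FLE", fle), ("solo", solo)):
        if len(seqs) < 2:
            out[label] = None
            continue
        aln = Alignment([f"{label}{i}" for i in range(len(seqs))], list(seqs))
        try:
            if label == "all":
                summ = tajimas_d(aln, policy, family=family, partition=label)
                summ.identical_copies = identical_copy_count(seqs)
            else:
                pi, k, S, n, L_used = nucleotide_diversity(aln, policy)
                summ = PopGenSummary(family, label, n, L_used, S, k, pi)
        except InsufficientSitesError:
            out[label] = None
            continue
        out[label] = summ
    return out


def summary_table(summaries: list[PopGenSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            dict(
                family=s.family,
                partition=s.partition,
                n=s.n,
                L_used=s.L_used,
                S=s.S,
                k=s.k,
                pi=s.pi,
                D="" if s.D is None else s.D,
                sig=s.sig_code,
                identical_copies=s.identical_copies,
            )
        )
    return pd.DataFrame(rows)
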