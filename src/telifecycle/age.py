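"""Copy-age profiling: JC69 distances, neighbor-joining trees, terminal
branch lengths, and the 0.05 substitutions/site old-insert rule.

The tree over a family's copies is built with classic Saitou-Nei neighbor
joining from Jukes-Cantor distances; the branch subtending each leaf is a
proxy for that copy's age.  Copies with terminal branch length at or above
the threshold (default 0.05 substitutions/site) are flagged old, and
families are summarized as five-number box statistics with 1.5 x IQR
whiskers and outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import Alignment, log

SATURATION_CAP = 3.0
OLD_THRESHOLD = 0.05


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite and nonnegative")
        self.d = d


def jc69_distance(
    a: str, b: str, cap: float = SATURATION_CAP
) -> tuple[float, bool]:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) between two sequences.

    Sites where either sequence carries a gap or N are excluded.  Returns
    (distance, saturated_flag); p >= 0.75 saturates the correction and the
    distance is set to the cap.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    usable = 0
    diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-N" or y in "-N":
            continue
        usable += 1
        diff += x != y
    if usable == 0:
        raise ValueError("zero usable sites")
    p = diff / usable
    if p >= 0.75:
        return cap, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def distance_matrix(aln: Alignment, cap: float = SATURATION_CAP) -> DistanceMatrix:
    n = aln.n
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            dist, sat = jc69_distance(aln.rows[i], aln.rows[j], cap)
            d[i, j] = d[j, i] = dist
            if sat:
                saturated.append((aln.ids[i], aln.ids[j]))
    if saturated:
        log.warning("%d saturated pairs capped at %.1f subs/site", len(saturated), cap)
    return DistanceMatrix(list(aln.ids), d, saturated)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q-matrix ties are broken toward the smallest (i, j) index pair in the
    current working order; negative branch estimates are clamped to zero
    with the deficit transferred to the sibling branch.  Returns an
    unrooted tree (trifurcating root) with leaf names from the matrix ids.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) in working order
        best = np.unravel_index(np.argmin(q), q.shape)
        bi, bj = sorted(best)
        i, j = active[bi], active[bj]
        vi = 0.5 * sub[bi, bj] + (r[bi] - r[bj]) / (2.0 * (m - 2))
        vj = sub[bi, bj] - vi
        if vi < 0:
            vj -= vi  # transfer the deficit to the sibling
            vi = 0.0
            log.debug("negative branch clamped for %s", nodes[i].name)
        if vj < 0:
            vi -= vj
            vj = 0.0
            log.debug("negative branch clamped for %s", nodes[j].name)
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = max(vi, 0.0)
        cj.length = max(vj, 0.0)
        parent.extend([ci, cj])
        # distances from the new node to every other active node
        dij = d[i, j]
        for a in active:
            if a in (i, j):
                continue
            d[i, a] = d[a, i] = 0.5 * (d[i, a] + d[j, a] - dij)
        nodes[i] = parent
        active.remove(j)

    # resolve the last three nodes at a trifurcating root (three-point formula)
    i, j, k = active
    root = TreeNode()
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        child = nodes[idx]
        child.length = max(v, 0.0)
        if v < 0:
            log.debug("negative terminal branch clamped for %s", child.name)
        root.append(child)
    return root


@dataclass
class AgeReport:
    """Per-copy terminal branch lengths and the family box summary."""

    family: str
    terminal_lengths: dict[str, float]
    old_flags: dict[str, bool]
    threshold: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[str]

    @property
    def old_fraction(self) -> float:
        return sum(self.old_flags.values()) / len(self.old_flags)


def terminal_branch_lengths(tree: TreeNode) -> dict[str, float]:
    return {tip.name: float(tip.length or 0.0) for tip in tree.tips()}


def age_profile(
    tree: TreeNode, threshold: float = OLD_THRESHOLD, family: str = ""
) -> AgeReport:
    """Terminal-branch age summary with 1.5 x IQR whiskers."""
    lengths = terminal_branch_lengths(tree)
    if len(lengths) < 2:
        raise ValueError("age profile needs at least 2 leaves")
    vals = np.array(sorted(lengths.values()))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_bound) & (vals <= hi_bound)]
    whisk_lo = float(inside.min()) if inside.size else float(q1)
    whisk_hi = float(inside.max()) if inside.size else float(q3)
    outliers = [k for k, v in lengths.items() if v < lo_bound or v > hi_bound]
    return AgeReport(
        family,
        lengths,
        {k: v >= threshold for k, v in lengths.items()},
        threshold,
        float(med),
        float(q1),
        float(q3),
        whisk_lo,
        whisk_hi,
        outliers,
    )


def ages_table(reports: list[AgeReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for cid, length in sorted(rep.terminal_lengths.items()):
            rows.append(
                dict(
                    family=rep.family,
                    copy_id=cid,
                    terminal_len=length,
                    old_flag=rep.old_flags[cid],
                )
            )
    return pd.DataFrame(rows)


def box_summary_table(reports: list[AgeReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        rows.append(
            dict(
                family=rep.family,
                n=len(rep.terminal_lengths),
                median=rep.median,
                q1=rep.q1,
                q3=rep.q3,
                whisker_low=rep.whisker_low,
                whisker_high=rep.whisker_high,
                n_outliers=len(rep.outliers),
                old_fraction=rep.old_fraction,
            )
        )
    return pd.DataFrame(rows)
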