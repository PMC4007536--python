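"""Expression quantification of stage-structured read sets against family
consensus sequences.

Reads are assigned by seeded ungapped matching to the family with the best
identity at or above a threshold (both strands); reads tying between
families are dropped.  Per-family/stage cells are replicate sums,
normalized by the global maximum for the linear heatmap and min-max scaled
in log10(x+1) space for the log heatmap.  Stage differences are tested per
family with a one-way ANOVA followed, when significant, by an unpaired
pooled-variance t-test between the two stages with the highest combined
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SequenceRecord, log, revcomp
from .simulate import STAGES


@dataclass
class StageTestResult:
    family: str
    anova_F: float | None
    anova_p: float | None
    significant: bool
    top_two_stages: tuple[str, str] | None = None
    t_stat: float | None = None
    t_p: float | None = None
    elevated_stage: str | None = None


def _kmer_index(consensi: list[SequenceRecord], k: int) -> dict[bytes, set[tuple[int, int]]]:
    """k-mer -> {(family index, offset)} over both strands (strand folded into
    offset sign handling at query time by indexing the forward consensus of
    each strand variant)."""
    index: dict[bytes, set[tuple[int, int]]] = {}
    for fi, rec in enumerate(consensi):
        b = rec.seq.encode()
        for off in range(len(b) - k + 1):
            index.setdefault(b[off : off + k], set()).add((fi, off))
    return index


def map_reads(
    reads: list[SequenceRecord],
    consensi: list[SequenceRecord],
    k: int = 10,
    min_identity: float = 0.80,
) -> dict[str, int]:
    """Per-family read counts by best seeded ungapped identity.

    Each read is evaluated on both strands against every consensus sharing
    an exact k-mer; it is counted for the family with the highest identity
    >= min_identity, and dropped (logged) when two families tie.
    """
    if not consensi:
        raise ValueError("empty consensus set")
    index = _kmer_index(consensi, k)
    arrs = [np.frombuffer(r.seq.encode(), dtype="S1") for r in consensi]
    counts = {r.id: 0 for r in consensi}
    dropped = 0
    for read in reads:
        if len(read.seq) < k:
            continue
        best_ident = 0.0
        best_fams: set[int] = set()
        for rseq in (read.seq, revcomp(read.seq)):
            rb = rseq.encode()
            rarr = np.frombuffer(rb, dtype="S1")
            rlen = rarr.size
            diagonals: set[tuple[int, int]] = set()
            for qo in range(0, rlen - k + 1):
                for fi, off in index.get(rb[qo : qo + k], ()):
                    diagonals.add((fi, off - qo))
            for fi, diag in diagonals:
                garr = arrs[fi]
                gs, ge = max(diag, 0), min(diag + rlen, garr.size)
                win = ge - gs
                if win < rlen:  # read must fit inside the consensus window
                    continue
                ident = float(np.sum(garr[gs:ge] == rarr[gs - diag : ge - diag])) / rlen
                if ident > best_ident + 1e-12:
                    best_ident = ident
                    best_fams = {fi}
                elif abs(ident - best_ident) <= 1e-12:
                    best_fams.add(fi)
        if best_ident >= min_identity and best_fams:
            if len(best_fams) == 1:
                counts[consensi[best_fams.pop()].id] += 1
            else:
                dropped += 1
    if dropped:
        log.info("%d reads dropped for family ties", dropped)
    return counts


def counts_to_matrix(counts: pd.DataFrame, stages: tuple[str, ...] = STAGES) -> pd.DataFrame:
    """family x stage matrix of replicate sums from a long count table."""
    wide = counts.pivot_table(
        index="family", columns="stage", values="count", aggfunc="sum", fill_value=0
    )
    return wide.reindex(columns=list(stages))


def normalize_matrix(cell_sums: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global-max normalized and log10(x+1) min-max normalized matrices."""
    vals = cell_sums.to_numpy(dtype=float)
    gmax = vals.max()
    if gmax <= 0:
        raise ValueError("all-zero expression table")
    normalized = cell_sums / gmax
    logs = np.log10(vals + 1.0)
    lo, hi = logs.min(), logs.max()
    span = hi - lo
    if span == 0:
        log_norm = pd.DataFrame(
            np.ones_like(logs), index=cell_sums.index, columns=cell_sums.columns
        )
    else:
        log_norm = pd.DataFrame(
            np.clip((logs - lo) / span, 0.0, 1.0),
            index=cell_sums.index,
            columns=cell_sums.columns,
        )
    return normalized, log_norm


def stage_tests(
    counts: pd.DataFrame, alpha: float = 0.05, stages: tuple[str, ...] = STAGES,
    welch: bool = False,
) -> list[StageTestResult]:
    """One-way ANOVA across stages per family; t-test on the top two stages.

    The t-test (pooled variance unless welch=True) is run only for families
    whose ANOVA is significant, between the two stages with the highest
    summed expression; elevated_stage is the higher-mean stage when the
    t-test is itself significant.
    """
    results = []
    for family, sub in counts.groupby("family", sort=False):
        groups = [
            sub.loc[sub["stage"] == s, "count"].to_numpy(dtype=float) for s in stages
        ]
        flat = np.concatenate(groups)
        if np.ptp(flat) == 0:  # no variance anywhere: F undefined
            results.append(StageTestResult(family, None, None, False))
            continue
        F, p = stats.f_oneway(*groups)
        if not np.isfinite(F):
            results.append(StageTestResult(family, None, None, False))
            continue
        res = StageTestResult(family, float(F), float(p), bool(p < alpha))
        if res.significant:
            sums = [g.sum() for g in groups]
            order = np.argsort(sums)[::-1][:2]
            s1, s2 = stages[order[0]], stages[order[1]]
            g1, g2 = groups[order[0]], groups[order[1]]
            t, tp = stats.ttest_ind(g1, g2, equal_var=not welch)
            res.top_two_stages = (s1, s2)
            if np.isfinite(t):
                res.t_stat, res.t_p = float(t), float(tp)
                if tp < alpha:
                    res.elevated_stage = s1 if g1.mean() >= g2.mean() else s2
            else:
                res.t_stat, res.t_p = 0.0, 1.0
        results.append(res)
    return results


def activity_correlation(
    reads_per_family: dict[str, float], identical_copies: dict[str, float]
) -> tuple[float, int]:
    """Pearson correlation between expression and identical-copy counts.

    Computed on untransformed values over the families present in both
    inputs; returns (r, n).
    """
    fams = sorted(set(reads_per_family) & set(identical_copies))
    if len(fams) < 3:
        raise ValueError("need at least 3 families")
    x = np.array([reads_per_family[f] for f in fams], dtype=float)
    y = np.array([identical_copies[f] for f in fams], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in correlation input")
    r = float(stats.pearsonr(x, y).statistic)
    return r, len(fams)


def plot_heatmaps(
    normalized: pd.DataFrame, log_normalized: pd.DataFrame, path: str
) -> None:
    """Two-panel expression heatmap (linear global-max and log-scaled)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 0.6 + 0.3 * len(normalized)))
    for ax, mat, title in (
        (axes[0], normalized, "normalized"),
        (axes[1], log_normalized, "log scale"),
    ):
        im = ax.imshow(mat.to_numpy(), cmap="viridis", vmin=0, vmax=1, aspect="auto")
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(mat.shape[0]), mat.index)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def tests_table(results: list[StageTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            dict(
                family=r.family,
                anova_F="" if r.anova_F is None else r.anova_F,
                anova_p="" if r.anova_p is None else r.anova_p,
                significant=r.significant,
                top_two_stages="" if not r.top_two_stages else "|".join(r.top_two_stages),
                t_stat="" if r.t_stat is None else r.t_stat,
                t_p="" if r.t_p is None else r.t_p,
                elevated_stage=r.elevated_stage or "",
            )
        )
    return pd.DataFrame(rows)
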