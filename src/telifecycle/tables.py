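"""Packaged characterization table for the 23 Capsaspora owczarzaki TE
families (five LTR retrotransposon, four non-LTR retrotransposon and 14 DNA
transposon families): copy numbers with the FLE/solo split for LTR
families, RNA-seq read totals, identical-paralogous-copy counts,
intra-element LTR identity ranges, nucleotide diversity and Tajima's D.

The single-copy Cobalt3 family has no diversity statistics; CoCACTA2's D is
not calculable (overlapping indels leave no usable sites).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# Printed study-wide read totals used for expression shares.
TOTAL_RNASEQ_READS = 394_576_834
TE_ORIGIN_READS = 1_165_292


def load_family_table() -> pd.DataFrame:
    """The 23-family characterization table as a DataFrame."""
    ref = resources.files("telifecycle.data") / "capsaspora_te_families.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def reads_identical_correlation() -> tuple[float, int]:
    """Pearson r between RNA-seq read counts and identical-copy counts
    across all 23 families (untransformed values)."""
    from .express import activity_correlation

    df = load_family_table()
    reads = dict(zip(df["family"], df["rnaseq_reads"].astype(float)))
    ident = dict(zip(df["family"], df["identical_copies"].astype(float)))
    return activity_correlation(reads, ident)


def expression_shares() -> dict[str, float]:
    """Read-share percentages: the dominant family among TE reads and TE
    reads among all reads, each at one decimal."""
    df = load_family_table()
    top = df.loc[df["rnaseq_reads"].idxmax()]
    return {
        "top_family": str(top["family"]),
        "top_family_share_pct": round(100.0 * top["rnaseq_reads"] / TE_ORIGIN_READS, 1),
        "te_share_pct": round(100.0 * TE_ORIGIN_READS / TOTAL_RNASEQ_READS, 1),
    }
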