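"""Locate family-terminus matches in genome sequence and extract flanks.

Search strategy: exact seed_len-mer matches between query terminus and
genome fix an ungapped diagonal; the full query-length window on that
diagonal is then evaluated directly, and the window is reported when its
identity is at least min_identity over at least min_cov of the query
length (windows clipped at contig edges are covered by the min_cov term).
Both strands are searched; minus-strand hits are reported in forward
genome coordinates with flanks re-oriented to the hit strand.  Overlapping
hits of the same query keep the higher identity, ties the leftmost.

Query termini longer than 300 bp are truncated with a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import GenomeInterval, SequenceRecord, log, revcomp

MAX_QUERY_LEN = 300


@dataclass(frozen=True)
class TerminusQuery:
    """One family terminus used as a search query."""

    family: str
    end_type: str  # {five_prime, three_prime, ltr}
    seq: str

    def __post_init__(self) -> None:
        if self.end_type not in ("five_prime", "three_prime", "ltr"):
            raise ValueError(f"unknown end_type {self.end_type!r}")


@dataclass
class TerminusHit:
    """A located terminus: interval in forward genome coordinates.

    Flanks are taken in the hit's strand orientation: up_flank is 5' of the
    element terminus, down_flank 3'.  edge_flag marks flanks or windows
    shortened at contig bounds.
    """

    family: str
    end_type: str
    interval: GenomeInterval
    identity: float
    up_flank: str = ""
    down_flank: str = ""
    edge_flag: bool = False


def _seq_to_arr(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype="S1")


def _scan_one_strand(
    garr: np.ndarray,
    contig: str,
    glen: int,
    query: TerminusQuery,
    qseq: str,
    strand: str,
    kmer_index: dict[bytes, list[int]],
    seed_len: int,
    min_identity: float,
    min_cov: float,
) -> list[TerminusHit]:
    qarr = _seq_to_arr(qseq)
    qlen = qarr.size
    diagonals: set[int] = set()
    qbytes = qseq.encode()
    for qo in range(0, qlen - seed_len + 1):
        kmer = qbytes[qo : qo + seed_len]
        for gp in kmer_index.get(kmer, ()):
            diagonals.add(gp - qo)
    hits: list[TerminusHit] = []
    for diag in sorted(diagonals):
        gs, ge = max(diag, 0), min(diag + qlen, glen)
        win = ge - gs
        if win < max(1, int(np.ceil(min_cov * qlen))):
            continue
        qs = gs - diag
        matches = int(np.sum(garr[gs:ge] == qarr[qs : qs + win]))
        ident = matches / win
        if ident < min_identity:
            continue
        if strand == "+":
            interval = GenomeInterval(contig, gs, ge, "+")
        else:
            interval = GenomeInterval(contig, glen - ge, glen - gs, "-")
        hits.append(TerminusHit(query.family, query.end_type, interval, ident, edge_flag=win < qlen))
    return hits


def _merge_overlaps(hits: list[TerminusHit]) -> list[TerminusHit]:
    """Among same-query hits, drop any that overlaps a better one.

    Better = higher identity; ties keep the smaller start.
    """
    hits = sorted(hits, key=lambda h: (-h.identity, h.interval.start))
    kept: list[TerminusHit] = []
    for h in hits:
        if any(k.interval.overlap(h.interval) > 0 for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.interval.contig, h.interval.start))
    return kept


def scan_genome(
    genome: list[SequenceRecord],
    queries: list[TerminusQuery],
    seed_len: int = 12,
    min_identity: float = 0.80,
    min_cov: float = 0.50,
    flank_len: int = 20,
) -> list[TerminusHit]:
    """Find all terminus matches on both strands of every contig."""
    if not queries:
        raise ValueError("empty query set")
    if seed_len < 8:
        raise ValueError("seed_len must be >= 8")
    capped = []
    for q in queries:
        if len(q.seq) > MAX_QUERY_LEN:
            log.warning(
                "query %s/%s truncated from %d to %d bp",
                q.family,
                q.end_type,
                len(q.seq),
                MAX_QUERY_LEN,
            )
            q = replace(q, seq=q.seq[:MAX_QUERY_LEN])
        capped.append(q)

    all_hits: list[TerminusHit] = []
    for contig in genome:
        gseq = contig.seq
        glen = len(gseq)
        garr = _seq_to_arr(gseq)
        rc = revcomp(gseq)
        rcarr = _seq_to_arr(rc)
        index: dict[bytes, list[int]] = {}
        gb = gseq.encode()
        for i in range(glen - seed_len + 1):
            index.setdefault(gb[i : i + seed_len], []).append(i)
        rc_index: dict[bytes, list[int]] = {}
        rb = rc.encode()
        for i in range(glen - seed_len + 1):
            rc_index.setdefault(rb[i : i + seed_len], []).append(i)
        for q in capped:
            fw = _scan_one_strand(
                garr, contig.id, glen, q, q.seq, "+", index, seed_len, min_identity, min_cov
            )
            # minus strand: scan the reverse-complemented contig with the query;
            # coordinates are mapped back to forward inside _scan_one_strand
            rv = _scan_one_strand(
                rcarr, contig.id, glen, q, q.seq, "-", rc_index, seed_len, min_identity, min_cov
            )
            merged = _merge_overlaps(fw + rv)
            for h in merged:
                all_hits.append(extract_flanks(contig, h, flank_len))
    all_hits.sort(key=lambda h: (h.interval.contig, h.interval.start, h.family, h.end_type))
    return all_hits


def extract_flanks(contig: SequenceRecord, hit: TerminusHit, flank_len: int = 20) -> TerminusHit:
    """Attach flank_len bases of flanking DNA in hit-strand orientation.

    up_flank is 5' of the hit on its own strand; flanks shortened at contig
    edges set edge_flag.
    """
    gseq = contig.seq
    iv = hit.interval
    left = gseq[max(0, iv.start - flank_len) : iv.start]
    right = gseq[iv.end : iv.end + flank_len]
    edge = hit.edge_flag or len(left) < flank_len or len(right) < flank_len
    if iv.strand == "+":
        up, down = left, right
    else:
        up, down = revcomp(right), revcomp(left)
    return replace(hit, up_flank=up, down_flank=down, edge_flag=edge)


def hit_sequence(contig: SequenceRecord, hit: TerminusHit) -> str:
    """Terminus sequence in hit-strand (element) orientation."""
    s = contig.seq[hit.interval.start : hit.interval.end]
    return s if hit.interval.strand == "+" else revcomp(s)


def hits_table(hits: list[TerminusHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        s1, e1 = h.interval.to_report()
        rows.append(
            dict(
                family=h.family,
                end_type=h.end_type,
                contig=h.interval.contig,
                start=s1,
                end=e1,
                strand=h.interval.strand,
                identity=h.identity,
                up_flank=h.up_flank,
                down_flank=h.down_flank,
                edge_flag=h.edge_flag,
            )
        )
    return pd.DataFrame(rows)
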