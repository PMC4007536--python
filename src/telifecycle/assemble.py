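"""Pair termini into individual inserts via TSD and flank evidence.

An integrated element is flanked by two copies of the same target-site
duplication (TSD), so the tsd_len bases immediately upstream of its 5'
terminus must equal the tsd_len bases immediately downstream of its 3'
terminus.  Pairing is greedy left-to-right along each contig: a candidate
pairs with its nearest downstream partner of compatible end type on the
same strand within max_span, if and only if the TSD test passes.  A lone
LTR hit whose own upstream flank tail equals its downstream flank head is
a solo LTR.  Anything else is emitted unpaired (a lone 3' terminus of a
non-LTR family is called truncated, the dead-on-arrival structure).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discover import TerminusHit

TSD_SCAN_RANGE = range(2, 13)


@dataclass
class ElementCopy:
    """One reconstructed insert (or unpaired terminus)."""

    copy_id: str
    family: str
    structure: str  # {FLE, soloLTR, full, truncated, unpaired}
    five_hit: TerminusHit | None = None
    three_hit: TerminusHit | None = None
    tsd_seq: str | None = None
    span: int = 0
    intra_ltr_identity: float | None = None
    low_confidence: bool = False

    @property
    def contig(self) -> str:
        hit = self.five_hit or self.three_hit
        return hit.interval.contig

    @property
    def outer_span(self) -> tuple[int, int]:
        """0-based half-open bounds over both termini."""
        ivs = [h.interval for h in (self.five_hit, self.three_hit) if h is not None]
        return min(iv.start for iv in ivs), max(iv.end for iv in ivs)


@dataclass
class TSDProfile:
    """Positional base composition of a family's TSDs."""

    family: str
    inferred_len: int | None
    per_position_freq: pd.DataFrame  # positions x {A,C,G,T}
    gc_by_position: list[float]
    n_sites: int


def _tsd_match(a: str, b: str, k: int, max_mismatch: int = 0) -> bool:
    if len(a) < k or len(b) < k or k == 0:
        return False
    return sum(x != y for x, y in zip(a[-k:], b[:k])) <= max_mismatch


def _element_orientation(hits: list[TerminusHit]) -> list[TerminusHit]:
    return sorted(hits, key=lambda h: (h.interval.contig, h.interval.start, h.interval.end))


def pair_inserts(
    hits: list[TerminusHit],
    te_class: str,
    tsd_len: int,
    max_span: int = 15_000,
    tsd_mismatch: int = 0,
) -> list[ElementCopy]:
    """Pair one family's terminus hits into element copies.

    With tsd_len = 0 pairing falls back to proximity only and every pair is
    flagged low-confidence.
    """
    ordered = _element_orientation(hits)
    used = [False] * len(ordered)
    copies: list[ElementCopy] = []
    serial = 0

    def next_partner(i: int) -> int | None:
        h = ordered[i]
        for j in range(i + 1, len(ordered)):
            if used[j]:
                continue
            h2 = ordered[j]
            if h2.interval.contig != h.interval.contig:
                return None
            if h2.interval.strand != h.interval.strand:
                continue
            if h2.interval.end - h.interval.start > max_span:
                return None
            if h2.interval.start < h.interval.end:
                continue
            return j
        return None

    for i, h in enumerate(ordered):
        if used[i]:
            continue
        strand = h.interval.strand
        j = next_partner(i)
        paired = False
        if j is not None:
            h2 = ordered[j]
            # element orientation: on the minus strand the genomic-left hit is
            # the element's 3' end
            five, three = (h, h2) if strand == "+" else (h2, h)
            types_ok = (
                {five.end_type, three.end_type} == {"ltr"}
                if te_class == "LTR"
                else (five.end_type == "five_prime" and three.end_type == "three_prime")
            )
            if types_ok:
                if tsd_len == 0:
                    tsd_ok, tsd = True, None
                    lowconf = True
                else:
                    tsd_ok = _tsd_match(five.up_flank, three.down_flank, tsd_len, tsd_mismatch)
                    tsd = five.up_flank[-tsd_len:] if tsd_ok else None
                    lowconf = False
                if tsd_ok:
                    serial += 1
                    structure = "FLE" if te_class == "LTR" else "full"
                    a, b = (
                        min(h.interval.start, h2.interval.start),
                        max(h.interval.end, h2.interval.end),
                    )
                    copies.append(
                        ElementCopy(
                            f"{five.family}_p{serial:03d}",
                            five.family,
                            structure,
                            five,
                            three,
                            tsd,
                            span=b - a,
                            low_confidence=lowconf,
                        )
                    )
                    used[i] = used[j] = True
                    paired = True
        if paired:
            continue
        # solo-LTR test: the lone LTR is itself flanked by the duplication
        if (
            te_class == "LTR"
            and h.end_type == "ltr"
            and tsd_len > 0
            and _tsd_match(h.up_flank, h.down_flank, tsd_len, tsd_mismatch)
        ):
            serial += 1
            copies.append(
                ElementCopy(
                    f"{h.family}_p{serial:03d}",
                    h.family,
                    "soloLTR",
                    five_hit=h,
                    tsd_seq=h.up_flank[-tsd_len:],
                    span=len(h.interval),
                )
            )
            used[i] = True
            continue
        serial += 1
        structure = "unpaired"
        if te_class == "nonLTR" and h.end_type == "three_prime":
            structure = "truncated"
        copies.append(
            ElementCopy(
                f"{h.family}_p{serial:03d}",
                h.family,
                structure,
                five_hit=h if h.end_type != "three_prime" else None,
                three_hit=h if h.end_type == "three_prime" else None,
                span=len(h.interval),
            )
        )
        used[i] = True
    return copies


def intra_ltr_identity(ltr5: str, ltr3: str) -> tuple[float, bool]:
    """Percent identity between the two LTRs of an FLE, one decimal.

    Equal-length sequences are compared position-wise; unequal lengths fall
    back to a prefix comparison over the shorter length and are flagged.
    """
    flagged = len(ltr5) != len(ltr3)
    L = min(len(ltr5), len(ltr3))
    if L == 0:
        raise ValueError("empty LTR sequence")
    matches = sum(a == b for a, b in zip(ltr5[:L], ltr3[:L]))
    return round(100.0 * matches / L, 1), flagged


def longest_duplication(up_flank: str, down_flank: str, scan=TSD_SCAN_RANGE) -> int:
    """Longest k in the scan range with up_flank tail == down_flank head (0 if none)."""
    best = 0
    for k in scan:
        if len(up_flank) >= k and len(down_flank) >= k and up_flank[-k:] == down_flank[:k]:
            best = k
    return best


def infer_tsd_len(
    candidates: list[tuple[str, str]], scan=TSD_SCAN_RANGE
) -> tuple[int | None, list[str | None]]:
    """Infer a family's TSD length from (up_flank, down_flank) candidates.

    Per insert, the longest duplicated k in the scan range; the family value
    is the modal k over inserts showing a duplication (ties broken toward the
    shorter length).  With fewer than 3 candidates the family value is None
    but per-insert TSDs are still reported.
    """
    per_insert: list[str | None] = []
    lens: list[int] = []
    for up, down in candidates:
        k = longest_duplication(up, down, scan)
        if k >= 2:
            per_insert.append(up[-k:])
            lens.append(k)
        else:
            per_insert.append(None)
    if len(candidates) < 3 or not lens:
        return None, per_insert
    counts = Counter(lens)
    top = max(counts.values())
    inferred = min(k for k, c in counts.items() if c == top)
    return inferred, per_insert


def tsd_composition(tsds: list[str], family: str = "") -> TSDProfile:
    """Per-position base frequencies and GC content of equal-length TSDs."""
    if not tsds:
        raise ValueError("no TSDs supplied")
    L = len(tsds[0])
    if any(len(t) != L for t in tsds):
        raise ValueError("TSDs of mixed length")
    freq = np.zeros((L, 4))
    bases = "ACGT"
    counted = np.zeros(L)
    for t in tsds:
        for i, c in enumerate(t.upper()):
            if c in bases:
                freq[i, bases.index(c)] += 1
                counted[i] += 1
    counted[counted == 0] = 1.0
    freq = freq / counted[:, None]
    df = pd.DataFrame(freq, columns=list(bases))
    df.insert(0, "position", np.arange(1, L + 1))
    gc = [float(freq[i, 1] + freq[i, 2]) for i in range(L)]
    return TSDProfile(family, L, df, gc, len(tsds))


def copies_table(copies: list[ElementCopy]) -> pd.DataFrame:
    rows = []
    for c in copies:
        a, b = c.outer_span
        rows.append(
            dict(
                copy_id=c.copy_id,
                family=c.family,
                structure=c.structure,
                contig=c.contig,
                start=a + 1,
                end=b,
                strand=(c.five_hit or c.three_hit).interval.strand,
                span=c.span,
                tsd_seq=c.tsd_seq or "",
                intra_ltr_identity="" if c.intra_ltr_identity is None else c.intra_ltr_identity,
                low_confidence=c.low_confidence,
            )
        )
    return pd.DataFrame(rows)
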