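"""Synthetic genomes with planted transposable-element families.

The generator emulates the statistical structure the downstream analyses
assume.  Each family descends from a master consensus: a copy of age ``t``
is the (sub)family founder sequence plus independent per-site substitutions
with probability ``p(t) = 1 - exp(-mu * t)``, each substitution drawn
uniformly from the three alternative bases (Jukes-Cantor).  LTR
retrotransposon copies carry two terminal repeats that are identical at
insertion and then mutate independently, so the expected intra-element LTR
divergence of an age-``t`` copy is approximately ``2*mu*t``.  Full-length
LTR copies convert to solo LTRs (ectopic recombination, 5' LTR retained)
with probability ``1 - exp(-rho * t)``; non-LTR copies are 5'-truncated
with probability ``q`` at a uniform breakpoint that spares the 3' UTR.

Insertion histories are either a constant-rate process over a horizon or a
list of discrete bursts; ages are in arbitrary units (only ``mu * t``
products matter).  Planting duplicates the target site so every insert is
flanked by identical target-site duplications (TSDs), optionally with a TA
or GC-biased target preference.  Stage-structured read sets are drawn per
family/stage/replicate from a negative binomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenomeInterval, SequenceRecord, revcomp

STAGES = ("adherent", "floating", "aggregate")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Burst:
    """A transposition burst: ``count`` insertions all of age ``age``."""

    age: float
    count: int

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("burst age must be >= 0")
        if self.count < 1:
            raise ValueError("burst count must be >= 1")


@dataclass(frozen=True)
class ConstantHistory:
    """Constant insertion rate ``rate`` per time unit over ``[0, horizon]``."""

    rate: float
    horizon: float


@dataclass
class TEFamilyModel:
    """Parameterization of one simulated TE family.

    ``terminus_len`` is the LTR length for LTR families and the 5'/3'
    noncoding terminus length otherwise; ``mu`` is the substitution rate
    per site per time unit; ``solo_rate`` the per-time FLE→solo conversion
    rate (LTR only); ``trunc_prob`` the 5'-truncation probability (non-LTR
    only); ``stage_means`` the expected read counts per life-cycle stage.
    """

    name: str
    te_class: str  # {LTR, nonLTR, DNA}
    terminus_len: int = 150
    internal_len: int = 1000
    tsd_len: int = 5
    target_pref: str = "none"  # {none, TA, GC_ends}
    history: ConstantHistory | list[Burst] = field(default_factory=lambda: [Burst(0.02, 20)])
    subfamily_split_age: float = 0.0
    mu: float = 1.0
    solo_rate: float = 0.0
    trunc_prob: float = 0.0
    loss_rate: float = 0.0
    stage_means: tuple[float, float, float] = (100.0, 100.0, 100.0)
    dispersion: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.te_class not in ("LTR", "nonLTR", "DNA"):
            raise ValueError(f"unknown te_class {self.te_class!r}")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if not 0.0 <= self.trunc_prob <= 1.0:
            raise ValueError("trunc_prob must be in [0, 1]")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if len(self.stage_means) != 3:
            raise ValueError("stage_means must have exactly 3 entries")
        if self.target_pref not in ("none", "TA", "GC_ends"):
            raise ValueError(f"unknown target_pref {self.target_pref!r}")
        if self.target_pref == "TA" and self.tsd_len != 2:
            raise ValueError("TA target preference requires tsd_len = 2")
        if isinstance(self.history, list):
            for b in self.history:
                if not isinstance(b, Burst):
                    raise ValueError("burst history must be a list of Burst")


@dataclass
class SimCopy:
    """One simulated element copy before genome planting.

    ``five_span`` / ``three_span`` are 0-based half-open terminus intervals
    in copy-local coordinates (element orientation); absent termini are None.
    """

    copy_id: str
    family: str
    structure: str  # {FLE, soloLTR, full, truncated}
    age: float
    seq: str
    five_span: tuple[int, int] | None
    three_span: tuple[int, int] | None
    subfamily: int = 0


@dataclass
class TruthRecord:
    """Planted-truth row for one genomic insert."""

    copy_id: str
    family: str
    structure: str
    age: float
    interval: GenomeInterval
    five_interval: GenomeInterval | None
    three_interval: GenomeInterval | None
    tsd_seq: str
    subfamily: int = 0


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode()


def mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    """Independent per-site substitution with probability p; uniform over the
    three alternative bases."""
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < p
    idx = np.nonzero(hit)[0]
    if idx.size:
        cur = arr[idx]
        # draw from the 3 alternatives by offsetting the current base index
        base_idx = np.searchsorted(_BASES, cur)
        # non-ACGT (N) positions are left untouched
        ok = cur == _BASES[np.clip(base_idx, 0, 3)]
        offs = rng.integers(1, 4, size=idx.size)
        newb = _BASES[(base_idx + offs) % 4]
        arr[idx[ok]] = newb[ok]
    return arr.tobytes().decode()


def _draw_ages(model: TEFamilyModel, rng: np.random.Generator) -> np.ndarray:
    if isinstance(model.history, ConstantHistory):
        n = rng.poisson(model.history.rate * model.history.horizon)
        ages = rng.uniform(0.0, model.history.horizon, size=n)
    else:
        ages = np.concatenate([np.full(b.count, b.age) for b in model.history])
    if model.loss_rate > 0 and ages.size:
        keep = rng.random(ages.size) < np.exp(-model.loss_rate * ages)
        ages = ages[keep]
    return np.sort(ages)[::-1]  # oldest first, purely for stable ids


@dataclass
class FamilyConsensus:
    """Ancestral sequence parts for one family."""

    terminus5: str
    internal: str
    terminus3: str

    @property
    def full(self) -> str:
        return self.terminus5 + self.internal + self.terminus3


def family_consensus(model: TEFamilyModel, rng: np.random.Generator, gc: float = 0.5) -> FamilyConsensus:
    """Draw the ancestral consensus for a family.

    For LTR families the 5' and 3' termini are the same LTR sequence; for
    non-LTR and DNA families the two noncoding termini are independent.
    """
    t5 = random_dna(rng, model.terminus_len, gc)
    t3 = t5 if model.te_class == "LTR" else random_dna(rng, model.terminus_len, gc)
    return FamilyConsensus(t5, random_dna(rng, model.internal_len, gc), t3)


def simulate_family(
    model: TEFamilyModel,
    rng: np.random.Generator,
    consensus: FamilyConsensus | None = None,
) -> tuple[list[SimCopy], FamilyConsensus]:
    """Simulate the copies of one family (sequences in element orientation).

    Returns the copies and the consensus used.  Raises if the insertion
    history yields zero copies.
    """
    if consensus is None:
        consensus = family_consensus(model, rng)
    ages = _draw_ages(model, rng)
    if ages.size == 0:
        raise ValueError(f"family {model.name}: insertion history produced zero copies")

    # Subfamily founders: each founder diverged from the ancestral consensus
    # subfamily_split_age time units ago.
    founders: list[FamilyConsensus]
    if model.subfamily_split_age > 0:
        p_split = 1.0 - math.exp(-model.mu * model.subfamily_split_age)
        founders = []
        for _ in range(2):
            t5 = mutate(consensus.terminus5, p_split, rng)
            t3 = t5 if model.te_class == "LTR" else mutate(consensus.terminus3, p_split, rng)
            founders.append(FamilyConsensus(t5, mutate(consensus.internal, p_split, rng), t3))
    else:
        founders = [consensus]

    Lt = model.terminus_len
    copies: list[SimCopy] = []
    for i, age in enumerate(ages):
        sub = int(rng.integers(0, len(founders)))
        fdr = founders[sub]
        p = 1.0 - math.exp(-model.mu * age)
        cid = f"{model.name}_c{i:03d}"
        if model.te_class == "LTR":
            # both LTRs identical at insertion, then mutate independently
            full = mutate(fdr.terminus5 + fdr.internal + fdr.terminus5, p, rng)
            p_solo = 1.0 - math.exp(-model.solo_rate * age) if model.solo_rate > 0 else 0.0
            if rng.random() < p_solo:
                copies.append(SimCopy(cid, model.name, "soloLTR", age, full[:Lt], (0, Lt), None, sub))
            else:
                L = len(full)
                copies.append(SimCopy(cid, model.name, "FLE", age, full, (0, Lt), (L - Lt, L), sub))
        else:
            full = mutate(fdr.full, p, rng)
            L = len(full)
            if model.te_class == "nonLTR" and rng.random() < model.trunc_prob:
                # uniform 5' breakpoint sparing the 3' terminus
                bp = int(rng.integers(1, L - Lt + 1))
                trunc = full[bp:]
                Lr = len(trunc)
                copies.append(SimCopy(cid, model.name, "truncated", age, trunc, None, (Lr - Lt, Lr), sub))
            else:
                copies.append(SimCopy(cid, model.name, "full", age, full, (0, Lt), (L - Lt, L), sub))
    return copies, consensus


def _target_sites(
    bg: str,
    model: TEFamilyModel,
    n: int,
    rng: np.random.Generator,
    min_gap: int,
    taken: list[tuple[int, int]],
) -> list[int]:
    """Choose n non-overlapping target-site starts in background coordinates."""
    k = model.tsd_len
    L = len(bg)
    lo, hi = min_gap, L - min_gap - max(k, 1)
    if hi <= lo:
        raise ValueError("background too short for requested placements")

    def clashes(s: int) -> bool:
        return any(s - min_gap < e and o < s + k + min_gap for o, e in taken)

    chosen: list[int] = []
    if model.target_pref == "TA":
        cand = np.array([i for i in range(lo, hi) if bg[i : i + 2] == "TA"])
        rng.shuffle(cand)
        for s in cand:
            if not clashes(int(s)):
                chosen.append(int(s))
                taken.append((int(s), int(s) + k))
                if len(chosen) == n:
                    break
        if len(chosen) < n:
            raise ValueError(f"family {model.name}: insufficient TA target sites")
        return chosen

    if model.target_pref == "GC_ends":
        # weight ends of the tsd-mer toward G/C (positions 1 and 5, 1-based)
        end_pos = [0, min(4, k - 1)] if k >= 1 else []
        for _ in range(200 * n):
            if len(chosen) == n:
                break
            s = int(rng.integers(lo, hi))
            if clashes(s):
                continue
            w = 1.0
            for j in set(end_pos):
                w *= 3.0 if bg[s + j] in "GC" else 1.0
            if rng.random() < w / 9.0:
                chosen.append(s)
                taken.append((s, s + k))
    else:
        for _ in range(200 * n):
            if len(chosen) == n:
                break
            s = int(rng.integers(lo, hi))
            if not clashes(s):
                chosen.append(s)
                taken.append((s, s + k))
    if len(chosen) < n:
        raise ValueError(f"family {model.name}: could not place {n} non-overlapping inserts")
    return chosen


def plant_genome(
    background_len: int,
    background_gc: float,
    families: list[tuple[TEFamilyModel, list[SimCopy]]],
    rng: np.random.Generator,
    contig_name: str = "chr1",
    min_gap: int = 60,
) -> tuple[SequenceRecord, list[TruthRecord]]:
    """Insert simulated copies into a random background with TSD duplication.

    Each copy is placed at a target site sampled per the family's target
    preference; the ``tsd_len`` target bases are duplicated so the insert is
    flanked by identical TSDs.  Placements are non-overlapping and separated
    by at least ``min_gap`` background bases.  Returns the genome and the
    per-insert truth records (final genome coordinates).
    """
    bg = random_dna(rng, background_len, background_gc)
    taken: list[tuple[int, int]] = []
    placements: list[tuple[int, SimCopy, TEFamilyModel, str]] = []
    for model, copies in families:
        sites = _target_sites(bg, model, len(copies), rng, min_gap, taken)
        for s, copy in zip(sites, copies):
            strand = "+" if rng.random() < 0.5 else "-"
            placements.append((s, copy, model, strand))
    placements.sort(key=lambda t: t[0])

    parts: list[str] = []
    truth: list[TruthRecord] = []
    prev = 0
    for s, copy, model, strand in placements:
        k = model.tsd_len
        tsd = bg[s : s + k]
        parts.append(bg[prev : s + k])
        g0 = sum(len(p) for p in parts)  # start of insert in final coordinates
        ins = copy.seq if strand == "+" else revcomp(copy.seq)
        parts.append(ins)
        parts.append(tsd)
        L = len(ins)

        def to_genome(span: tuple[int, int] | None) -> GenomeInterval | None:
            if span is None:
                return None
            a, b = span
            if strand == "+":
                return GenomeInterval(contig_name, g0 + a, g0 + b, "+")
            return GenomeInterval(contig_name, g0 + L - b, g0 + L - a, "-")

        truth.append(
            TruthRecord(
                copy.copy_id,
                copy.family,
                copy.structure,
                copy.age,
                GenomeInterval(contig_name, g0, g0 + L, strand),
                to_genome(copy.five_span),
                to_genome(copy.three_span),
                tsd,
                copy.subfamily,
            )
        )
        prev = s + k
    parts.append(bg[prev:])
    genome = SequenceRecord(contig_name, "".join(parts), "synthetic genome with planted TEs")
    return genome, truth


def truth_table(truth: list[TruthRecord]) -> pd.DataFrame:
    """Truth records as a TSV-ready table (1-based inclusive coordinates)."""
    rows = []
    for t in truth:
        s1, e1 = t.interval.to_report()
        rows.append(
            dict(
                copy_id=t.copy_id,
                family=t.family,
                structure=t.structure,
                age=t.age,
                contig=t.interval.contig,
                start=s1,
                end=e1,
                strand=t.interval.strand,
                tsd=t.tsd_seq,
                subfamily=t.subfamily,
            )
        )
    return pd.DataFrame(rows)


def _nb_count(mean: float, dispersion: float, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 0
    if not math.isfinite(dispersion):
        return int(rng.poisson(mean))
    return int(rng.negative_binomial(dispersion, dispersion / (dispersion + mean)))


def simulate_reads(
    families: list[tuple[TEFamilyModel, list[SimCopy]]],
    rng: np.random.Generator,
    read_len: int = 70,
    error_rate: float = 0.01,
    replicates: int = 3,
    stages: tuple[str, ...] = STAGES,
) -> tuple[dict[tuple[str, int], list[SequenceRecord]], pd.DataFrame]:
    """Stage-structured read sets per family.

    Read counts per family/stage/replicate are negative binomial with the
    family's stage mean and dispersion (``dispersion = inf`` gives Poisson).
    Reads are sampled uniformly along uniformly chosen copies on a random
    strand, with substitution errors at ``error_rate``.  Returns the reads
    keyed by (stage, replicate) and a truth-count table.
    """
    for model, copies in families:
        shortest = min(len(c.seq) for c in copies)
        if read_len > shortest:
            raise ValueError(
                f"read_len {read_len} exceeds shortest {model.name} copy ({shortest} bp)"
            )
    reads: dict[tuple[str, int], list[SequenceRecord]] = {
        (s, r): [] for s in stages for r in range(1, replicates + 1)
    }
    counts = []
    for model, copies in families:
        for si, stage in enumerate(stages):
            for rep in range(1, replicates + 1):
                n = _nb_count(model.stage_means[si], model.dispersion, rng)
                counts.append(dict(family=model.name, stage=stage, replicate=rep, count=n))
                for i in range(n):
                    copy = copies[int(rng.integers(0, len(copies)))]
                    start = int(rng.integers(0, len(copy.seq) - read_len + 1))
                    frag = copy.seq[start : start + read_len]
                    if error_rate > 0:
                        frag = mutate(frag, error_rate, rng)
                    if rng.random() < 0.5:
                        frag = revcomp(frag)
                    reads[(stage, rep)].append(
                        SequenceRecord(f"{model.name}|{stage}|{rep}|{i}", frag)
                    )
    return reads, pd.DataFrame(counts)
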