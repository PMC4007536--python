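import math
from collections import Counter

import numpy as np
import pytest

from telifecycle.io import Alignment, revcomp, write_fasta
from telifecycle.popgen import nucleotide_diversity
from telifecycle.simulate import (
    Burst,
    ConstantHistory,
    TEFamilyModel,
    mutate,
    plant_genome,
    simulate_family,
    simulate_reads,
)


def ltr_model(**kw):
    base = dict(name="L", te_class="LTR", terminus_len=150, internal_len=300)
    base.update(kw)
    return TEFamilyModel(**base)


class TestSimulateFamily:
    def test_age_zero_burst_gives_identical_copies(self, rng):
        copies, cons = simulate_family(ltr_model(history=[Burst(0.0, 10)]), rng)
        aln = Alignment([c.copy_id for c in copies], [c.seq[:150] for c in copies])
        assert nucleotide_diversity(aln)[0] == 0.0
        assert all(c.seq == cons.terminus5 + cons.internal + cons.terminus5 for c in copies)

    def test_intra_ltr_divergence_matches_clock_expectation(self, rng):
        mu_t = 0.05
        copies, _ = simulate_family(
            ltr_model(history=[Burst(mu_t, 200)], internal_len=50), rng
        )
        divs = []
        for c in copies:
            a, b = c.seq[:150], c.seq[-150:]
            divs.append(sum(x != y for x, y in zip(a, b)) / 150)
        # two independently mutating LTRs: expected per-site difference
        p = 1 - math.exp(-mu_t)
        expect = 2 * p * (1 - p) + p * p * (2 / 3)
        se = np.std(divs, ddof=1) / math.sqrt(len(divs))
        assert abs(np.mean(divs) - expect) <= 3 * se + 1e-3
        assert np.mean(divs) == pytest.approx(2 * mu_t, rel=0.15)

    @pytest.mark.parametrize("q,expected", [(1.0, {"truncated"}), (0.0, {"full"})])
    def test_truncation_probability_boundaries(self, rng, q, expected):
        model = TEFamilyModel(
            "n", "nonLTR", terminus_len=100, internal_len=400,
            history=[Burst(0.01, 20)], trunc_prob=q,
        )
        copies, _ = simulate_family(model, rng)
        assert {c.structure for c in copies} == expected
        if q == 1.0:
            # the 3' terminus always survives truncation
            assert all(c.three_span is not None and c.five_span is None for c in copies)

    def test_zero_copy_history_rejected(self, rng):
        with pytest.raises(ValueError, match="zero copies"):
            simulate_family(ltr_model(history=ConstantHistory(0.0, 1.0)), rng)

    def test_solo_fraction_converges_to_conversion_probability(self):
        rng = np.random.default_rng(99)
        t, rho = 0.1, 10.0
        copies, _ = simulate_family(
            ltr_model(history=[Burst(t, 1000)], internal_len=50, solo_rate=rho), rng
        )
        frac = np.mean([c.structure == "soloLTR" for c in copies])
        expect = 1 - math.exp(-rho * t)
        assert abs(frac - expect) <= 3 * math.sqrt(expect * (1 - expect) / 1000)

    def test_recent_burst_site_spectrum_dominated_by_singletons(self):
        rng = np.random.default_rng(5)
        model = TEFamilyModel(
            "b", "DNA", terminus_len=300, internal_len=50, history=[Burst(0.02, 25)]
        )
        copies, _ = simulate_family(model, rng)
        aln = Alignment([c.copy_id for c in copies], [c.seq[:300] for c in copies])
        singletons = intermediates = 0
        for j in range(aln.length):
            col = aln.column(j)
            counts = sorted(Counter(col).values())
            if len(counts) < 2:
                continue
            minor = sum(counts[:-1])
            if minor == 1:
                singletons += 1
            elif minor >= 2:
                intermediates += 1
        assert singletons >= intermediates


class TestPlantGenome:
    def test_ta_preference_constrains_every_tsd(self, rng):
        model = TEFamilyModel(
            "d", "DNA", terminus_len=80, internal_len=100, tsd_len=2,
            target_pref="TA", history=[Burst(0.0, 10)],
        )
        copies, _ = simulate_family(model, rng)
        genome, truth = plant_genome(50_000, 0.5, [(model, copies)], rng)
        for t in truth:
            assert t.tsd_seq == "TA"
            iv = t.interval
            assert genome.seq[iv.start - 2 : iv.start] == "TA"
            assert genome.seq[iv.end : iv.end + 2] == "TA"

    def test_zero_tsd_means_no_duplication(self, rng):
        model = TEFamilyModel(
            "d", "DNA", terminus_len=80, internal_len=100, tsd_len=0,
            history=[Burst(0.0, 8)],
        )
        copies, _ = simulate_family(model, rng)
        _, truth = plant_genome(40_000, 0.5, [(model, copies)], rng)
        assert all(t.tsd_seq == "" for t in truth)

    def test_fixed_seed_reproduces_genome(self):
        def build(seed):
            rng = np.random.default_rng(seed)
            model = TEFamilyModel(
                "d", "DNA", terminus_len=80, internal_len=100, history=[Burst(0.01, 20)]
            )
            copies, _ = simulate_family(model, rng)
            return plant_genome(200_000, 0.5, [(model, copies)], rng)

        g1, t1 = build(42)
        g2, t2 = build(42)
        assert g1.seq == g2.seq
        assert [(a.copy_id, a.interval) for a in t1] == [(b.copy_id, b.interval) for b in t2]

    def test_truth_intervals_slice_back_to_copy_sequences(self, rng):
        model = TEFamilyModel(
            "d", "nonLTR", terminus_len=90, internal_len=200, tsd_len=7,
            history=[Burst(0.03, 15)], trunc_prob=0.4,
        )
        copies, _ = simulate_family(model, rng)
        genome, truth = plant_genome(80_000, 0.45, [(model, copies)], rng)
        by_id = {c.copy_id: c for c in copies}
        for t in truth:
            s = genome.seq[t.interval.start : t.interval.end]
            if t.interval.strand == "-":
                s = revcomp(s)
            assert s == by_id[t.copy_id].seq
            # both flanks carry the duplicated target
            k = model.tsd_len
            assert genome.seq[t.interval.start - k : t.interval.start] == t.tsd_seq
            assert genome.seq[t.interval.end : t.interval.end + k] == t.tsd_seq


class TestSimulateReads:
    def _fam(self, means, dispersion=10.0):
        model = TEFamilyModel(
            "f", "DNA", terminus_len=100, internal_len=300,
            history=[Burst(0.0, 5)], stage_means=means, dispersion=dispersion,
        )
        return model

    def test_zero_means_give_zero_reads(self, rng):
        model = self._fam((0.0, 0.0, 0.0))
        copies, _ = simulate_family(model, rng)
        reads, counts = simulate_reads([(model, copies)], rng, read_len=50)
        assert counts["count"].sum() == 0
        assert all(len(v) == 0 for v in reads.values())

    def test_poisson_limit_concentration(self, rng):
        model = self._fam((1000.0, 1000.0, 1000.0), dispersion=math.inf)
        copies, _ = simulate_family(model, rng)
        _, counts = simulate_reads([(model, copies)], rng, read_len=50)
        assert (abs(counts["count"] - 1000) <= 3 * math.sqrt(1000)).all()

    def test_fixed_seed_byte_identical_files(self, tmp_path):
        def build(seed, name):
            rng = np.random.default_rng(seed)
            model = self._fam((50.0, 20.0, 10.0))
            copies, _ = simulate_family(model, rng)
            reads, _ = simulate_reads([(model, copies)], rng, read_len=50)
            p = tmp_path / name
            write_fasta(reads[("adherent", 1)], p)
            return p.read_bytes()

        assert build(7, "a.fa") == build(7, "b.fa")

    def test_read_longer_than_shortest_copy_rejected(self, rng):
        model = self._fam((10.0, 10.0, 10.0))
        copies, _ = simulate_family(model, rng)
        with pytest.raises(ValueError, match="read_len"):
            simulate_reads([(model, copies)], rng, read_len=10_000)


def test_mutate_changes_expected_fraction(rng):
    s = "A" * 10_000
    out = mutate(s, 0.1, rng)
    frac = sum(a != b for a, b in zip(s, out)) / len(s)
    assert frac == pytest.approx(0.1, abs=0.02)
    assert set(out) <= set("ACGT")
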