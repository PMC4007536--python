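"""End-to-end orchestration: simulate -> discover -> assemble -> popgen ->
age -> express, with a per-family summary table shaped like a TE family
characterization table (copy numbers with FLE/solo split, read totals,
identical copies, intra-LTR identity range, diversity partitions, Tajima's
D with significance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import age as age_mod
from . import assemble, discover, express, popgen, simulate
from .io import (
    Alignment,
    SequenceRecord,
    log,
    write_fasta,
    write_tsv,
)

DEFAULTS = dict(
    background_len=200_000,
    background_gc=0.5,
    read_len=70,
    error_rate=0.01,
    replicates=3,
    seed_len=12,
    min_identity=0.80,
    min_cov=0.50,
    flank_len=20,
    max_span=15_000,
    tsd_mismatch=0,
    gap_policy="complete_deletion",
    age_threshold=0.05,
    alpha=0.05,
    mapper_k=10,
    mapper_min_identity=0.80,
)


def demo_config(seed: int = 42) -> dict:
    """The packaged three-family demonstration configuration.

    One LTR family with a single recent transposition burst and solo-LTR
    formation, one non-LTR family with two diverged subfamilies and 5'
    truncation, and one DNA family under a constant insertion rate with a
    TA target preference.
    """
    cfg = dict(DEFAULTS)
    cfg.update(
        seed=seed,
        families=[
            dict(
                name="LtrA",
                te_class="LTR",
                terminus_len=150,
                internal_len=800,
                tsd_len=5,
                target_pref="GC_ends",
                history=[dict(age=0.015, count=24)],
                solo_rate=24.0,
                stage_means=[600, 150, 60],
                dispersion=12.0,
            ),
            dict(
                name="LineB",
                te_class="nonLTR",
                terminus_len=150,
                internal_len=900,
                tsd_len=9,
                target_pref="none",
                history=[dict(age=0.005, count=20)],
                subfamily_split_age=0.1,
                trunc_prob=0.3,
                stage_means=[200, 420, 100],
                dispersion=12.0,
            ),
            dict(
                name="DnaC",
                te_class="DNA",
                terminus_len=150,
                internal_len=700,
                tsd_len=2,
                target_pref="TA",
                history=dict(rate=400.0, horizon=0.05),
                stage_means=[80, 80, 450],
                dispersion=12.0,
            ),
        ],
    )
    return cfg


def model_from_dict(d: dict) -> simulate.TEFamilyModel:
    d = dict(d)
    hist = d.get("history")
    if isinstance(hist, dict):
        d["history"] = simulate.ConstantHistory(float(hist["rate"]), float(hist["horizon"]))
    elif isinstance(hist, list):
        d["history"] = [
            b if isinstance(b, simulate.Burst) else simulate.Burst(float(b["age"]), int(b["count"]))
            for b in hist
        ]
    if "stage_means" in d:
        d["stage_means"] = tuple(float(x) for x in d["stage_means"])
    return simulate.TEFamilyModel(**d)


ANALYZED_TERMINUS = {"LTR": "ltr", "nonLTR": "three_prime", "DNA": "five_prime"}


def terminus_queries(
    model: simulate.TEFamilyModel, cons: simulate.FamilyConsensus
) -> list[discover.TerminusQuery]:
    if model.te_class == "LTR":
        return [discover.TerminusQuery(model.name, "ltr", cons.terminus5)]
    return [
        discover.TerminusQuery(model.name, "five_prime", cons.terminus5),
        discover.TerminusQuery(model.name, "three_prime", cons.terminus3),
    ]


@dataclass
class FamilyResult:
    model: simulate.TEFamilyModel
    copies: list[assemble.ElementCopy] = field(default_factory=list)
    tsd_inferred_len: int | None = None
    tsd_profile: assemble.TSDProfile | None = None
    popgen: dict[str, popgen.PopGenSummary | None] = field(default_factory=dict)
    tree: object | None = None
    age_report: age_mod.AgeReport | None = None
    ltr_identity_range: tuple[float, float] | None = None
    read_count: int = 0


@dataclass
class RunResult:
    genome: SequenceRecord
    truth: list[simulate.TruthRecord]
    hits: list[discover.TerminusHit]
    families: dict[str, FamilyResult]
    truth_read_counts: pd.DataFrame | None = None
    expression_counts: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None
    log_normalized: pd.DataFrame | None = None
    stage_tests: list[express.StageTestResult] = field(default_factory=list)
    activity_r: float | None = None
    summary: pd.DataFrame | None = None


def analyzed_terminus_sequences(
    genome: SequenceRecord,
    fam: FamilyResult,
    skip_edge: bool = True,
) -> tuple[list[str], dict[str, list[str]]]:
    """One analyzed-terminus sequence per reconstructed copy.

    LTR families contribute one LTR per insert (the 5' LTR of an FLE, the
    surviving LTR of a solo); non-LTR families the 3' UTR; DNA families the
    5' ITR.  Edge-clipped hits are skipped so the stack is a gap-free
    alignment.  Returns (all sequences, partition map for LTR families).
    """
    te_class = fam.model.te_class
    seqs: list[str] = []
    parts: dict[str, list[str]] = {"FLE": [], "solo": []}
    for c in fam.copies:
        if te_class == "LTR":
            hit = c.five_hit
            if c.structure not in ("FLE", "soloLTR") or hit is None:
                continue
        elif te_class == "nonLTR":
            hit = c.three_hit
        else:
            hit = c.five_hit
        if hit is None or (skip_edge and hit.edge_flag):
            continue
        s = discover.hit_sequence(genome, hit)
        seqs.append(s)
        if te_class == "LTR":
            parts["FLE" if c.structure == "FLE" else "solo"].append(s)
    return seqs, parts


def run_all(config: dict, out_dir: str | Path | None = None) -> RunResult:
    """Execute every stage on a simulated genome and write the module TSVs."""
    cfg = dict(DEFAULTS)
    cfg.update(config)
    seed = int(cfg.get("seed", 0))
    log.info("run_all seed=%d families=%d", seed, len(cfg["families"]))
    rng = np.random.default_rng(seed)

    models = [model_from_dict(d) for d in cfg["families"]]
    sim_copies: list[tuple[simulate.TEFamilyModel, list[simulate.SimCopy]]] = []
    consensi: dict[str, simulate.FamilyConsensus] = {}
    queries: list[discover.TerminusQuery] = []
    for model in models:
        copies, cons = simulate.simulate_family(model, rng)
        sim_copies.append((model, copies))
        consensi[model.name] = cons
        queries.extend(terminus_queries(model, cons))

    genome, truth = simulate.plant_genome(
        int(cfg["background_len"]), float(cfg["background_gc"]), sim_copies, rng
    )
    reads, truth_counts = simulate.simulate_reads(
        sim_copies,
        rng,
        read_len=int(cfg["read_len"]),
        error_rate=float(cfg["error_rate"]),
        replicates=int(cfg["replicates"]),
    )

    hits = discover.scan_genome(
        [genome],
        queries,
        seed_len=int(cfg["seed_len"]),
        min_identity=float(cfg["min_identity"]),
        min_cov=float(cfg["min_cov"]),
        flank_len=int(cfg["flank_len"]),
    )

    result = RunResult(genome, truth, hits, {}, truth_read_counts=truth_counts)
    all_summaries: list[popgen.PopGenSummary] = []
    age_reports: list[age_mod.AgeReport] = []
    trees: dict[str, object] = {}
    for model in models:
        fam = FamilyResult(model)
        fam_hits = [h for h in hits if h.family == model.name]
        copies = assemble.pair_inserts(
            fam_hits,
            model.te_class,
            model.tsd_len,
            max_span=int(cfg["max_span"]),
            tsd_mismatch=int(cfg["tsd_mismatch"]),
        )
        fam.copies = copies
        # TSD length inference from paired flank evidence
        cand = [
            (c.five_hit.up_flank, c.three_hit.down_flank)
            for c in copies
            if c.five_hit is not None and c.three_hit is not None
        ]
        cand += [
            (c.five_hit.up_flank, c.five_hit.down_flank)
            for c in copies
            if c.structure == "soloLTR"
        ]
        fam.tsd_inferred_len, _ = assemble.infer_tsd_len(cand)
        tsds = [c.tsd_seq for c in copies if c.tsd_seq]
        if tsds and len({len(t) for t in tsds}) == 1:
            fam.tsd_profile = assemble.tsd_composition(tsds, model.name)
        # intra-LTR identity per FLE
        idents = []
        for c in copies:
            if c.structure == "FLE":
                ltr5 = discover.hit_sequence(genome, c.five_hit)
                ltr3 = discover.hit_sequence(genome, c.three_hit)
                c.intra_ltr_identity, _ = assemble.intra_ltr_identity(ltr5, ltr3)
                idents.append(c.intra_ltr_identity)
        if idents:
            fam.ltr_identity_range = (min(idents), max(idents))
        # diversity statistics on the analyzed terminus
        seqs, parts = analyzed_terminus_sequences(genome, fam)
        if model.te_class == "LTR":
            fam.popgen = popgen.partitioned_diversity(
                parts, policy=cfg["gap_policy"], family=model.name
            )
        elif len(seqs) >= 2:
            aln = Alignment([f"{model.name}_{i}" for i in range(len(seqs))], seqs)
            try:
                summ = popgen.tajimas_d(aln, cfg["gap_policy"], family=model.name)
                summ.identical_copies = popgen.identical_copy_count(seqs)
                fam.popgen = {"all": summ}
            except popgen.InsufficientSitesError:
                fam.popgen = {"all": None}
        for label in ("all", "FLE", "solo"):
            s = fam.popgen.get(label)
            if s is not None:
                all_summaries.append(s)
        # copy tree and age profile
        if len(seqs) >= 3:
            ids = [f"{model.name}_{i}" for i in range(len(seqs))]
            dm = age_mod.distance_matrix(Alignment(ids, seqs))
            fam.tree = age_mod.neighbor_joining(dm)
            trees[model.name] = fam.tree
            fam.age_report = age_mod.age_profile(
                fam.tree, float(cfg["age_threshold"]), model.name
            )
            age_reports.append(fam.age_report)
        result.families[model.name] = fam

    # expression: map every replicate against the family consensus sequences
    consensus_records = [
        SequenceRecord(m.name, consensi[m.name].full) for m in models
    ]
    count_rows = []
    for (stage, rep), rec_list in reads.items():
        mapped = express.map_reads(
            rec_list,
            consensus_records,
            k=int(cfg["mapper_k"]),
            min_identity=float(cfg["mapper_min_identity"]),
        )
        for famname, cnt in mapped.items():
            count_rows.append(dict(family=famname, stage=stage, replicate=rep, count=cnt))
    counts = pd.DataFrame(count_rows)
    result.expression_counts = counts
    cell = express.counts_to_matrix(counts)
    result.normalized, result.log_normalized = express.normalize_matrix(cell)
    result.stage_tests = express.stage_tests(counts, alpha=float(cfg["alpha"]))
    for fam in result.families.values():
        fam.read_count = int(counts.loc[counts["family"] == fam.model.name, "count"].sum())
    ident_by_fam = {
        name: float(fam.popgen["all"].identical_copies)
        for name, fam in result.families.items()
        if fam.popgen.get("all") is not None
    }
    reads_by_fam = {name: float(fam.read_count) for name, fam in result.families.items()}
    try:
        result.activity_r, _ = express.activity_correlation(reads_by_fam, ident_by_fam)
    except ValueError:
        result.activity_r = None

    result.summary = _summary_table(result)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        write_fasta([genome], out / "genome.fa")
        write_tsv(simulate.truth_table(truth), out / "truth.tsv")
        write_tsv(truth_counts, out / "truth_counts.tsv")
        for (stage, rep), rec_list in reads.items():
            if rec_list:
                write_fasta(rec_list, out / f"{stage}_{rep}.fa")
        write_tsv(discover.hits_table(hits), out / "hits.tsv")
        write_tsv(
            pd.concat(
                [assemble.copies_table(f.copies) for f in result.families.values() if f.copies],
                ignore_index=True,
            ),
            out / "copies.tsv",
        )
        write_tsv(popgen.summary_table(all_summaries), out / "stats.tsv")
        profs = [
            f.tsd_profile.per_position_freq.assign(
                family=f.model.name, GC=f.tsd_profile.gc_by_position
            )
            for f in result.families.values()
            if f.tsd_profile is not None
        ]
        if profs:
            write_tsv(pd.concat(profs, ignore_index=True), out / "tsd_profile.tsv")
        if age_reports:
            write_tsv(age_mod.ages_table(age_reports), out / "ages.tsv")
            write_tsv(age_mod.box_summary_table(age_reports), out / "age_box_summary.tsv")
        tree_dir = out / "trees"
        tree_dir.mkdir(exist_ok=True)
        for name, tree in trees.items():
            tree.write(str(tree_dir / f"{name}.nwk"))
        write_tsv(counts, out / "expression.tsv")
        write_tsv(result.normalized.reset_index(), out / "expression_normalized.tsv")
        write_tsv(result.log_normalized.reset_index(), out / "expression_log_normalized.tsv")
        write_tsv(express.tests_table(result.stage_tests), out / "stage_tests.tsv")
        express.plot_heatmaps(
            result.normalized, result.log_normalized, str(out / "heatmap.png")
        )
        write_tsv(result.summary, out / "summary.tsv")
    return result


def _summary_table(result: RunResult) -> pd.DataFrame:
    rows = []
    for name, fam in result.families.items():
        te_class = fam.model.te_class
        structures = [c.structure for c in fam.copies]
        if te_class == "LTR":
            n_fle = structures.count("FLE")
            n_solo = structures.count("soloLTR")
            copy_number = f"{n_fle + n_solo} ({n_fle}/{n_solo})"
        else:
            n_classified = sum(s in ("full", "truncated") for s in structures)
            copy_number = str(n_classified)
        allrow = fam.popgen.get("all")
        fle = fam.popgen.get("FLE")
        solo = fam.popgen.get("solo")
        rng_txt = ""
        if fam.ltr_identity_range:
            lo, hi = fam.ltr_identity_range
            rng_txt = f"{lo:.1f}-{hi:.1f}" if lo != hi else f"{hi:.1f}"
        rows.append(
            dict(
                family=name,
                te_class=te_class,
                copy_number=copy_number,
                rnaseq_reads=fam.read_count,
                identical_copies=0 if allrow is None else allrow.identical_copies,
                ltr_identity_range=rng_txt,
                pi="" if allrow is None else round(allrow.pi, 4),
                pi_fle="" if fle is None else round(fle.pi, 4),
                pi_solo="" if solo is None else round(solo.pi, 4),
                tajima_d="" if allrow is None or allrow.D is None else round(allrow.D, 3),
                sig="n/a" if allrow is None or allrow.D is None else allrow.sig_code,
                tsd_len="" if fam.tsd_inferred_len is None else fam.tsd_inferred_len,
            )
        )
    return pd.DataFrame(rows)
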