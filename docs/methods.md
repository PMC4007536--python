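# Methods

## Scope and model overview

`telifecycle` treats the copies of one transposable-element family inside a
single sequenced genome as a population sample and asks where the family
sits in its life cycle: actively expanding, subdivided into old lineages,
or decaying. The evidence is (a) structural — individual inserts
reconstructed from terminus matches paired by target-site duplications
(TSDs); (b) molecular-evolutionary — nucleotide diversity, Tajima's D,
intra-element LTR divergence, identical-copy counts and terminal branch
lengths on copy trees; and (c) transcriptional — stage-structured read
counts per family. A synthetic-genome generator supplies ground truth for
every stage.

## The synthetic-data generator

### Copy model

Each family has an ancestral consensus drawn uniformly at random at a
configurable GC content (default 0.5): an LTR family is LTR + internal +
LTR (both termini the same sequence), non-LTR and DNA families are 5′
terminus + internal + 3′ terminus with independent termini. A copy of age
`t` is the founder sequence with independent per-site substitutions applied
at probability `p(t) = 1 − exp(−μt)`, each substitution uniform over the
three alternative bases (Jukes–Cantor). Ages are in arbitrary units; only
the product μt matters, and μ defaults to 1 so ages read directly as
expected substitutions per site.

Copies are i.i.d. descendants of the (sub)family founder rather than a full
birth–death genealogy. This is deliberate: a single recent burst then
yields a star genealogy whose variants are almost all singletons (negative
D), while a two-subfamily history (two founders independently mutated from
the ancestor for `subfamily_split_age` time units, copies assigned to a
founder uniformly) yields shared founder variants at intermediate frequency
(positive D). These are exactly the two regimes the downstream
interpretation of D distinguishes, and the i.i.d. construction gives them
closed-form expectations (intra-LTR divergence ≈ 2μt; terminal branch
length ≈ μt for burst copies).

Insertion histories are either a list of bursts (age, count) or a constant
rate over a horizon (count Poisson, ages uniform); an optional loss rate
thins copies with survival `exp(−loss_rate · t)`.

Structural processes:

* **LTR families**: both LTRs are identical at insertion and then mutate
  independently, so an age-`t` FLE has expected intra-LTR difference
  `2p(1−p) + (2/3)p²` ≈ 2μt. With probability `1 − exp(−ρt)` a copy is
  emitted as a solo LTR; the 5′ LTR is retained by convention (the
  recombination product is a single LTR either way; fixing the 5′ one makes
  truth tables deterministic).
* **non-LTR families**: with probability `q` a copy is 5′-truncated at a
  breakpoint uniform over positions that spare the 3′ terminus, mirroring
  the dead-on-arrival products of incomplete reverse transcription. The 3′
  UTR is the analyzed terminus precisely because it survives truncation.
* No indel process: copies are gap-free so terminus stacks are alignments
  by construction. Gap and N handling in the statistics is exercised
  separately on crafted gapped alignments, not via simulation.

### Genome planting

Target sites are sampled in a random background: uniformly (`none`), only
at TA dinucleotides (`TA`, TSD length 2), or with a threefold weight for
G/C at the first and fifth positions of the target k-mer (`GC_ends`, the
chromovirus-like preference; with background GC 0.5 the accepted sites have
expected terminal GC fraction 0.75 against 0.5 internally). The
`tsd_len` target bases are duplicated so the insert is flanked by identical
TSDs; placements are non-overlapping with a minimum background gap (60 bp)
so flank windows never cross neighboring inserts; strand is random.
Truth records carry the final genome coordinates of the insert and of each
terminus, the TSD, the age, the structure, and the subfamily.

### Reads

Per family × stage × replicate the read count is negative binomial with the
family's stage mean and dispersion (`dispersion = inf` degenerates to
Poisson); reads are drawn uniformly along uniformly chosen copies on random
strands with substitution errors at `error_rate`. Stages are labels with
expression means only — no stage biology is modeled.

### What passing tests do and do not show

The generator has no indels, no nested or fragmented inserts, no selection,
no insertion-site epistasis, and TSDs that never mutate after planting
(they are recorded at insertion state). Recovery results on it therefore
demonstrate the correctness of the pipeline's logic — pairing, TSD
inference, statistics, dating — under clean insertions, not its robustness
to assembly artifacts, nested repeats or degraded TSDs in real genomes.
The `--tsd-mismatch` option exists for the latter case but defaults to 0.

## Terminus discovery

Queries (one LTR per LTR family; 5′ and 3′ noncoding termini otherwise)
are capped at 300 bp. An exact `seed_len`-mer (default 12) shared between
query and genome fixes an ungapped diagonal; the full query-length window
on that diagonal is evaluated directly and reported when identity ≥
`min_identity` (default 0.80) over ≥ `min_cov` (default 0.50) of the query
length — the coverage term only bites for windows clipped at contig edges.
Direct window evaluation (rather than score-drop extension) makes the
reported interval coincide with the best-identity sliding window, which is
what the planted-truth comparisons measure, and keeps all extracted
terminus sequences the same length so they stack into gap-free alignments.
Both strands are searched; minus-strand hits are reported in forward
coordinates with flanks re-oriented to the element strand. Overlapping hits
of one query keep the higher identity, ties the leftmost. Gapped termini
are a known limitation of the ungapped search and are simply missed.

Defaults were chosen for desk-scale sensitivity down to ~15% copy
divergence (a 12-mer exact seed is very likely within a 150–300 bp terminus
at that divergence) and are config-exposed.

## Insert assembly

Pairing is greedy left-to-right per contig: an unused hit pairs with its
nearest downstream unused hit of compatible end type on the same strand
within `max_span` (default 15 kb, generous for multi-kb elements) iff the
`tsd_len` bases ending the 5′ hit's upstream flank equal those starting the
3′ hit's downstream flank (element orientation; on the minus strand the
genomic-left hit is the element's 3′ end). A lone LTR hit whose own
upstream-flank tail equals its downstream-flank head is a solo LTR. A lone
3′ terminus of a non-LTR family is called truncated; other leftovers are
unpaired. With `tsd_len = 0` pairing falls back to proximity and is flagged
low-confidence. TSD uniqueness is not re-checked globally; colliding
contexts simply fail the TSD test and surface as unpaired hits.

TSD length is inferred per family as the modal longest duplicated k in
2–12 bp (covering the observed 2/3/5/9 bp family classes) over ≥ 3
candidate inserts, ties toward the shorter length; inserts with no
duplication ≥ 2 bp are reported TSD-absent rather than guessed.
Intra-element LTR identity is the percent of matching positions over the
two extracted LTRs (prefix comparison with a flag if lengths differ),
reported to one decimal.

## Diversity statistics

Complete deletion is the default gap policy: every column containing a gap
or N in any row is removed before anything is computed, so π and S always
share a site set, and an alignment whose every column is gapped somewhere
raises an insufficient-sites signal that the reports render as "n/a"
(the behaviour a heavily indel-riddled family produces). Pairwise deletion
is available for π only. N is treated as a gap (conservative exclusion).

k is the mean pairwise difference count over all n(n−1)/2 pairs; π = k/L;
S counts polymorphic usable columns. Tajima's D uses the standard a₁…e₂
constants and is undefined (reported empty, never 0) when n < 4 or S = 0.
Significance uses the beta approximation — D rescaled to its attainable
range (Dmin, Dmax) is treated as a beta variate with mean 0 and variance 1
on the D scale — mapped to ns/*/**/*** at 0.05/0.01/0.001; a seeded
coalescent-simulation p-value (genealogy branch lengths, S mutations
multinomial on branches, D recomputed from the implied frequency spectrum)
is available as an alternative.

Identical paralogous copies are counted as the number of sequences
belonging to any exact-identity group of size ≥ 2, after uppercase and
strand normalization (a sequence and its reverse complement are the same
copy), computed on the analyzed terminus region. For LTR families π is
additionally partitioned into FLE (5′ LTR) and solo (surviving LTR) sets,
one LTR per insert, with D computed on the pooled set only; a partition
with fewer than 2 members is reported empty.

## Copy ages

JC69 distances, `d = −(3/4)ln(1 − 4p/3)` over sites where neither sequence
has a gap/N, feed classic Saitou–Nei neighbor joining. p ≥ 0.75 saturates
the correction; such pairs are capped at 3.0 substitutions/site and logged
(the cap keeps the Q-matrix finite and only affects pairs already beyond
dating). Q ties break toward the smallest index pair in the working order;
negative branch estimates are clamped to zero with the deficit moved to the
sibling so path lengths are preserved; the last three nodes are resolved at
a trifurcating root by the three-point formula. Distance-based NJ is used
deliberately instead of likelihood tree inference: the downstream quantity
is terminal branch length against a coarse 0.05 substitutions/site
threshold, for which an additive distance tree is an adequate,
dependency-free proxy — absolute branch lengths will differ from
likelihood estimates, and only the old/young classification and the
distributional shape are treated as comparable. Age summaries report the
per-family five-number box (median, quartiles, 1.5×IQR whiskers, outliers)
and the old-copy fraction.

## Expression

Reads are assigned by the same seeded ungapped evaluation against each
family's full consensus on both strands; the best identity ≥ 0.80 wins,
and reads tying across families are dropped and logged (counting a
multi-family read once per family would inflate correlated families). The
mapper seed is 10 bp — shorter than the genome-scan seed because a 70 bp
read at ~10% divergence plus sequencing error needs a denser seed to
guarantee an exact match.

Heatmap cells are replicate sums per family × stage (sums, not means, so
cells add up to per-family totals); the linear matrix is normalized by the
single global maximum cell, the log matrix is min-max scaled in log10(x+1)
(zeros exist, hence +1). No library-size normalization is applied by
default, matching the global-max convention; a per-replicate option exists.
Per family, a one-way ANOVA (df 2, 6) across the three stages is followed,
when significant at α = 0.05, by an unpaired pooled-variance t-test (df 4;
Welch optional) between the two stages with the highest summed expression;
an elevated stage is declared only when both tests pass, which holds the
null false-elevation rate well under 0.05 (measured ≈ 0.01–0.02 on
negative-binomial nulls). No multiple-testing correction is applied by
default; Benjamini–Hochberg-style control can be layered on the reported
p-values. The expression/activity association is the Pearson correlation
between untransformed per-family read totals and identical-copy counts.

## Numerical and reporting conventions

Internal coordinates are 0-based half-open; every human-facing table is
1-based inclusive. Floats in TSVs are printed at 6 significant digits;
intra-LTR identity at one decimal. All randomness flows through a single
`numpy` Generator seeded from the run seed, and outputs are byte-identical
under a fixed seed and config. Logging goes to stderr with the effective
configuration (seed included) echoed at the start of a run and written
beside the outputs.

## Problem sizes used in validation

The packaged demonstration uses a 200 kb background with three families
(~60 inserts, ~6,000 reads over 9 stage/replicate sets); the oracle battery
uses 1,000 random alignments (n ≤ 8, L ≤ 30) and 40 random additive
matrices (≤ 10 leaves); regime checks use 20–60 copies per dataset and 25
replicate datasets per regime; the null expression calibration uses 1,000
families. These sizes give the sign and coverage assertions comfortable
margins (binomial CIs are quoted where relevant) while keeping a full
validation run in the tens of seconds.

## Known limitations

* Nested, fragmented and edge-overlapping inserts are out of scope; the
  pairing rule assumes inserts are contiguous and non-interleaved.
* Ungapped search misses termini with indels relative to the consensus.
* NJ/JC69 branch lengths are proxies, not substitution-model estimates.
* The identical-copy count is computed on the analyzed terminus, not the
  full-length copy; very recent copies differing only outside the terminus
  are counted as identical.
* The generator's stage labels carry no biology beyond their expression
  means; stage-test calibration says nothing about confounders in real
  transcriptome designs (library size, batch).
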