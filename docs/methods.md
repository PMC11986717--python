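# Methods

This note records the statistical model behind `exonsplice`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical and design decisions a maintainer should
know about. Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Data model and preprocessing

The chip is purely hierarchical — probe → probe set (exon) → transcript
cluster (gene) — with no genomic coordinates anywhere; identifiers are
opaque strings. Intensity matrices advance through four stages
(`raw → normalized → transformed → background_corrected`) and the stage is
part of the type, so operations cannot be applied out of order. Missing
values are not supported: the medians used throughout are only exact on
complete data, and the upstream arrays have none.

**Quantile normalization.** Every array's value at rank *r* is replaced by
the across-array mean of the *r*-th order statistics ("complete" quantile
normalization, with the mean of all arrays as the reference rather than a
percentile array). Ties within an array receive the mean of the reference
values over their tied rank span — deterministic and independent of input
order. Consequences worth knowing: for tie-free data all arrays end with
an identical value multiset and the map is idempotent (both are asserted in
tests); with ties the averaged values replace the shared multiset, which is
the price of a deterministic tie rule. Quantile normalization also largely
absorbs global array (hybridization) effects, and — a known property — with
an *asymmetric* spike-in it transfers a small intensity-dependent shift
onto the unspiked genes of the heavier group (see "Limitations").

**GC filter and log transform.** Probes with GC count outside 6..17 are
excluded (`gc.min`/`gc.max`). Scores are mapped to `log2(value + 0.1)`;
the additive offset (`log.offset`, default 0.1) stabilizes the transform
near zero and base 2 (`log.base`) makes downstream fold changes powers of
two. The source description of this step is garbled ("multiplying by the
logarithm of 0.1" would only rescale and sign-flip every score), so the
offset reading is adopted and both constants are configuration keys.

**Background model.** Antigenomic probes are binned by GC count, pooled
across arrays; per bin the median ("GC background"), mean, and variance are
kept, along with the average per-bin variance (`Var`), the total variance
of bin-median-centred background values (feeding `Pvar`), and per-group bin
means. Each annotated probe then has its bin's median subtracted; negative
corrected scores are permitted. Subtraction is shift-equivariant per bin
(tested).

## Presence statistics

**Probe-set level.** For probe set with k passing probes, group mean score
T, GC-matched corrected background mean P and background variance term
`Pvar`, the statistic is `T0 = √GroupSize · (T − P)/√Pvar`; the set is
expressed when the upper normal tail at T0 is ≤ 0.001. Two readings of
`Pvar` are implemented (`presence.pvar`): the default `literal` divides the
total background variance by k², exactly as the source sentence reads; the
`mean_variance` alternative divides by k (the variance of a k-probe mean).
The literal form makes T0 anti-conservative for k > 1 — calibration of the
0.001 level holds exactly only at k = 1 (verified by a null property
test); since the call feeds a *filter*, not an inference, the literal
default is kept for fidelity. P is computed on the background-corrected
scale (bin mean − bin median, weighted by the set's probe GC composition),
the only scale consistent with scores whose bin median is already removed.

**Gene level.** `N0 = Σ(corrected probe scores over the group's arrays) /
√(K·Var)` with K the number of summed values; expressed when the upper
tail is < 0.01. The standardized denominator makes N0 exactly standard
normal under the null (verified); the unscaled `Sum/Var` variant, which is
not scale-free, remains available as `presence.n0 = literal` because the
source prints it that way. Percentages in the co-expression report use
half-up rounding to one decimal; totals, pairwise shared counts and
exclusives satisfy inclusion–exclusion exactly by construction.

## The filter cascade

Steps, each recorded in the ledger with probe / probe-set / cluster counts
(counts never increase; asserted): (0) chip totals; (1) Core probe sets
only; (2) GC-passing probes, probe sets keeping ≥ 3 passing probes;
(3) probe sets expressed above background in at least one analysis group
(`presence.require`, default `any`: a set silent in every group carries no
signal, while requiring `all` would delete genuinely group-exclusive
expression); (4) a named no-op (no absolute-score filter), kept so ledgers
align with the chip-level report; (5) the invariance filter, then the
analysis gene list = clusters with 4–200 passing probe sets. Probe sets
are always removed for *all* arrays, never per array, so every cluster
stays balanced — this is what makes the closed-form ANOVA below exact.

**Invariance filter.** A probe set is dropped when
`(N−1)·s²_set / s̄²_gene` falls below the lower 10% chi-square quantile
with N−1 df. The reference scale `s̄²_gene` is the cluster's **median**
probe-set variance by default (`invariance.reference`), with the mean
available as an option. The mean was rejected after analysis: one
genuinely spliced exon (e.g. +2 log2 in a 3v3 design contributes ≈ 1.2 to
its across-array variance, against ≈ 0.02 for its siblings) inflates the
cluster mean so far that *every* sibling exon falls below the cut — for
genes with ≤ 30 exons the whole cluster then dies at the 4-set rule, i.e.
the mean-referenced filter deletes exactly the genes the pipeline exists
to find. The median reference preserves the filter's purpose (dropping
sets that vary implausibly little relative to their gene) while being
robust to a single loud exon.

## Nested mixed-model ANOVA

Per cluster: `y_gae = μ + αg + b_a(g) + τe + (ατ)ge + ε`, groups and exons
fixed, arrays random nested in group. Expression data arrive in batches by
hybridization, so the array is the natural random unit. Because every
array scores every passing probe set exactly once, the design is balanced
in the exon direction and expected-mean-squares F tests are exact, fast
and deterministic — no iterative (REML) fitting is needed:

* `F_group = MS_group / MS_array(group)` (df G−1, Σ(n_g−1)) — differential
  expression, tested against array-to-array variation;
* `F_exon = MS_exon / MS_resid`;
* `F_interaction = MS_group×exon / MS_resid` (df (G−1)(E−1), Σ(n_g−1)(E−1))
  — alternative splicing.

Unequal group sizes are supported (exons are crossed with every array, so
the sums of squares stay orthogonal). Degenerate inputs: an all-constant
cluster is guarded to F = 0, p = 1 (numerically, any sum of squares below
`size · (max|y|+1)² · 1e−26` is treated as zero); a zero residual df is
flagged. The statistics agree with an explicit-loop oracle to < 1e−10
relative error on 100 random clusters and with a statsmodels
sequential-sums-of-squares fit to 1e−8.

**Multiple testing.** BH step-up per test family (group and interaction
separately): `adj_i = min_{j≥rank(i)} p_(j)·N/j`, capped at 1. DE list:
adjusted group p < `alpha.anova` (0.01); AS list: adjusted interaction
p < `alpha.anova`, minus genes expressed above background in fewer than two
groups (`near_background` flag) — near the background (or saturation) an
exon's response is dampened, producing spurious non-parallelism. That
weakest sufficient rule is the default; a dynamic-range refinement hook
exists but is off.

**Fold changes.** Per-array gene score = mean of probe-set scores,
back-transformed (`2^score − offset`, floored at 1e−9); fold change
r = mean(treated)/mean(reference) reported as +r if r ≥ 1 else −1/r, the
first sample-sheet group being the reference (`fc.reference`). The
accompanying test is the classical pooled-variance two-sided Student t
(`alpha.fc_ttest`, 0.05); it is reported alongside, not combined with, the
ANOVA group test, since the two thresholds differ upstream.

## Overrepresentation

Terms are flat gene sets intersected with the tested universe (no GO DAG
propagation). With G tested genes, A significant, a term of n tested
members containing a significant ones: the exact p is the hypergeometric
tail P(X ≥ a); the normal approximation is the upper tail at
`x = (a − n·p)/√(n·p(1−p))`, p = A/G computed separately for the DE and AS
lists. Both are reported per term; the significance flag (either list's
exact p < 0.01) and ordering use the exact tail. No correction across
terms by default (an optional per-class BH column exists). A numerical
fact the tests pin down: the printed x carries no continuity correction,
so its error against the exact tail is ≈ pmf(a)/2 near the centre of the
distribution — up to ~0.09 when `n·p(1−p)` is small — while the
continuity-corrected variant (`continuity=True`) tracks the exact tail to
within 0.02 whenever n·p ≥ 5, n·(1−p) ≥ 5 and the term is a small fraction
of the universe. The literal form is the published statistic and stays the
default.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes, on the
log2 scale (so effects are multiplicative on the raw scale):

    probe value = baseline(probe set) + β_gc·(gc − 12) + array effect
                  + δ_DE·[spiked, treated group]
                  + δ_AS·[spiked, treated group, affected exon] + noise

Background probes share the GC affinity, array effects and noise but no
gene structure. Defaults model the two-arm liver study the pipeline
targets: 2 groups × 3 arrays, genes of 4–12 exons × 4 probes, probe GC
unimodal around 12 on 3..25 (binomial), 200 background probes per GC bin,
baselines N(7, 1) against a background level of 4 (comfortably detectable,
as liver-expressed genes are), β_gc = 0.05/GC unit, σ_array = 0.1,
σ_resid = 0.25, spike sizes in log2 units (δ_AS default 2.0 affecting
exactly one exon — the hardest detectable, most splice-like case). Spiked
genes occupy the first `round(f·n)` indices (exact counts, exchangeable by
construction); each gene draws from its own counter-keyed stream, so
enlarging a simulation never perturbs earlier genes.

What it does *not* emulate: probe-sequence cross-hybridization,
saturation, optical artifacts, correlated probes within a set, heavy-tailed
noise, or annotation errors. Passing tests therefore demonstrate the
statistical machinery is correct under its stated model, not that real
chips meet that model.

Measured behaviour under these conditions (recomputed by the test suite
and `scripts/acceptance.py`): on a 2,000-gene null chip the raw interaction
test rejects at 0.0083–0.0098 for α = 0.01 with KS distance from
uniformity ≈ 0.01–0.04; with 50/1,000 single-exon spikes of 2 log2 units
(3v3), mean recall is 1.0 and mean empirical FDR at q = 0.05 is ≈ 0.05
over ten seeds; pure expression spikes are essentially never called as
splicing (specificity ≈ 1.0).

## Limitations

* Quantile normalization redistributes an asymmetric spike-in: with ~5% of
  genes shifted in one group, the compensating intensity-dependent shift on
  null genes inflates the splicing empirical FDR from ≈ 0.05 to ≈ 0.086 at
  q = 0.05 in combined spike simulations. This is a property of the
  normalization, not of the test; it matters whenever treatment effects are
  widespread and one-directional.
* The literal `Pvar` (division by k²) makes probe-set presence calls
  anti-conservative; they are used only as a filter.
* BH assumes independent (or PRDS) tests across genes; co-regulated genes
  violate this, as does any gene-set structure.
* The EMS ANOVA requires within-cluster balance; the cascade guarantees it,
  but externally constructed score matrices with missing arrays are
  rejected rather than fitted.
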