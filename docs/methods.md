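# Methods

## The paired ratio-of-ratios test

The design crosses a regulator perturbation (overexpression vs vector
control, knockdown vs siRNA control) with subjects. For gene *g* and
subject *s*, with pseudocount ε on the linear scale,

    OE_ratio(s,g) = (x_OE + ε) / (x_OE_ctl + ε)
    KD_ratio(s,g) = (x_KD + ε) / (x_KD_ctl + ε)
    d_s(g)        = log2 OE_ratio(s,g) − log2 KD_ratio(s,g)

The per-gene statistics are the paired t, T = mean(d)/(sd(d)/√n) with
sd computed at n−1 degrees of freedom, and log2FC = mean(d). The contrast
d is a ratio of ratios: a genuinely induced gene contributes +effect under
OE and −effect under KD, so its expectation is twice the single-condition
effect, while additive subject and batch terms cancel. With n = 3 subjects
the t has only 2 degrees of freedom, which is why significance is not
taken from the t distribution but from permutation.

### Empirical nulls and Pt/Pf

For each of B permutations (default 1000) the condition labels are
shuffled and T and log2FC recomputed for every gene. The permuted values
are pooled across permutations **and genes** into a single null per
statistic, giving N ≈ B·G null values. Rationale: a per-gene null from a
3-subject design has at most 24³ = 13 824 distinct relabelings and far
fewer distinct statistic values, so per-gene p-values would be coarse and
noisy; pooling borrows the null shape across genes, the same trade-off
SAM-style permutation tests make. The cost is that genes with atypical
null spread are mildly mis-calibrated relative to their own null; the
global-null calibration test bounds the aggregate effect.

Two-sided empirical p-values use absolute values and the plus-one
correction:

    p = (1 + #{ |v| ≥ |obs| }) / (1 + N)

so p ∈ [1/(N+1), 1] and monotone in |obs|. Pt is the p-value of T, Pf of
log2FC; genes with Pt ≤ 0.05 and Pf ≤ 0.10 (inclusive) are called DEGs,
labelled induced/suppressed by the sign of log2FC. No further
multiple-testing correction is layered on top: the dual threshold on
pooled-null p-values is the calling rule itself.

### Permutation scheme

Default (`within_subject`): the four role labels are permuted
independently within each subject, preserving the subject blocking that
the observed statistic exploits — the null then reflects "no condition
effect given this subject structure". An alternative `across_samples`
scheme that reassigns all 4·S samples to the S×4 slots is available behind
a flag; it additionally randomizes subject structure and gives a slightly
wider null.

`build_null` has three modes. `auto` (default) enumerates every distinct
relabeling exhaustively whenever their count (24^S paired, C(n, n_case)
unpaired) does not exceed B, making the null exact on small designs, and
Monte-Carlo samples otherwise; `exhaustive` forces enumeration;
`montecarlo` forces sampling and warns when B exceeds the distinct count
(duplicates are then permitted). Monte-Carlo permutation streams are drawn
up front from a single generator, so results are seed-stable regardless of
how the computation is chunked.

### Degenerate and low-expression genes

A gene whose contrast is exactly constant across subjects has sd(d) = 0.
If the constant is 0 the statistic is a clean null value, T = 0. If it is
nonzero, T is undefined: the gene is flagged degenerate, T is reported as
NaN, and Pt falls back to the log2FC null (Pt = Pf) with a warning, rather
than reporting ±∞. Non-finite permuted T values are likewise excluded from
the pooled null, with the drop count recorded on the `NullDistribution`.

Genes below ε in every design sample carry no information beyond the
pseudocount and are dropped before testing (count logged). ε defaults to
1.0 expression unit — on the FPKM scale this bounds ratios for
zero-expression genes without materially shifting moderately expressed
ones — and is configurable everywhere.

### The unpaired variant

Case/control datasets (the public senescence studies the workflow
integrates) get an equal-variance two-sample Student t on log2(x + ε),
log2FC = difference of group means, with group labels shuffled across all
samples for the null and the same pooled-null Pt/Pf machinery. Equal
variance (not Welch) matches the classical "Student's t-test" convention
for these small balanced groups.

## Quantile normalization

Columns are forced to the common distribution of rank-wise means: sort
each column, average across columns at each rank, map back by rank. Ties
within a column all receive the mean of the rank means over the tied span,
which preserves column sums and hence the grand mean. On tie-free
(continuous) data the transform is exactly idempotent and all sorted
columns are identical to machine precision. With column-specific ties
those two properties hold only approximately — the tied blocks of
different columns average different spans — which is inherent to the
standard tie convention (limma's `normalizeQuantiles` behaves the same
way); FPKM-like continuous input is effectively tie-free apart from zeros.
Normalization is applied to linear-scale values, before any log.

## Integration and target nomination

DEG sets are matched by canonicalized gene symbol (upper-cased, stripped).
`venn_counts` reports all exclusive intersection regions of 2–3 sets;
candidates are the genes in *every* set. The consistency rule maps the
regulator's own change in the condition to an expected direction per
candidate: regulator **down** in senescence ⇒ induced targets expected
**down**, suppressed targets expected **up** (regulator up ⇒ the targets
follow their regulator direction). A candidate must satisfy the
expectation in **all** senescence datasets; failures are excluded with a
reason token (`inconsistent:<label>`). The rule is invariant to flipping
every direction in all sets simultaneously, and filtering is idempotent
and order-independent. Discordant per-subject contrasts in the paired
comparison are *flagged* in a concordance report (signs of d_s per
subject), not filtered — the analogous manual-inspection step is
deliberately left to the analyst.

## qPCR quantification

ΔCt = Ct_target − Ct_reference per sample; ΔΔCt = mean ΔCt(treated) −
mean ΔCt(control); fold change = 2^(−ΔΔCt), assuming perfect doubling per
cycle (no efficiency correction). Group-mean ΔΔCt is used because the
assay groups are not paired; per-treated-sample fold changes against the
control-mean ΔCt are also returned so a standard error can be quoted.
Swapping the groups inverts the fold change exactly, and any constant
offset applied to one gene's Ct across all samples cancels.

## The synthetic-study generator

`generate_study` emulates the statistical structure of the motivating
study: one paired perturbation experiment (default 3 subjects × 4
conditions) and two unpaired senescence datasets (default 3 case vs 3
control), generated log-normally:

    log2 x = baseline(g) + subject_effect(s) + condition_effect(g, cond) + N(0, σ)

Defaults: baseline ~ N(5, 2²) (log2 FPKM-like), subject effect
~ N(0, 0.1²) shared across a subject's four samples (the within-subject
correlation the pairing removes), noise σ = 0.25, effect size
|log2FC| = 1.0. The default effect/noise pair gives intermediate power at
B = 1000, so power tests are informative rather than saturated; the
power-recovery runs use effect 2.0 as the strong-effect condition. Planted
regulator-induced genes get +effect under OE and −effect under KD (the
paired contrast therefore sees ≈ 2·effect); suppressed genes the reverse.
Planted senescence genes shift the case group by ±effect. Shared
"consistent" genes follow the regulator-down rule in every senescence
dataset; shared "inconsistent" genes violate it in exactly one.
`n_senescence_de` counts senescence-only planted genes per dataset, on top
of the shared ones; senescence-only blocks are disjoint from the regulator
genes and from each other so the planted shared genes are the only
expected triple overlap. Each senescence dataset draws its own baseline
(different platforms/studies). Everything is a deterministic function of
the seed.

What the generator does **not** emulate: count-level sampling noise
(negative binomial), library-size or GC artifacts, batch effects,
correlated gene modules, or platform-specific probe effects. Passing
recovery tests therefore demonstrates the statistical machinery is
correct under the stated generative model, not that real data meet that
model.

## Problem sizes and reproducibility checks

The calibration and power suites use 2000 genes, 3 subjects and B = 1000
permutations — the same shape as the motivating study and large enough
for stable fractions; the integration-recovery run uses 800 genes with
100 senescence-only DE genes per dataset and 5 + 2 planted shared genes.
Exactness of the permutation machinery is checked on a 2-subject,
20-gene instance against full enumeration (576 relabelings). The
global-null type-I fraction at Pt ≤ 0.05 is asserted within [0.03, 0.07]
(binomial tolerance at 2000 correlated genes); planted-effect sensitivity
≥ 0.9 and precision ≥ 0.8 at effect 2.0. All of these are recomputed by
`scripts/acceptance.py` at run time; nothing is hard-coded.

## Known limitations

- Pooled nulls trade per-gene calibration for resolution (above).
- With 3 subjects the paired test cannot distinguish subject-specific
  regulation from noise; the concordance report surfaces this but the
  decision is left to the analyst.
- Cross-platform gene matching is by symbol only; probe-to-gene mapping
  and ortholog handling are out of scope.
- Quantile normalization assumes comparable global distributions across
  samples; it will erase genuine global shifts.
- The ΔΔCt method assumes amplification efficiency 2 for both genes.
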