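# Methods

## The heterogeneity score

The package targets a specific blind spot of classical gene-set enrichment:
a pathway whose members split into an upregulated and a downregulated half
within one tissue has a set-average shift near zero and is invisible to any
mean-based statistic, yet such bidirectional rewiring is exactly what
distinguishes one cell type's copy of a pathway from another's.

Each tissue is compared against a *virtual median cell*: the per-gene median
across all samples of all tissues.  For gene *i* and tissue *T*,

    t_i = (M1(i) - M2(i)) / s(i)

with M1 the median over T's replicates, M2 the all-sample median, and s the
pooled standard deviation of two groups.  A median has no variance of its
own, so "the two groups" are taken as (a) the tissue's replicate values and
(b) all samples' values, pooled by the standard two-sample formula
sqrt(((n1-1)s1² + (n2-1)s2²)/(n1+n2-2)); a config switch (`group2="rest"`)
instead uses only the samples outside the tissue.  Genes with
|M1 - M2| below log2 of the fold-change threshold (default 2) are filtered
out, and

    HS(S, T) = sum over filter-passing members of S of |t_i|.

Expression values are assumed log2-scale (RMA-style normalisation), so a
fold-change threshold *c* becomes an absolute log2 difference of log2(c).
Guards: 1e-8 is added to every pooled sd, and genes whose two group
variances are both below 1e-8 get t = 0, so constant probes never
contribute.

## Permutation inference

Sample-to-tissue labels are permuted and steps 1-3 (t-statistics, filter,
HS) recomputed per permutation.  Two conventions needed fixing:

* **Equivalent arrangements.** Permuting samples *within* a tissue changes
  nothing, so enumeration runs over distinct label arrangements
  (n!/prod(n_t!) of them).  HS of a set in tissue T depends only on which
  samples form T's group, so the exhaustive path enumerates group
  compositions and weights each by its arrangement multiplicity — a
  mathematically identical but much faster formulation.
* **Ties.** For the test of tissue T, an arrangement that assigns the same
  sample multiset to T as the observed labelling reproduces the observed HS
  identically; counting those forced ties as exceedances would floor every
  p-value at roughly (number of such arrangements)/(total) — 20/1680 on a
  3-tissue x 3-replicate design — making FDR-adjusted significance
  unreachable on exactly the designs the method is meant for.  Such
  arrangements are therefore excluded from T's null (they are not distinct
  relabelings of that test).  Genuine ties between *different* compositions
  still count as exceedances, and the add-one estimator

      p(S,T) = (1 + #{HS_perm >= HS_obs}) / (1 + N_distinct)

  keeps p strictly positive; in particular an observed HS of 0 still gets
  p = 1.  When the total arrangement count exceeds `exhaustive_cap`
  (10,000) the null is sampled by `n_perm` Monte Carlo permutations with
  the same conventions.

Benjamini-Hochberg correction is applied jointly across all (set, tissue)
tests (the conservative family choice), via statsmodels.  Significance is
reported at q < 0.05.

A note on shortcuts: a fixed HS threshold cannot replace the permutation —
the null scale of HS depends on set size and on how many genes survive the
filter — so no score-to-p conversion is offered.

## Tissue specificity (the 60% rule)

A *heterogeneous element* of a set is a measured member passing the filter
in at least one tissue; it is *unique* to T when it passes in T only.  A
set is assigned to T when unique-to-T elements make up at least 60% of its
heterogeneous elements (threshold configurable; ties are impossible above
50%).

## Pathway Z-score

For heatmap display the per-tissue fold change of gene *i* is M1 - M2 (log2
space); with mu and sigma the mean and sd of all genes' fold changes in the
tissue, x_p the mean over a set's p measured genes,

    Z = (x_p - mu) * sqrt(p) / sigma.

For a mean-zero bidirectional set, x_p ~ mu and Z ~ 0 — the contrast that
motivates HS.

## Comparators

Two minimal, self-contained comparator scores are included ("pgsea-like",
"gsea-like"; parity with the published R packages is a non-goal):

* **pgsea-like** — per sample, fold change = value minus the gene's
  all-sample median; a set's score is the one-sample t of its members' fold
  changes against zero, floored at sd 1e-12 (a degenerate set of identical
  fold changes reports a huge finite score and p clipped to 1e-15).  The
  per-tissue score is the mean of the tissue's per-sample scores, with a
  two-sided p from t(n_set - 1) — the aggregation the per-sample definition
  leaves open, documented here as the package's choice.
* **gsea-like** — weighted Kolmogorov-Smirnov running sum with weight
  exponent 1; ranking metric per tissue is the per-gene pooled-variance
  two-sample t of the tissue against all other samples.  Misses decrement
  1/(N - n_set) (zero when the set is the whole universe); if every member
  metric is zero, hits fall back to equal weights.  Significance is by
  phenotype permutation on |ES|.

## Simulation study

Data follow a linear additive model: y_ij = alpha_i + beta_ij + eps_ij with
alpha_i ~ N(0,1) per gene, eps ~ N(0,1), and beta drawn per gene and sample
from N(mu_g, sigma_g) by sample group (three groups of as-equal-as-possible
size; n = 10 splits 4/3/3).  Only the truly shifted members of the DE set
get a non-null group-1 effect: (0.5, 0.5) weak, (1.0, 0.5) strong; all
other gene-group pairs use (0, 1), so a null gene's within-gene variance is
2.  The shifted count is round-half-up(fraction x set size).  Each dataset
is fully determined by (seed, rep_index) through a PCG64 generator.

Each method reduces a dataset to one score per sample per set:

* pgsea: the per-sample one-sample t above;
* gsea: the running-sum ES on the per-sample fold-change ranking;
* heterogeneity: the *signed* sum of standardised deviations
  (x_ij - M2(i))/s2(i) over set genes whose |x_ij - M2(i)| clears the
  fold-change threshold, with M2/s2 the all-sample median and sd.  The
  tissue-level algorithm sums |t|, but a per-sample absolute deviation is
  uninformative here: under the simulation's strong setting the shifted
  group's variance drops (sigma_1 = 0.5) by almost exactly as much as its
  mean rises, so E|z| barely moves and an absolute-value score has
  essentially no power (and is non-monotone in effect size).  Keeping the
  sign restores a score that responds to the planted shift while the filter
  still restricts it to strongly perturbed genes in either direction.

A one-way fixed-effects ANOVA across the three groups at alpha = 0.05 on
each score vector yields, over replicate datasets, power (rejections on the
DE set) and empirical type-I error (rejections on the matched non-DE set),
with 95% Wilson intervals.  The default study grid covers
n in {10, 20, 40, 60}, set sizes {50, 150}, shifted fractions
{0.25, 0.5, 0.8} and both effects; the test suite and acceptance script run
200 replicates per cell (the full 500 is a flag away) at m = 5000 genes.

## ROC/AUC evaluation

Ground truth is consensus-derived from the comparators over (set, tissue)
tests pooled across tissues: positive when q < 0.01 in *both* methods,
negative when q > 0.2 in both, ambiguous (excluded) otherwise; an "any"
rule is available behind a flag.  The heterogeneity score (HS) is the
classifier score.  AUC is the normalised Mann-Whitney statistic with
half-credit for ties — identical to the trapezoidal integral of the ROC
curve (curves from scikit-learn).  AUC significance is by permuting the
positive/negative labels over the scored tests: p = fraction of permuted
AUCs >= observed, floored at 1/n_perm, with exhaustive enumeration when the
label arrangements number at most 10,000.  The protocol is run at
fold-change thresholds 1.5, 2 and 3.

## Promoter scanning and networks

Scanning uses the MATCH scoring scheme.  Position weights
I(i) = sum_b f(i,b) ln(4 f(i,b)) (frequencies carry a 0.01 pseudocount, so
logs are finite); a window's score is Current = sum_i I(i) f(i, b_i),
normalised as MSS = (Current - Min)/(Max - Min) with Min/Max substituting
per-position minimal/maximal frequencies.  MSS is exactly 1 on the
consensus window and exactly 0 on the anti-consensus.  The core similarity
score applies the same formula to the 5 consecutive positions of highest
total information (the whole motif when shorter).  A hit needs MSS and CSS
both >= the cutoff (0.7 default, per the putative-regulator convention);
windows containing N never match; both strands are scanned, positions
reported as 1-based forward-strand starts.  A degenerate matrix with
Max = Min scores every window 1.0.

Motif over-representation: the statistic is the number of target promoters
with >= 1 hit; the null redraws target-set-sized subsets from a
user-supplied background (no genome download; GC matching is not applied),
p = (1 + #{null >= observed})/(1 + n_draws).  The minSum cutoff minimises
FN% + FP% over a 0.50-1.00 grid (step 0.01, ties to the larger cutoff),
with positives sampled from the PWM columns — a documented interpretation,
since exon-based negative sets are not assumed available — and FP% the
per-window background match rate.

Network edges run from TFs whose motif is over-represented (p < 0.05) *and*
which are themselves upregulated in the tissue (t > 0 and passing the
fold-change filter) to heterogeneous member genes of significant pathways
whose promoters carry a passing hit.  The curated-vs-scanned provenance is
an `evidence` tag on each edge ('annotated'/'putative'), not two pipelines.
Only JASPAR-format matrices are read.

## Synthetic fixtures: what they emulate and what they do not

`generate_fixture` emulates an RMA-normalised multi-tissue array study:
per-gene baselines ~ N(7, 1) on the log2 scale, replicate noise
N(0, 0.25), and planted log2 shifts added to a target tissue only.  The
defaults mirror the headline scenario: 2,000 genes, 3 tissues x 3
replicates, one 50-gene pathway with half its members at +1 and half at -1
log2 units, 20 same-sized decoy sets.  `generate_promoter_fixture` builds
uniform-random 300-bp promoters with a 12-bp motif (consensus base
frequency 0.95) embedded in a chosen fraction of 50 targets against 500
backgrounds.  Neither generator models inter-gene correlation, probe-level
effects, batch structure, sequence composition bias or motif clustering —
so passing tests demonstrate correctness of the statistics under their
stated model, not robustness to those real-data features.

## Problem sizes in the test suite

The bundled tests and the acceptance script use 50-seed replications of the
planted-fixture contrast, 200-replicate simulation cells at m = 5000, and
200-500 draw enrichment nulls; these sizes give binomial standard errors
well inside the asserted margins while keeping a full run to minutes.

## Known limitations

* The pooled-sd reading of the t-statistic (tissue vs all samples) double
  counts the tissue's replicates in group 2; the `group2="rest"` switch
  avoids this at the cost of a smaller reference group.  Both are exposed
  because the definition admits either reading.
* Permutation resolution is bounded by design size; with 3x3 designs the
  per-test null has 84 distinct compositions, so p-values are granular and
  the exclusion-plus-add-one convention above determines the attainable
  floor.
* The comparators are deliberately minimal; they reproduce the qualitative
  directional-vs-bidirectional contrast, not any particular R package's
  numbers.
* TRANSFAC matrices are not supported (proprietary); promoter extraction
  from a genome is out of scope — sequences arrive pre-extracted.
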