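# Methods

## Scope and data model

`thermomod` operates downstream of primary normalization: its inputs are an
expression matrix on a log-like scale (genes × samples, TSV), sample
metadata (condition / tissue / study), an optional probe→gene map, a
gene→term annotation, gene models (BED6), per-base coverage tracks
(bedGraph), and peak calls (BED5 with a confidence score).  Raw-data steps
(array normalization, read mapping, peak calling) are deliberately outside
the package; the pipeline consumes their outputs.  All genomic coordinates
are 0-based half-open; the TSS of a minus-strand gene is `end − 1`.

## HVG selection

The variability of a gene across temperature regimes is measured twice on
the *pre-z-score* matrix: the standard deviation over all samples (sample
SD, n−1 denominator) and the p-value of a one-way fixed-effects ANOVA over
condition groups.  Selection demands both `SD > t_SD` and
`−log10 p > t_p`, strict inequalities.  The ANOVA is never run on z-scores:
z-scoring equalizes per-gene SD and would erase the first criterion.
Conditions with fewer than two samples are dropped with a warning; all-flat
genes get p = 1; p-values below the smallest positive normal double
(≈2.2e−308) are clamped and flagged, capping −log10 p near 307.7.

Cutoffs can be fixed by the user or derived from the scree plot of each
sorted statistic.  The elbow is the point of maximal perpendicular distance
from the chord joining the first and last points of the descending curve —
a parameter-free, deterministic knee detector; ties break to the smallest
index, and an exactly linear curve is reported as having no elbow.
Conventional fixed cutoffs of `SD > 1` with `−log10 p > 35` or `> 10`
correspond to compendia of roughly 150 profiles; at desk scale
(7 conditions × 3 replicates = 21 samples, F with (6, 14) df) even a strong
planted effect of 6 within-condition SDs yields `−log10 p ≈ 5–8`, so the
elbow-derived cutoffs are the operative route for simulated data, and the
fixed cutoffs serve as the stringent reference in null-calibration checks.

## Clustering and group statistics

HVG profiles are z-scored per gene (constant rows become zeros and are
flagged rather than dropped, and are excluded upstream by the SD criterion
anyway) and clustered with Ward's minimum-variance linkage on Euclidean
distances — the combination Ward's criterion requires.  The dendrogram is
cut into exactly k clusters; labels are renumbered by descending size so
cluster 1 is always the largest, making runs comparable.  k is a user
parameter; the default is the elbow of the within-cluster sum of squares
over k = 2..10.  The partition is invariant to gene input order (labels
may permute; membership does not).

Group comparisons pool (gene, sample) normalized values — one observation
per profile value, matching dot-per-profile summaries.  The family-level
test is one-way ANOVA followed by Tukey's HSD over all condition pairs
(studentized-range family-wise adjustment, via statsmodels).  Two-group
comparisons use the two-sided Wilcoxon rank-sum test with a Bonferroni
multiplier equal to the number of requested comparisons; the exact null
distribution is used for combined n ≤ 25 without ties, otherwise the normal
approximation with continuity and tie corrections.  All-tied comparisons
report p = 1 with a tie flag.  Star annotations follow the bands
p ≤ 0.05 (*), ≤ 0.01 (**), ≤ 0.001 (***), ≤ 0.0001 (****), else ns, applied
to adjusted p-values.

## Enrichment

Per term, the one-sided over-representation p is the hypergeometric upper
tail P(X ≥ k) with universe N (the declared background), term size K,
query size n, overlap k; k = 0 reports p = 1.  The term universe is every
term with K ≥ 1 after restricting the annotation to the background.
Adjustment is Benjamini–Hochberg by default with Hochberg step-up
selectable; under-representation and annotation-graph propagation are out
of scope (the annotation is treated as flat).  Binding-class composition of
clusters is tested with the Pearson chi-squared statistic on the
cluster × class count table, expected counts from the margins,
df = (r−1)(c−1), continuity correction off so the statistic equals
Σ(O−E)²/E exactly; zero-margin rows/columns are dropped and expected counts
below 5 raise a validity flag.

## Occupancy analysis

Coverage normalization divides every per-base value by the genome-wide mean
computed over *all* declared genome positions, zeros included — no
mappability mask — so a normalized value is a fold over average coverage
and the track mean is 1 by construction.  Peak→gene assignment is
deterministic: a peak's midpoint (floor of the interval centre) must lie
within `[TSS − w, TSS + w]`, both ends inclusive (default w = 500 bp), and
the peak goes to the qualifying gene with the nearest TSS, ties broken to
the lexicographically smaller gene identifier.  A gene's binding score is
the maximum over its assigned peaks (recorded in output metadata; summing
per-promoter peaks is the plausible alternative).  "Bound" means at least
one assigned peak regardless of score — score thresholds belong to the
upstream peak caller.

Meta-profiles extract the 2w+1 per-base values centred on each gene's TSS,
reverse minus-strand vectors so negative offsets are always upstream, and
average across genes.  Genes whose window intersects any other gene's body
`[start, end)`, or runs off the chromosome, are excluded; the count of
exclusions is reported.  Binding classification across assay conditions:
type I = bound only in the designated specific condition; type II = bound
in every condition; other = any remaining bound pattern; none = unbound.
The four classes partition the gene universe per TF.  Multi-TF comparisons
report the intersection of all target sets ("common") and, per TF, the
genes no other TF targets ("specific"), with score and expression summaries
suitable for rank-based tests.

## Synthetic data generator

The generator emulates the statistical structure of an integrated
temperature compendium, not its biology.  Expression: per-gene baseline
~N(7, 1) on a log-like scale; each planted module adds `effect_size` times
a per-condition multiplier in its active conditions (heat-shock module:
heat shock 1.0, recovery 0.5; cold module: freezing and cold 1.0; ambient
module: low and high ambient 1.0; freezing-suppressed module: freezing
−1.0); i.i.d. Gaussian noise `noise_sd` per cell; a scalar batch offset
~N(0, `batch_sd`) per sample.  Defaults: 2000 genes, four modules of 100,
seven conditions × 3 replicates, effect_size 3.0, noise_sd 0.5, batch_sd
0.3 — an effect of six within-condition SDs, the regime of strong
temperature-stress responses, at replicate counts typical of individual
expression studies.

Genome/binding: genes of 500 bp are laid sequentially on (default) two
chromosomes of 2.5 Mb with 1400 bp intergenic gaps; a configurable 10% of
genes are placed only 250 bp after their neighbor to exercise the
meta-profile exclusion rule; strands are random.  Coverage per TF and
condition is a flat background (5 reads/bp) plus a symmetric triangular
bump of half-width 250 bp and height `peak_height × background` (default
10×) centred on the TSS of every gene bound in that condition;
condition-specific bumps are 2× taller than constitutive ones, mirroring
the higher peak-calling confidence of condition-specific binding sites.
Peak tables carry one record per bump with score = bump height.
Condition-specific (type I) targets are drawn from the heat module and
constitutive (type II) targets from the cold module (half of each, by
default), so cluster × class enrichment has planted signal.  Annotation:
one term per module covering 80% of its genes plus a 2% background rate,
and 20 random background terms at 5%.

Every output is a pure function of (config, seed); independent RNG streams
per operation keep expression, genome, and annotation draws decoupled.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: probe-level microarray artifacts,
mean–variance coupling of counts, gene–gene correlation beyond module
membership, gene-specific batch interactions, diurnal/light covariates
confounded with temperature (a real concern for ambient-temperature
modules), mappability and GC biases in coverage, and peak-caller score
distributions.  The scalar per-sample batch offset is a stand-in: real
batch structure is richer, and joint normalization upstream is assumed to
have removed most of it.

A consequence of the shared batch offsets worth stating: under the null
(effect_size 0) each gene's ANOVA p-value is marginally uniform, but all
genes share the same per-sample offsets, so p-values are dependent across
genes and any single dataset's pooled calibration check (KS uniformity,
fraction below 0.05) will fail for an unlucky batch draw.  Calibration
checks therefore run with batch_sd = 0, which is the exchangeable null the
nominal rate refers to.

## Numerical choices and degenerate inputs

- Sample SD (n−1) throughout, with a ddof switch on z-scoring; z-scoring is
  idempotent to 1e-9.
- z-scoring with `group_by` normalizes each sample group independently —
  used to re-normalize tissues jointly for cross-tissue comparison; the
  grouping used is recorded per run.
- Elbow detection requires ≥3 points sorted descending; flat-curve
  tolerance is 1e-9 relative to the curve's range.
- Ward clustering requires 2 ≤ k ≤ n_genes; k = n gives singletons.
- Wilcoxon switches to the asymptotic path at combined n > 25 or in the
  presence of ties; exact and asymptotic p-values differ most for tiny
  samples, which the exact path covers.
- Coverage tracks that are identically zero are an error (no mean to
  normalize by); empty gene sets and empty groups are errors, not silent
  no-ops; conditions with one observation are dropped with a warning.
- The pipeline orchestrator fails fast, naming the stage and the offending
  input; outputs are plain TSV with header rows, plus a JSON manifest with
  package versions, the config hash, the seed, cutoffs actually applied,
  and per-stage counts.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
desk scale: null calibration uses 2000 genes × 21 samples over 10–20 seeds;
planted-recovery uses four 100-gene modules over 10 seeds; occupancy checks
use 300–2000 genes on 1.2–5 Mb toy genomes.  These sizes keep a full run in
well under a minute while leaving every statistical check far from its
detection floor.

## Known limitations

- The elbow rule is one of several defensible knee definitions; curves with
  two knees or heavy tails can move the chosen index.  Fixed cutoffs are
  the escape hatch and are always recorded.
- Tukey's HSD assumes balanced-ish groups and homoscedasticity; pooled
  (gene, sample) observations are also not independent across genes within
  a module, so its p-values are descriptive rather than strictly inferential
  at the family level — matching how such panels are commonly annotated.
- Peak→gene assignment considers TSS proximity only, not enhancer contacts
  or gene-body binding.
- The chi-squared test on binding classes treats genes as independent
  draws, which planted module structure (and real co-regulation) violates.
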