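# Methods

This note documents the models and procedures implemented in `vetkey`, their
default parameters, the design decisions taken where the workflow left
choices open, and what the synthetic panels do and do not represent.

## Synthetic panels

**Genotypes.** Each SNP draws an ancestral allele frequency from
Uniform(0.05, 0.95); the lower bound keeps the panel clear of degenerate
rare-allele SNPs so the MAF filter is exercised without dominating the
panel. Each population then draws its own frequency from the
Balding–Nichols Beta distribution, Beta(p(1−F)/F, (1−p)(1−F)/F), with a
per-population drift parameter F ∈ [0, 1); F = 0 reproduces the base
frequency exactly. A population may declare its base frequency as a weighted
mixture of previously defined populations' frequencies, which is how
retained shared ancestry / isolation-by-distance gradients are emulated (a
flat independent-drift model cannot place one population "between" two
others). Diploid genotypes are two binomial allele draws; F1 hybrids draw
one allele per SNP from each parental frequency vector; first-generation
backcrosses combine a gamete from the recurrent parent with a gamete whose
per-SNP origin is 50/50 between the parents (expected ancestry 75/25);
sibling groups are Mendelian offspring of two parents drawn once per group.
Missingness is missing-completely-at-random (default rate 0.02) — the
simplest model consistent with what a per-SNP missingness filter removes.

**Default study-like configuration** (`default_config`): six clusters —
wild mallard (n=40, F=0.05), interior Mexican duck (30, 0.05), northern
Mexican duck (40, F=0.02 around a base of 85% interior + 15% wild-mallard
frequencies, encoding retained mallard ancestry in the north), western-coast
Mexican duck (20, F=0.05 founded from the northern base), game-farm mallard
(20, 0.15), and Khaki Campbell (10, 0.18); four wild-mallard F1s, two Khaki
Campbell F1s, two backcrosses, and three sibling groups. The panel carries
6,000 SNPs (about half the marker count of a typical filtered ddRAD panel,
chosen as the desk-scale point at which relatedness and F1 signals resolve
cleanly), with 5.5% assigned to the Z chromosome.

**mtDNA.** Two core control-region sequences (default 625 bp) separated by
15 substitutions define the OW-A and NW-B haplogroups. Each maternal lineage
(one per independent sample, one per sibling group) adds
Poisson(1.5)-distributed private substitutions to its haplogroup core.
Hybrids inherit the maternal parent's haplotype process; domestic lineages
are fixed for OW-A, wild mallards carry OW-A at 31%, Mexican ducks at 1%.

**Traits.** Pure Mexican ducks draw null (0) states, with a 10% chance of a
single background level-1 noise state (so null birds score PS 0–1). Immature
males are special: with probability `variant_expression_prob` (0.25) they
express a random bundle of the mallard-like variant traits (≤25% green head,
tidal back pattern, black in rump, flank vermiculation, under-tail
vermiculation, partial tail curl). The configured fraction
`ps_le4_fraction` (0.97) of **all** immature males stays at PS ≤ 4; the
complement (3%) is drawn from within the expressers and overflows into the
hybrid PS range. This is the only reading under which a 25% expression rate
and a ~97% immature-male key accuracy are simultaneously attainable, and
both rates are verified by construction in the tests. For immature males the
background noise draw excludes the variant traits, whose expression is
governed solely by `variant_expression_prob`. Mallards draw each applicable
trait at its maximum level with probability 0.97 (else one level lower).
Hybrids take the forced intermediate level on the three 3-level traits, a
mixture level on the 4-level green-head trait, and 50/50 parental draws on
the binary traits, rejection-sampled into the window (4, cohort max − 3];
a `hybrid_overlap` knob widens the window, since real hybrid PS ranges are
variable and no fixed effect size is defensible. Structural traits are
normal draws whose adult means differ by class only for tarsus length, wing
arc, and mass.

## Filtering

The chain is order-dependent: MAF → missingness → LD. Boundary semantics
follow the flag definitions: a SNP at minor-allele frequency exactly 0.005
is retained (removal is strict `<`), a SNP missing exactly 20% of calls is
removed (inclusive `≥`), and a pair at r² exactly 0.5 is retained (removal
is strict `>`). LD r² is the squared Pearson correlation of {0,1,2} dosages
over complete pairs (pairwise deletion; no imputation), computed as
cov²/(var·var) so dyadic boundary cases are exact. "Window 2, step 1" is
read literally as SNP-count windows of adjacent pairs, pruned repeatedly in
the supplied SNP order until no window pair exceeds the threshold; whether
the original analysis pruned within loci only is not recoverable, so pruning
in supplied order is the documented behavior. Each filter is idempotent on
its own output, and the report satisfies removed + retained = input.

## Ancestry model

The admixture log-likelihood
Σᵢⱼ [gᵢⱼ log(Σₖ qᵢₖ fₖⱼ) + (2−gᵢⱼ) log(Σₖ qᵢₖ(1−fₖⱼ))] is maximized by EM
block updates from a seeded Dirichlet/uniform start. EM was chosen over
quasi-Newton block relaxation: the likelihood target is identical, the
update is monotone (asserted at every iteration), and convergence speed is
adequate at desk scale; the cost is more iterations near the optimum, so the
default `max_iter` is 500 with `tol` 1e-4 on the log-likelihood and a
best-so-far result flagged `converged=False` on exhaustion. Frequencies are
clipped to [1e-6, 1−1e-6]. On tiny instances the EM optimum is checked
against a per-sample grid search over q (grid 0.01) given the EM
frequencies.

K is selected by masked-entry cross-validation: 10% of observed entries are
masked per fold (default 5 folds), the model is refit, and masked dosages
are predicted as 2·Σₖ qᵢₖ fₖⱼ; the CV error is the mean squared deviation and
the reported K minimizes the fold-mean error. Bootstrap standard errors
resample SNP columns with replacement (B refits), align clusters to the
point estimate by greedy correlation matching of cluster frequency vectors
(ambiguous replicates dropped with a log message), and take the per-cell
standard deviation. Combined assignments over labeled cluster groups sum q,
with SE = √(Σ SE²).

## Co-ancestry and siblings

The co-ancestry matrix is a documented simplified analogue of
chromosome-painting co-ancestry, not a reimplementation of it: per-SNP
sharing s = 1 − |g_a − g_b|/2 over complete pairs, weighted by allele rarity
w = −log max(p, 0.001). The weight is monotone in rarity and bounded at the
MAF floor; only the rank/threshold behavior of the matrix is meaningful, and
all decision rules are written at that level. The dendrogram is
average-linkage clustering of 1 − C.

Sibling candidates are same-population pairs with C above the population's
within-group mean + `t_sd`·SD (default t_sd = 3, a value with measurable
specificity under the simulation null — the source workflow says only
"higher than average"). Pairs merge by transitive closure; a group is
confirmed when all members share a collection site and (when a haplotype
table is available) one mtDNA haplotype, otherwise it is retained
unconfirmed; a missing haplotype table leaves the flag unknown rather than
failing the group. Representatives are the lexicographically first member,
and dropping to representatives removes Σ(group size − 1) samples.

## Hybrid decision rules

**Assignment rule:** hybrid iff the summed assignment to the focal taxon
AND to the union of all mallard types are each strictly greater than the
threshold (default 0.10). The rule uses point estimates, with bootstrap CIs
attached and a low-confidence flag when the mallard-side 95% CI overlaps 0.
Raising the threshold can only shrink the hybrid set.

**Co-ancestry rule:** hybrid iff (a) mean co-ancestry to each parental
reference group exceeds the grand mean of cross-group co-ancestry, and (b)
the sample's dendrogram attachment lies outside every parental reference
population clade — its merge height (median cophenetic distance to the
clade) exceeds the clade's internal maximum merge height. Clade heights are
computed after trimming straggler members whose own merge heights fall above
the Tukey upper whisker (Q3 + 1.0·IQR over member merge heights): without
the trim, one outlying reference bird widens its clade enough to absorb
genuine F1s, which is the failure mode observed on the synthetic panels.
A feral-parent flag is set for called hybrids whose co-ancestry to the
domestic reference subset exceeds that to wild mallards. On panels with
retained shared ancestry the assignment rule systematically calls more
hybrids than the co-ancestry rule; the concordance report cross-tabulates
the two.

## Diversity and haplotypes

Nucleotide diversity: for aligned sequences, mean pairwise Hamming
differences per comparable site (pairwise deletion of non-ACGT characters);
for SNP panels, the per-site unbiased heterozygosity 2p(1−p)·n/(n−1)
averaged over assayed sites (optionally over a caller-supplied total site
count to express π per surveyed base pair). Differentiation uses the
Hudson-form estimator 1 − (mean within-group diversity)/(between-group
diversity) as a composite ratio of sums over all sites of a partition —
"composite" is not otherwise defined in the source workflow, so
concatenation (ratio of sums) rather than per-locus averaging is used and
documented here. Negative estimates are clamped to 0 with the raw value
retained; zero between-group diversity with positive within-group diversity
is flagged undefined. Z-chromosome statistics are computed identically to
autosomal ones; sex-aware ploidy correction is out of scope and logged as a
limitation. Haplotype collapsing is exact-sequence dedupe after uppercasing
(ambiguity characters make a sequence its own haplotype unless identical to
another); haplogroup assignment is nearest reference by Hamming distance
with ties reported as unassigned.

## Plumage scores and keys

The packaged schema transcribes the 16 ordinal plumage traits (12 binary,
three 3-level, one 4-level) and 7 structural/mass traits with their
applicable sex-age cohorts; cohort maxima are PS 21 (males), 15 (immature
females), 11 (adult females). Diagnostic flags are populated from the
applicability columns and marked provisional — the bolded diagnostic subset
of the original table is not recoverable from text. Missing traits
contribute 0 to PS and are counted in `n_missing`: the bias runs toward the
Mexican-duck class (the conservative direction for museum skins with gaps)
and the count keeps it auditable.

Structural traits are screened by one-way ANOVA per cohort (default alpha
0.001 — the stricter of the two thresholds quoted in the source material,
configurable) with Welch pairwise comparisons; they are excluded from PS,
ordination, and keys. Diagnostic trait selection fits a ridge-regularized
LDA (pooled within-class covariance + ε·I, ε scaled to 1e-4 of the mean
total variance; the ridge keeps perfect separators well-defined where
shrinkage estimators collapse to prior-only prediction) and runs standard
forward selection maximizing leave-one-out accuracy; accuracy ties resolve
toward fewer traits, then higher standardized loading, then schema order.

Keys are calibrated per cohort from the PS ranges of genetically vetted
reference classes. The Mexican-duck interval is fixed at [0, 4] (boundary
values belong to the lower class, so PS = 4 is Mexican duck); the hybrid
interval extends to the observed hybrid maximum and the mallard interval
covers the remainder. When observed hybrid and mallard ranges overlap, the
two merge into a combined hybrid/mallard class — distinguishing them is not
a goal the key can always meet; separating pure Mexican ducks from all
others is. Exact hybrid/mallard endpoints are calibrated values, not
constants. Rebuilding a key from its own classified reference panel
reproduces the intervals when the calibration classes are disjoint.

## What the synthetic panels do not show

The generator reproduces drift-based frequency structure, Mendelian
relatedness, maternal haplogroup inheritance, and cohort-conditional trait
distributions. It does not simulate linkage blocks or haplotype sharing
(each SNP is independent given the frequency vectors), read-level error,
locus dropout structure, coalescent genealogies, or recombination — so
passing tests demonstrate correctness of the estimators and decision rules
under the assumed model, not performance on raw sequencing data. Real
co-ancestry methods draw additional power from linked rare haplotypes that
the independent-SNP model cannot represent; the synthetic panels compensate
with somewhat higher per-population drift than the real species pair shows.
Absolute co-ancestry values are tool-specific; only their ranks and
thresholds carry meaning here.

## Problem sizes

Default test and acceptance runs use 600–6,000 SNPs and 100–180 samples per
panel, 20 seeded replicates for detection-rate estimates, and trait panels
of 800–1,000 records — sizes at which every stage completes in seconds on a
single CPU while leaving the filters, estimators, and decision rules
non-trivially exercised.
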