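# Methods

## Generative model and its assumptions

All inference rests on the diploid heterozygous identity: a somatic
variant private to a clone of cellular prevalence *P* (fraction of tumour
cells carrying it, i.e. the clone plus its descendants), observed in a
sample of purity *p* at a copy-number-neutral locus, has expected variant
allele fraction *p·P*/2. The assumptions behind it — and hence behind the
whole pipeline — are: diploid copy number at the tested loci (enforced by
the |CN − 2| ≤ 0.25 mask over *every* sample of a case), heterozygosity of
somatic point mutations, and well-mixed sampling of tumour and normal
cells. Loci without a covering segment default to copy number 2.

Clone fractions are expressed two ways. *Cellular prevalence* is the
subtree quantity above; *exclusive fractions* assign each tumour cell to
its most-derived clone and sum to 1 per sample. The instability index is
defined on exclusive fractions because that choice makes its two
interpretive endpoints exact: an unchanged monoclonal tumour scores 0 and
two completely unrelated tumours score 1.

## Somatic LLR filter

For tumour counts (r_t, v_t) and matched-normal counts (r_n, v_n), three
binomial models are compared with natural logarithms:

* somatic: normal at the sequencing error rate e, tumour at its ML allele
  fraction floored at e;
* germline heterozygous: both samples at 0.5;
* wild type: both samples at e.

llr = ll_somatic − max(ll_het, ll_wt); a call is retained when llr > 3
and both samples have ≥ 10× coverage. e defaults to 0.001 (a typical
short-read substitution error) and is exposed as a flag. Two properties
follow from the definition and are asserted in tests: wild type in both
samples gives llr exactly 0 (the somatic model degenerates into the
wild-type model), and llr is monotone in tumour variant reads only while
the wild-type branch is the best germline explanation — approaching 50%
VAF the heterozygous branch takes over and llr falls again. A variant is
kept for a case when it passes in at least one tumour sample,
union-of-evidence style.

## Clustering

The read counts of n variants across the S samples of a case form an
S-dimensional binomial mixture: variant i in component k has
var_is ~ Binomial(depth_is, θ_ks). EM is run for K = 1..k_max (default
10) with n_restarts = 10 quantile-spaced, seed-jittered initialisations;
K is selected by BIC with K·S + K − 1 parameters. A binomial (rather than
beta-binomial) component likelihood matches the generator's noise model
and keeps the M-step closed form; overdispersion is a noted extension.
Components with fewer than min_members = 5 hard members are dissolved and
their members reassigned (singletons cannot form clones); variants whose
maximum posterior is below 0.8 are flagged outliers but keep their
assignment; posterior ties break to the lowest cluster index. Cases with
fewer than 10 variants are refused and flagged for manual review. Cases
in which some cluster pair differs by less than 0.05 VAF in every sample
carry a low-separation flag. The per-sample *median VAF of member
variants* — not the fitted θ — is the subclone summary handed downstream.

## Purity

Purity is estimated per specimen (never pooled across cores) as
min(1, 2 × median VAF of the founder cluster). With a fitted clustering
the founder is the detected cluster with the highest median VAF in the
sample; without one, the upper mode of a Gaussian-KDE-smoothed VAF
histogram stands in. At least 20 copy-number-neutral variants with depth
≥ 20 are required; otherwise the estimate is refused with advice to
supply purity externally. The purity correction removes the expected
normal-cell read mass from the reference count:
adjusted_ref = max(0, ref − (1 − p)·depth), rounded half-up so that
Fisher's exact test downstream receives integer counts — the unique
linear rule mapping founder VAF p/2 to 50%. On the VAF scale this is
min(1, v/p).

## Temporal classification

Each variant's purity-corrected counts are compared between every
baseline core and every surgical core with the two-sided Fisher's exact
test (sum of table probabilities ≤ the observed table's). With several
cores the minimum p is used and direction is the majority sign of the
corrected VAF change (minimum-p pair breaks ties) — the aggregation rule
is this package's choice. p ≥ 0.05 → shared_stable; significant changes
with both corrected VAFs ≥ 10% → enriched/depleted by direction;
significant changes below 10% at the other time point become
baseline-/surgical-specific when the own-time-point RNA support is ≥ 1
read, else they degrade to enriched/depleted with an `rna_rule_failed`
flag. The 10% threshold applies to *corrected* VAFs, consistent with the
correction step preceding the test. No multiple-testing correction is
applied, mirroring the P < 0.05 retention rule; a BH option exists but is
off by default.

## Trees, fractions, collisions

Cluster prevalences are min(1, 2 × corrected median VAF); clusters whose
corrected median VAF is below the 1% detection limit in a sample get
prevalence 0 there rather than a noisy raw value. All parent maps rooted
at a founder candidate (a cluster maximal in every sample, within
tolerance — near-ties admit multiple candidate roots so finite-depth
noise cannot reject the true founder) are enumerated with depth-first
pruning; a tree is feasible when every parent's prevalence is at least
the sum of its children's in every sample within
ε = 0.05 + one binomial standard error of the cluster prevalence. Hard
constraints alone would reject true trees at finite depth, hence the
composite tolerance. Feasible trees are ordered by total sum-rule slack;
equal-slack trees are ordered by a label-free key built from prevalence
profiles, so cluster relabelling cannot change which tree ranks first.
Downstream numbers use the first (most parsimonious) tree; alternatives
are reported.

Exclusive fractions take the founder's prevalence as 1 (the tumour-cell
population after purity correction), subtract children's prevalences,
clip negatives (within tolerance) at 0 and renormalise to sum to 1.

A case is a collision when (a) no cluster is detected at ≥ 1% corrected
VAF in both a baseline and a surgical sample (disjoint variants), or
(b) clusters are shared but no single-origin tree is feasible even at a
3× relaxed tolerance. The relaxation is deliberate: "no feasible tree" is
an extraordinary claim, and transient EM overfits (a split cluster
double-counts prevalence mass) must not masquerade as a second tumour.
Only gross, sustained sum-rule violations qualify.

## Instability index and patterns

index = mean over the union of clones detected (exclusive fraction ≥ the
1% limit) at either time point of |f_pre − f_post|, with absent clones at
0; multi-core time points are averaged arithmetically (clones missing
from a core contribute 0) — the averaging rule is this package's choice.
Collision cases take the index's defining value 1.0 directly: for two
disjoint trees with more than one clone each the raw mean-absolute-
difference formula would yield 2/(n_A+n_B) < 1, contradicting the
index's stated interpretation that 1 means completely unrelated tumours.

Patterns: collision; simple_stable (one detected clone, index ≤ 0.1);
complex_stable (index ≤ 0.1); complex_dynamic (index > 0.1); manual
(unclusterable). The stable/dynamic boundary is inclusive on the stable
side so an index of exactly 0.1 — and the reference complex-stable case
at 0.097 — is stable. When an endocrine-response label is missing,
surgical Ki67 > 10% (strict) marks resistance, consistent with the
observed group ranges (sensitive 0–7.0%, resistant 10.4–47.1%). Cohort
medians are computed in exact rational arithmetic and rounded half-up
(indices to two decimals, Ki67 percentages to one), because floating
medians of printed decimals otherwise round the wrong way at exact
half-way points.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not raw reads: a rooted phylogeny per tumour (uniform random parent
assignment), per-sample exclusive fractions summing to 1, DNA depth
Poisson(depth_mean, floor 1) with binomial variant reads at
VAF·(1−e) + (1−VAF)·e, RNA support reads at Poisson(rna_depth_mean,
unfloored — zero depth models an untranscribed locus), and a matched
normal carrying error reads only. Purities default to the 12–100% range
seen in practice. Scenario shifts: stable |Δ| ≤ 0.05 per clone; dynamic
swaps a dominant (0.6–0.9) with a rare (≤ 0.03) clone, guaranteeing a
shift ≥ 0.5; emergent plants a clone at 0.5% exclusive fraction (below
the 1% VAF limit) that takes 50–80% post; collision builds two disjoint
trees, one per time point; monoclonal is a single founder. Optional
per-core Dirichlet jitter emulates spatial heterogeneity between
concurrent cores. Defaults: depth_mean 80 (the combined
discovery-plus-validation coverage scale; WGS-only and panel presets are
just different depth_mean values, with no claim to reproduce real depth
distributions), 50 variants per clone, RNA depth 30, error rate 0.001.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: copy-number aberrations and subclonal
CNV (all simulated loci are diploid), overdispersed sequencing noise,
mapping artefacts, strand bias, FFPE damage, and clone-specific
expression (RNA support mirrors DNA VAF).

## Validation benchmark

`clonaldrift.validation.run_recovery` fits 100 planted cases (cycling
stable/dynamic/collision scenarios; 2–5 clones; one core per time point;
depth 150; 50 variants per clone; purities 0.7–1.0; pairwise expected-VAF
separation ≥ 0.1 between clones) and scores clone-number recovery,
Hungarian-matched assignment accuracy, purity error, planted-tree
membership in the feasible set (undefined for collisions, which have no
single planted tree), index error and pattern recovery. Two geometric
facts shape the conditions: K clusters pairwise ≥ 0.1 VAF apart must fit
in a range of width purity/2, so purities are drawn from 0.7–1.0; and a
*stable* case must hold all separations in a single composition, which
caps stable scenarios at 4 clones. When rejection sampling cannot realise
the separation, the generator falls back to a deterministic spaced
composition (star or chain), which is why `min_vaf_separation` is off by
default and enabled only in the benchmark.

## Numerical choices and degenerate inputs

Binomial coefficients are omitted inside the LLR (identical across
hypotheses) but included in the mixture log-likelihood used by BIC. EM
stops at a relative log-likelihood change of 1e-8 or 500 iterations; θ is
clipped to [1e-6, 1−1e-6]. An all-zero Fisher table returns p = 1 with a
warning. A VAF at exactly the 1% detection limit counts as present
(closed boundary; "approximately 1%" is made testable by fixing the
boundary). Corrected counts at purity 1 are the identity. Single-time-
point cases refuse collision evaluation explicitly.

## Known limitations

Copy-number-aware clustering, beta-binomial overdispersion, ploidy-shift
tumours and subclonal CNV deconvolution are out of scope — cases with
complex copy-number and ploidy changes must be assigned manually (the
clinical table carries a `manual_pattern` override column for exactly
this). Tree enumeration is exhaustive and bounded at 10 clusters. RNA
allele-specific expression is not modelled; RNA reads serve only as
presence evidence. The tier system and manual review of the original
calling pipeline are represented by annotation fields, not automated.
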