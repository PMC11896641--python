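# Methods

## Scope and data model

`microstand` operates on the post-denoising product of an amplicon
workflow: an integer ASV-by-sample count table plus sample metadata
(habitat, stand age as a categorical label, plot). Reading, QC and
denoising of raw reads are upstream of this package; taxonomy and
guild/function assignments enter only as externally supplied
annotation maps, with unmapped taxa kept as an explicit "Unassigned"
category so composition summaries always conserve per-sample mass.

## Preprocessing

Rarefaction draws a multivariate-hypergeometric subsample per sample
(sampling reads without replacement), so each retained column sums
exactly to the target depth and no cell exceeds its original count;
samples below the depth are dropped and reported. The rare-ASV filter
removes features whose grand total falls strictly below a fraction
(default 0.005%) of the table's total reads; features exactly at the
threshold are kept, which makes results bit-reproducible. The default
pipeline order is rarefy first, then filter on the rarefied totals; the
order is configurable because the two orders legitimately differ and
the convention is a choice, not a theorem.

## Diversity and ordination

Shannon entropy uses natural logarithms (nats) by default, matching
the vegan-ecosystem convention; the base is an argument. Bray-Curtis is
computed on rarefied counts by default (proportions are an option);
pairs of all-zero samples are undefined and recorded as missing rather
than coerced to 0 or 1. Per-group beta diversity is summarized as the
k(k−1)/2 within-group pairwise dissimilarities (not distances to a
centroid), which is what per-group box plots with letter annotations
display.

PCoA double-centers −D²/2 (Gower), eigendecomposes, and keeps axes with
eigenvalues above a relative tolerance of 1e-10; proportions explained
are taken over the positive eigenvalues. Negative eigenvalues from
semi-metrics such as Bray-Curtis are dropped by default — the common
default for ordination of ecological dissimilarities — with a Lingoes
correction available behind a flag.

PERMANOVA is the one-way distance-based pseudo-F: with
SS_total = Σ_{i<j} d²_ij / N and SS_within the analogous per-group sum,
F = (SS_between/(a−1)) / (SS_within/(N−a)), and
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) over label permutations from
a seeded generator (999 by default). Only the one-way form is
implemented; crossed designs are handled by running within strata
(e.g., ages within one habitat). Note that permutations which happen to
reproduce the observed partition tie the observed F, so the attainable
p floor is slightly above 1/(n_perm+1) for small balanced designs.

## ANOVA and Duncan's multiple range test

Duncan's test uses the one-way ANOVA MS_error and error df, the
harmonic mean group size for unequal groups, and studentized-range
quantiles at the protection level 1−(1−α)^(p−1) for a range spanning p
ordered means. Testing is step-down: a range contained in a range
already declared homogeneous is never re-tested. Because homogeneity is
then a union of intervals over the ordered means, the compact letter
display is exact — the maximal homogeneous intervals become letters,
and two groups share a letter if and only if their comparison is
non-significant (property-tested exhaustively for up to five groups
against an independent second implementation).

## Co-occurrence networks

The published convention fixes only the 0.1% relative-abundance floor
and the Zi/Pi role thresholds; the edge criteria are this package's
explicit defaults, recorded on every exported graph: Spearman |ρ| ≥ 0.6
and Benjamini-Hochberg q ≤ 0.05, with the abundance floor applied to
the mean relative abundance across the samples entering the network
(per-sample maximum behind a flag). Constant taxa have undefined
correlations and cannot form edges. Module detection defaults to
deterministic greedy modularity maximization (Louvain behind a flag,
seeded); isolated nodes become singleton modules. Zi standardizes the
within-module edge count against the node's own module using the
population SD, with Zi = 0 by convention when that SD is zero (such
nodes cannot be hubs of a uniformly connected module); degree-zero
nodes get Pi = 0. Role thresholds are strict inequalities (hubs at
Zi > 2.5, connectors at Pi > 0.62); equality falls to the
peripheral/non-connector side since the published rules leave it
undefined.

## Average variation degree

For group g with k samples and ASV i, a_i(s) = |x_i(s) − x̄_i| / δ_i
with x̄_i and δ_i the within-group mean and sample SD (ddof = 1, a
documented choice — the defining equations do not fix the
denominator). Per-sample AVD averages a_i(s) over the n usable ASVs;
the group AVD is the mean over samples, identically the double sum
divided by k·n. ASVs with δ_i = 0 (absent or constant in the group) are
0/0 terms and are excluded from n by default (n can instead be held at
the global feature count). Per-sample values exist so that cross-age
significance tests have replicates; their mean equals the group-level
double-sum definition exactly.

A structural property of this definition deserves emphasis: because
every ASV is standardized by its *own* within-group SD, AVD is
invariant to per-ASV rescaling — each ASV contributes the ratio of its
replicate mean absolute deviation to its replicate SD, a quantity that
depends only on the **shape** of the replicate distribution, not its
magnitude. Two consequences follow. First, AVD is identical on rarefied
counts and on relative abundances at equal depth. Second, a group whose
replicates are simply "noisier by a scale factor" does **not** get a
higher AVD: simulations in this package show that scaling the
Dirichlet concentration of one group by 8× changes its expected AVD by
well under 2% (and if anything slightly downward, as heavier-tailed
replicate distributions have a smaller MAD/SD ratio). AVD therefore
discriminates between groups through changes in occupancy patterns and
distributional shape — sporadic presence/absence, skewed blow-ups —
rather than through variance magnitude per se. The dedicated
dispersion-contrast test in the acceptance suite documents this
honestly: pure concentration scaling is recovered by the replicate
variance of proportions, not by AVD rank order.

## Synthetic communities

The generator emulates the survey design: 4 groups (stand ages
12/22/30/40) × 5 replicates per habitat, 200 ASVs, library sizes
log-normal around 30,000 reads (SD 3,000) — the magnitude of the depths
that motivated the rarefaction defaults. Base log abundances are
normal with SD 1.5 (a few dominant taxa, a long tail); a configurable
subset of "effect" taxa is shifted on the log scale along a monotone
age gradient; per-sample compositions are Dirichlet around the group
mean with concentration 500 by default (moderate overdispersion;
divided by per-group multipliers for stability contrasts); counts are
multinomial at the drawn depth. Inter-taxon association is planted as
shared standard-normal latent factors added to log abundance for
blocks of taxa, so correlation must survive softmax compositionality,
Dirichlet noise and counting — the same distortions real inference
faces. Block taxa should remain a minority of the community: when
planted blocks dominate total abundance, compositional closure induces
strong negative cross-block correlations, which is a property of
compositions, not an artifact of the generator.

The generator is deterministic given its config (which includes the
seed). What it does not model: habitat-specific taxon identities, plot
autocorrelation (replicates are exchangeable), sequencing error or
chimeras, and taxon-specific dynamics. Passing tests on these
communities validate the statistical machinery against known ground
truth; they do not certify behavior on real data with structured noise.

## Problem sizes and numerical choices

The validation suite runs at deliberately modest sizes chosen to make
its Monte-Carlo checks sharp yet quick: PERMANOVA calibration uses 500
null communities (two groups of five, 200 taxa, 999 permutations; the
rejection rate must sit inside the binomial 95% interval around 0.05)
and 100 communities for power at a 2-log-fold shift on 20 taxa; module
recovery uses 20 seeds of a 100-taxon community with two planted
10-taxon blocks over 40 samples, scored by adjusted Rand index;
rarefaction expectations average 1,000 seeded draws. Tolerances: exact
formula oracles at 1e-12; PCoA embedding reconstruction at 1e-9;
eigenvalue retention at a 1e-10 relative tolerance. Ties in Spearman
use mid-ranks; BH correction is applied to the valid upper-triangle
p-values only.

## Known limitations

Spearman co-occurrence on relative abundances is not
composition-aware (no SparCC/SPIEC-EASI); rarefaction discards reads
and is used because the emulated workflow used it, not as a
recommendation; PERMANOVA is one-way only; Duncan's test controls its
special protection level, not the family-wise error rate in the
Tukey sense; AVD's shape-sensitivity (above) means it should be
interpreted as an occupancy/shape stability index rather than a
variance meter.
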