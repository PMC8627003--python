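# Methods

This note records the models, conventions and design choices behind the
package, in the order a user meets them.

## Bioenergetics

Growth metrics are pure arithmetic on tank records: growth `(W_f − W_i)/t`
(g/day), `SGR = 100(ln W_f − ln W_i)/t` (%BW/day, invariant to weight
units), survival `100 N_f/N_i`, and FCR as cumulative feed over the period
divided by per-fish gain. Feed intake is carried on a dry-matter basis; a
per-day intake times the duration serves as the cumulative amount. FCR is
`None` (never silently infinite) when gain is zero or negative. Report
tables round half-up, and only at the presentation boundary — chains always
run at full precision.

Digestibility uses the inert-marker ratio method: the marker (yttrium) is
not absorbed, so the nutrient-to-marker ratio in faeces relative to feed
measures the unabsorbed fraction. ADC is *returned* in percent (the
reporting convention) and *consumed* by the balance functions as a fraction;
the `/100` conversion is the caller's, at exactly one boundary.
Carbohydrate is computed by difference, `1000 − (protein + fat + ash)` g/kg
DM. Crude protein is definitionally Kjeldahl-N × 6.25, and profiles carrying
both fields are validated against that identity (1% relative tolerance).

The nitrogen chain is gross intake → digestible (× ADC_N) → retained
(body-pool difference over time), with branchial/urinary loss defined as the
remainder — so DN = RN + BUN holds to machine precision by construction, and
the test suite asserts it at 1e-9 relative tolerance. The energy chain
values excreted ammonia-N at 24.85 kJ per gram of N (all branchial/urinary N
assumed excreted as NH3-N), subtracts it from digestible energy to give
metabolisable energy, and defines heat production as ME − RE. Maintenance
energy subtracts deposition costs at fixed efficiencies of ME (protein 50%,
fat 90%). These three constants are module-level and immutable.

A note on trial duration: report tables of this kind are only internally
consistent for one specific duration (here 41 days reproduces the printed
growth and SGR from the printed weights), so duration is always an explicit
input, never inferred.

## ASV tables and community statistics

`AsvTable` validates a non-negative integer samples × ASVs matrix with
1:1-aligned metadata. Rarefaction is a single multivariate-hypergeometric
draw per sample (subsampling reads without replacement), seeded; it is not
averaged over repeats, because every downstream statistic consumes one
rarefied table. Samples below a minimum depth are dropped (and logged)
before rarefying. Unbiasedness of the subsampled proportions is asserted in
the tests.

Alpha diversity is observed richness and the Shannon index with natural
logs, intended for equal-depth (rarefied) tables. Beta diversity is
Bray–Curtis; ordination is classical PCoA (eigendecomposition of the
Gower-centred squared-distance matrix, via scikit-bio). Negative eigenvalues
of non-Euclidean matrices are reported as-is, with no Lingoes/Cailliez
correction, since none is applied in the workflow the package mirrors.

PERMANOVA is implemented from first principles on squared dissimilarities:
total and within-group sums of squared interpoint distances give the
pseudo-F, and p-values come from label permutation with the standard
`(1 + #{F* ≥ F}) / (1 + n_perm)` estimator. For one-way two-group designs,
`n_perm="exhaustive"` enumerates every distinct assignment and returns the
exact permutation p (identity included). Two-way crossed designs test main
effects by unrestricted permutation of raw observations, with residual
SS = total − SS_A − SS_B on n − a − b + 1 degrees of freedom; the
interaction term is omitted (the replicate structure of this design does not
support it robustly). Factor confounding (empty design cells) is rejected up
front. The default 9999 permutations is configurable.

SIMPER exploits the additive decomposition of Bray–Curtis: for each
between-group sample pair the dissimilarity is exactly
`Σ_k |x_k − y_k| / (Σx + Σy)`, so averaging each ASV's term over all pairs
yields contributions that sum to the mean between-group dissimilarity (an
identity asserted numerically in the tests). It runs on the rarefied counts
by default, with a flag for relative abundances.

Core membership is prevalence-based: an ASV is core in a group iff present
in strictly more than a threshold fraction (default just over 1/3, i.e. at
least 2 of 5 fish in a tank-treatment) of the group's samples. Venn-style
intersections and uniques are computed set-theoretically for any 2–4 groups
and across timepoints.

Indicator species use the IndVal statistic `sqrt(A · B)` where A is
specificity (a group's mean abundance over the sum of group means) and B is
fidelity (occurrence fraction within the group); the best group is taken per
ASV and significance comes from group-label permutations (default 1000).
Constant-zero ASVs are excluded.

DistLM-style marginal tests regress the Gower-centred distance matrix on one
predictor at a time: with hat matrix H of the centred predictor, the
explained trace is tr(GH), pseudo-F = tr(GH)/[(tr G − tr(GH))/(n − 2)], and
p comes from permuting the predictor (a fresh generator per predictor, so
marginal results are independent of column order). A plain
Pearson-versus-PCoA-axis companion is provided for descriptive use.
Mann–Whitney tests use midranks with tie correction, exact p for small
untied samples (scipy's auto policy); fully tied data return p = 1.

## Co-occurrence networks

Networks are built per treatment group from the rarefied table. A
configurable prevalence filter (default: present in more than 20% of the
group's samples) removes low-prevalence ASVs whose correlations are
unstable; this filter is an implementation safeguard, not part of the
workflow being mirrored, and can be disabled. All pairwise correlations
(Pearson default; Spearman available and preferred when monotone antagonism
matters) are tested, Benjamini–Hochberg adjusted across all pairs, and pairs
with adjusted p below alpha (default 0.05) become signed edges. Isolated
nodes are dropped but counted.

Topology metrics: density and average degree by their defining ratios;
clustering as the mean local coefficient with degree-<2 nodes contributing
zero; path length as the mean shortest path over connected pairs only
(component count logged); modularity as best-partition Newman Q at
resolution 1 on the unsigned graph — exhaustive over all partitions for
graphs of at most 8 nodes (exact, and the brute-force reference for the
oracle tests), Louvain with a fixed seed above that, so every value is
deterministic. Standard Q cannot exceed 1; published tables occasionally
print larger "modularity" values, which cannot arise under this definition
and are therefore not comparable to this package's output.

Group comparison subsamples every sample to 70% of its reads (without
replacement), rebuilds the network and its metrics per replicate (default
50, minimum 20), and compares replicate distributions per metric with
two-sided Mann–Whitney tests — pairwise between groups, or pooled by factor
levels when a group→factor mapping is supplied. Undefined (infinite)
positive/negative ratios are capped above the largest finite replicate
before ranking.

## Synthetic data

The community generator encodes the experiment's design: per sample the
expected composition is `(1 − κ(t)) · source + κ(t) · RAS`, a linear mixture
in proportion space between the sample's rearing source (FTS or BFS) and a
common recirculating-system community, with κ non-decreasing over
timepoints. Realised compositions are Dirichlet draws around the mixture
(concentration interpolated between source and RAS values), counts are
multinomial at depths drawn uniformly from the configured range — together a
Dirichlet-multinomial, chosen because ASV counts are overdispersed. Defaults
mirror the emulated study conditions: a species-poor, highly variable FTS
source versus a species-rich, homogeneous BFS source; eight core ASVs held
above a floor proportion in every community; depths spanning 3380–30442
reads; five fish per tank at the first two timepoints and three at the last;
three tanks per treatment with a two-diet split at the final timepoint.
Planted correlation blocks share a per-sample log-normal latent factor
(positive blocks multiply all members; negative blocks multiply one half and
divide the other), giving network construction a known truth to recover —
rank correlation recovers the negative blocks far more reliably than Pearson
on raw proportions, which is why the recovery experiments use Spearman.
Geometric (log-space) mixing was considered for the convergence model and
left as a non-default idea; linear mixing keeps κ interpretable as the
fraction of the community replaced.

What the generator does *not* emulate: taxonomy-dependent structure beyond
an arbitrary genus labelling, phylogenetic relatedness, read-level error or
chimeras (generation starts at the ASV-count level), tank-level
pseudo-replication beyond the sample grouping, and diet effects on
composition (diet labels exist so two-way designs can be exercised under the
null). Passing tests therefore demonstrate correctness of the statistics and
estimators under a plausible overdispersed compositional model, not that any
particular biological effect exists in real data.

The growth and digestibility generators invert their estimators from known
truth: `w_f = w_i · exp(SGR · t/100)` with mean-one log-normal tank noise
and a metabolic-weight feed ration (20 g per kg^0.8 body weight per day,
averaged over the true trajectory); faeces profiles whose nutrient-to-marker
ratios equal the feed's times `(1 − ADC_true)` with mean-one multiplicative
noise, the marker concentrating threefold. With zero noise, recovery is
exact; with noise, unbiased in expectation — both are tested.

## Pipeline and reproducibility

`run_full_analysis` validates a flat config against a schema before any
computation (unknown keys are rejected by name), derives every stage's seed
from the one top-level seed, and writes a manifest recording package
version, config, input digests, per-stage timings and output SHA-256
digests. Re-running from a manifest's config reproduces the outputs byte for
byte; a failing stage is recorded in the manifest with its error before the
exception propagates, and earlier outputs are retained.

## Problem sizes and numerical conventions

The test and acceptance workloads run at desk scale: null calibrations use
500 simulations (12 samples × 20 ASVs for PERMANOVA at 199 permutations;
6 samples × 10 ASVs with 20 subsample replicates per group for the network
comparison), oracle equivalence covers all two-group designs to n = 8 and
random graphs to 8 nodes, and recovery experiments use 100 seeds per
quantity with 40-ASV single-timepoint scenarios. Ties in permutation
p-values are resolved by counting `F* ≥ F − 1e-12` to keep exact-enumeration
comparisons stable against floating-point noise. Reported percentages are
rounded half-up only in presentation tables.

## Known limitations

Two-way PERMANOVA offers only unrestricted raw-observation permutation (no
restricted/strata schemes) and no interaction term. The network comparison
treats subsample replicates as exchangeable draws per group; it does not
model tank nesting. SIMPER is two-group only. PCoA axes are reported for
positive eigenvalues without correction, so badly non-Euclidean matrices
under-represent total variation. The indicator-species permutation resolves
no finer than 1/(n_perm + 1), and tiny designs (3 vs 3) cannot reach
p < 0.05 at any permutation count.
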