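# Methods

## Network inference

Input is a samples × taxa biomass matrix for one class. Columns are
autoscaled (zero mean, unit SD with the n−1 convention; Pearson r is
scale-invariant, so the convention affects reported z-scores only).
Zero-variance taxa cannot be scaled and are excluded with a notice.

Edges are defined by a critical-|r| threshold rather than per-pair
p-values: r\* = t\*/√(df + t\*²) with df = n − 2 and t\* the two-sided
Student-t quantile at level α. For Pearson correlations of normal data the
two formulations are identical; the threshold form makes the rule explicit
and auditable (r\* is recorded on the network). Ties at the threshold are
included (the rule is "significant at P ≤ α", inclusive). No
multiple-testing correction is applied by default — the edge rule is a
per-pair significance statement, and the spurious-edge rate it implies
(≈ α among truly independent pairs) is verified by simulation in the
acceptance suite. Isolated nodes remain in the node set but are excluded
from n when computing density, centralization, clustering and path metrics
(switchable via `include_isolated`); with that policy the reachable-pair
coverage of a connected thresholded network is 100 %.

Path-based metrics default to unweighted hop counts, the convention of the
widely used NetworkAnalyzer tooling whose attribute set we mirror; a
weighted mode using |r| as additive edge length is available
(`path_metric_mode="weighted"`). Closeness is the reciprocal of the mean
distance to *reachable* nodes (0 for isolated nodes); betweenness is
normalised by (m−1)(m−2)/2 with m the node's component size, which equals
whole-graph normalisation for connected networks; local clustering is
defined as 0 for degree < 2 and included in the network mean.
Centralization is (n/(n−2))·(k_max/(n−1) − density) — 1 for a star, 0 for
vertex-transitive graphs. Heterogeneity is √(population variance of
degree)/mean degree. Degenerate inputs (edgeless or < 3 effective nodes)
yield NaN path metrics with `path_metrics_defined=False` instead of an
exception, so a failed class cannot abort a multi-class comparison.

All topology metrics are sign-blind by construction (they see |r| or hop
counts); the sign enters only edge bookkeeping and reporting.

## Synthetic communities

The generator is a latent-factor lognormal model. Each class has
`n_guilds` independent standard-normal factors per sample. Taxon j's
log-biomass is μ_j + a_j·F_g(j) + ε_js with ε ~ N(0, noise_sd²); guild
members load +`guild_loading`, antagonists −`antagonist_loading` on the
same factor; a `guild_coverage` fraction of taxa is assigned to factors at
all. Biomass is exp(log-biomass), rescaled so the mean per-sample total
equals `biomass_scale` (exact to floating tolerance). Any two taxa on a
common factor form a ground-truth pair with population log-scale
correlation a_i·a_j/√((a_i²+σ²)(a_j²+σ²)), signed by the loading product.

Parameter choices:

- `guild_loading = antagonist_loading = noise_sd = 0.35`: guild-mate
  log-correlation is then exactly 0.5 and total log-SD ≈ 0.5 (biomass
  CV ≈ 50 %, moderate overdispersion). Chosen once; the closed form makes
  0.5 the natural recovery target.
- `guild_coverage = 0.6`: ecological surveys typically record many taxa
  that take no detectable part in the correlation structure.
- Class presets CW (61 taxa, 2 guilds, antagonist fraction 0.5),
  MW (74, 4, 0.3), WW (89, 8, 0.1) encode the qualitative gradient from a
  cohesive, antagonist-balanced cold-winter community to a fragmented
  warm-winter one; biomass scales 28.25/0.730/0.094 mg l⁻¹ and the
  temperature parameters follow the study conditions.
- The `cw_like`/`ww_like` contrast presets (1 guild at loading 0.8 with
  balanced antagonists vs 12 guilds at loading 0.35) were designed by an
  a-priori power calculation on the lognormal-attenuated correlations so
  the expected ordering (higher clustering/centralization, shorter paths
  for the cohesive preset) has a wide margin.
- Scenario assembly shares a core taxon pool across classes sized so the
  core is ~26 % of the union (`shared_fraction`); per-class RNG streams
  are keyed by a stable hash of the class name, so results do not depend
  on class order.

Correlations in the pipeline act on the observed (exponentiated) scale,
where lognormality attenuates them below the log-scale closed form; the
recovery tolerances (recall ≥ 95 % at population ρ = 0.5, n = 84) absorb
this. What the generator does **not** emulate: temporal autocorrelation and
station-replicate structure of biomass, compositional effects, per-taxon
abundance-biomass distinctions, and by default any seasonal forcing of
taxon means (a per-taxon thermal-sensitivity hook exists, default off, so
that network tests are not confounded by shared seasonal trends). Passing
tests therefore demonstrate correctness of the machinery under the stated
statistical model, not field realism. Lognormal biomass is itself an
assumption — per-taxon distributions of such surveys are rarely reported.

Environmental tables: temperature is an annual cosine with its minimum at
the class's winter mean and amplitude fixed so the annual mean is matched,
plus N(0, winter SD) noise; sampling dates default to 28 months × 3
stations = 84 samples. Dissolved oxygen is drawn with a Gaussian coupling
of −0.555 to standardised temperature (rank correlation ≈ −0.5); the other
variables are independent normal draws from per-class mean/SD profiles,
truncated at zero where physically non-negative (everything except pH and
temperature). Within-class standardisation of temperature means DO carries
no between-class mean signal, only the physical within-class coupling.

## Diversity and group statistics

H′ = −Σ pᵢ log pᵢ over positive shares, natural log by default (the H′
range 1.6–2.3 for 61–89 taxa with strong dominance is consistent with
nats, the common limnological convention; base 2/10 available and recorded
in reports). J′ = H′/log S; undefined (NaN, flagged) for S < 2. Per-class
summaries compute H′/J′ per sample and report mean ± SD (the mode matching
mean-±-SD tables); class-pooled values can be obtained by calling the
functions on pooled vectors. Diversity in the pipeline uses biomass
shares, the matrix's only currency; the functions accept any nonnegative
vector, so abundance-based use is unchanged. Jaccard similarity is
expressed in percent on the observed (biomass > 0) taxon sets; two empty
sets are 100 % similar by convention, with a warning.

ANOVA + Tukey letters use the compact-letter-display construction via
maximal cliques of the non-significance graph, so groups share a letter
iff they belong to a common homogeneous subset. Kruskal–Wallis applies the
tie correction (biomass tables contain many zeros). A fully degenerate
input (all groups constant and equal) reports p = 1. Spearman correlations
mid-rank ties and flag constant inputs as undefined.

## Thermal discrimination

`rank_variables` fits a multiclass XGBoost on a stratified 2/3 train
split; importance is split frequency ("weight", the boosting F score) by
default, with "gain" as an option. The number of boosting rounds is chosen
by early stopping (patience 20, learning rate 0.1, depth 3, cap 500) on a
validation fold carved from the training split: rounds past signal
exhaustion only accumulate noise splits, which would pollute the
split-frequency ranking. Train/test accuracies and the split are recorded;
the mode is labelled stochastic and requires a seed. `anova_f` mode is the
deterministic oracle (per-variable one-way F).

The discrimination sanity check runs on classes that differ **only** in
their thermal regime (winter/annual temperature parameters; a shared
baseline profile for all other variables). This isolates the question the
check asks — does the ranking find the true discriminating axis? — from a
separate fact worth knowing: with fully class-specific profiles, the
transparency/suspended-solids variables have between/within ratios that
legitimately rival or exceed temperature's at the per-sample level, and no
marginal-signal method would rank temperature first under those
conditions. The package runs fine either way; the check's scope is the
thermal signal.

## Numerical conventions and limitations

- Correlation matrices are symmetrised ((R + Rᵀ)/2), clipped to [−1, 1],
  unit diagonal enforced.
- Reports serialise deterministically (sorted JSON keys, single-threaded
  XGBoost), so identical config + seed ⇒ byte-identical output.
- Problem sizes in the validation suite (500 oracle graphs of 4–7 nodes,
  10⁵ null draws, 200 recovery replicates, 50-run orderings, 1000 type-I
  replicates) were chosen as the smallest sizes at which the binomial/
  Monte-Carlo error of each check is well below its decision margin.
- Missing values are not supported in community matrices (surveys report
  zeros, not gaps); environmental tables may carry NaN, which XGBoost
  handles natively and the F oracle propagates.
- The per-pair complete-case refinement of the edge rule (per-pair r\*
  when pair-wise n differs) is unnecessary under the no-missing-data
  contract and is not implemented.
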