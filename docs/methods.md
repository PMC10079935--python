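# Methods

This note records the models, conventions and numerical choices behind
`ltsp-sig`, and what the synthetic-data tests do and do not establish
about real data.

## Signal model and preprocessing

The input is a genes × arrays matrix of model-extracted mRNA signal
estimates on a linear, pM-like scale. Such estimates are noisy around zero
and can be slightly negative, so preprocessing runs in a fixed order:

1. **Low-signal elimination** (linear scale): a gene is dropped when its
   mean over *all* arrays is below `low_signal_threshold` (default −1.5
   linear units). The global mean — rather than per-condition means — is
   used; filtering must precede the log transform because negative signal
   exists only pre-log.
2. **log10 transform**: values below `epsilon_floor` (default 0.01 linear
   units) are floored before taking log10. The floor keeps the map total
   and monotone; floored entries are counted and logged. Surviving genes
   after the −1.5 filter rarely trigger it.
3. **Per-array standardization** ("common statistics"): each array column
   is affinely rescaled to a target mean and sample sd on the log scale,
   defaulting to the pooled mean and pooled sd of all arrays before
   normalization. This is the minimal reading of "common statistics";
   quantile normalization (`method="quantile"`) is available for users who
   want distribution-identical arrays but is not the default.

Sample standard deviations use the n−1 denominator everywhere — replicate
counts are small (n = 3–5 per condition).

Per-gene centering (`center_genes`) supports the clustered-heatmap view;
`geneset_replicate_zscores` averages member genes per array and z-scores
the per-set vector across arrays (mean 0, sd 1 over replicates), the form
used for GO-level replicate summaries.

## Clustering and PCA

Hierarchical clustering is agglomerative **average linkage on Euclidean
distance**, for genes and for arrays; merge heights must be non-decreasing
(average linkage is monotone) and the implementation hard-errors
otherwise. Trees export to Newick with branch lengths equal to
merge-height differences.

PCA is **correlation-based**: every gene row is standardized (mean 0,
sd 1 across arrays) before the SVD of the arrays-by-genes data, which is
equivalent to an eigendecomposition of the array-by-array correlation
structure. Covariance-based PCA (`standardize_genes=False`) is behind a
flag. Variance fractions are σ²_k/Σσ² over the min(n_arrays − 1, n_genes)
non-trivial components. PCA signs are arbitrary, so each component is
flipped to make the lexicographically first array's score non-negative. A
gene's **factor loading** on a component is the Pearson correlation
between its profile and the component's score vector — bounded in [−1, 1]
and scale-free, unlike raw rotation weights.

## Loading screen and hypergeometric over-representation

"Highly contributing" genes for a component satisfy **both** a quantile
rule and a cutoff: loading rank within the top (or bottom)
⌈3% · N_genes⌉ — the ceiling guarantees at least one eligible gene in
small universes — **and** loading ≥ +0.8 (or ≤ −0.8). Ties at the rank
boundary break lexicographically by gene ID. Genes with undefined loading
(zero variance) leave both the numerator and the universe.

Over-representation of a gene set among screened genes uses the one-sided
upper-tail hypergeometric probability P(X ≥ k) with population
N = analyzed universe, successes K = |set ∩ universe|, draws n = screened
genes. Significance is raw p < 0.01 with no multiple-testing correction —
the screening convention this pipeline follows — with Benjamini–Hochberg
available behind a flag. Gene sets are size-filtered to 6–200 members
*after* intersection with the analyzed universe, since the statistic is
defined only over analyzed genes.

## GSEA

Genes are ranked by the difference of condition means of log-normalized
expression, Δ(g) = mean_A(g) − mean_B(g), descending, ties broken by gene
ID. For a set with K members in the N-gene ranking, the running sum gains
|Δ|^p / Σ_hits |Δ|^p at hits and loses 1/(N−K) at misses; ES is the signed
maximal deviation. When the positive and negative extremes of the running
sum tie in magnitude (possible with rational step sizes), the sign is
resolved positive — the tie is detected at 1e-12 so floating-point noise
cannot flip it. `weight_p` defaults to 1, the canonical weighting; at
p = 0, |ES| is exactly the two-sample KS statistic between hit and miss
positions (a property the tests exploit as an independent oracle). If all
hit metrics are zero at p > 0, hit increments fall back to uniform 1/K
with a warning.

**Null model.** The default null draws, for each distinct set size K,
`n_permutations` random K-gene subsets of the ranked universe
(gene-sampling null). Same-size sets share one null sample — statistically
identical under this null and much cheaper, which is what makes
1,000-set × 1,000-permutation calibration runs take seconds. Phenotype
(label) permutation is available via `scheme="phenotype"`, but with n = 3
replicates in one condition there are at most C(8,3) = 56 distinct splits,
too few for a stable FDR — hence it is not the default.

**Scoring.** NES = ES / mean(|null ES| of matching sign), computed per
size group. Nominal p is add-one smoothed, (b+1)/(m+1), over same-sign
null ES at least as extreme, so p is never 0. The FDR q-value is the
classical pooled-null ratio: for NES* ≥ 0, q = [fraction of pooled null
NES ≥ NES*] / [fraction of observed NES ≥ NES*], capped at 1, computed
symmetrically for negative NES, then monotonized within each sign
(step-up: each set takes the minimum q among itself and all less-extreme
sets), so a more extreme |NES| never carries a larger q. All randomness
flows from one integer seed.

## Stress/growth balance

Per array, AVR_RS and AVR_MBS are arithmetic means of the **linear**
signal over the stress-response and biosynthesis set members; the
statistic is log10(AVR_RS/AVR_MBS). Averaging on the linear scale is
deliberate: averaging logged values instead would produce a geometric
mean (that variant exists via `on_log_scale=True`). Since the pipeline
carries a normalized log matrix at this stage, the default route is
back-transforming it (`to_linear`) before averaging. The ratio is
invariant to any common rescaling of the matrix. Condition means of the
per-array ratios are compared all-pairs with Tukey's HSD on a one-way
layout, each array one observation.

## CFU kinetics

For counts N_i at times t_i (hours), the per-interval rate is
μ_i = |log(N_{i+1}/N_i)/(t_{i+1}−t_i)|. Natural log is the default — μ is
an exponential-phase rate — and the base is configurable since it only
rescales μ. A window (first, last) of timepoint indices averages
μ_first..μ_{last−1}; the defaults are growth = (0, 3) and death = (3, 5),
matching a six-timepoint sampling design, but windows are always explicit
inputs, never hard-coded times. Intervals touching a zero count have
undefined μ and are excluded from window means with a warning.
Replicate-level μ values (not pooled counts) feed Dunnett's many-to-one
test against the control strain; the multivariate-t tail integration in
the test is randomized quadrature, so the implementation fixes its
internal quadrature seed for reproducibility (p-values are stable to
~1e-4).

## Synthetic data: what it emulates, and what it does not

`simulate_expression` draws per-gene baselines b_g ~
N(baseline_log10_mean, baseline_log10_sd) (defaults 1.0 ± 0.6, i.e.
signals around 10 pM), adds planted condition-specific log10 shifts
δ_{g,c} for chosen sets, and i.i.d. replicate noise ε ~ N(0,
noise_log10_sd) (default 0.2); the matrix is returned on the linear scale
(10^x). The design defaults to the three-group layout LL:5, STS:3,
LTSsn:5. An optional low-signal fraction draws linear values from
N(−3, 0.5) — near zero, occasionally negative — so the elimination filter
has realistic prey. `simulate_cfu` produces piecewise-exponential
N(t) with mean-one multiplicative log-normal count noise of configurable
CV (mean-one, so log-ratios carry only a −σ²/2-order bias).

The generator does **not** emulate probe-level hybridization,
between-array batch effects, correlated gene-gene noise, or
dilution-plating count error beyond log-normal noise. Passing
planted-recovery tests therefore demonstrates that the statistics recover
known structure under the stated noise model at the study's design scale —
not that any particular biological dataset will behave likewise.

## Problem sizes and numerical conventions

Planted-recovery and calibration checks run at 1,000–2,000 genes ×
13 arrays with 1,000 permutations over 20 simulation seeds, and a full
pipeline exercise at ~3,700 genes — the scale of the motivating study
design. Exact oracles (hypergeometric enumeration, running-sum walk,
eigendecomposition) are held to 1e-8–1e-12; permutation-based quantities
to binomial-error bands (3 SE) or ≥ 18/20-seed recovery. Ties everywhere
break lexicographically by gene or set ID; all stochastic stages take an
explicit integer seed and are bit-reproducible given it.

## Known limitations

- The gene-sampling GSEA null ignores inter-gene correlation, which can
  make q-values anti-conservative on strongly co-regulated sets;
  phenotype permutation avoids this but needs more replicates than the
  3-replicate design provides.
- The affine "common statistics" normalization assumes arrays differ by
  location/scale only; gross distributional differences call for the
  quantile option.
- Hypergeometric screening treats gene sets as independent; overlapping
  GO terms yield correlated p-values and no redundancy collapsing is
  attempted.
- The balance statistic depends on annotation completeness of the two GO
  categories; it is a descriptive contrast, not a mechanistic
  growth-law fit.
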