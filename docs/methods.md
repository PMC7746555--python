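# Methods

`covnet` implements a group-level structural covariance network (SCN)
analysis of regional cortical thickness: two groups of subjects each yield
one binary brain graph per connection density, graph parameters are
compared between groups across a density range, and inference uses
subject-label permutation with area-under-the-curve (AUC) summaries.

## Model and pipeline

**Input.** A subjects × regions table: group label, age, sex, and mean
cortical thickness (mm) for each of 68 Desikan–Killiany regions (any
parcellation list works; 68 is the default).

**Corrected thickness.** For each region, ordinary least squares removes
the effects of age, sex (coded 0/1) and the subject's global mean
thickness (the unweighted mean of the regional values):

    thickness ~ 1 + age + sex + global_mean

Residuals ("corrected thickness") are what enter correlation.
Residualization is fitted per group by default (matching group-wise
network construction); a pooled fit is available via `scope="pooled"`.
Under permutation, per-group residualization is re-fit inside each
pseudo-group, so the null faithfully replays the whole pipeline.

Two degenerate-design rules keep the operation total and idempotent: the
*derived* global-mean column is dropped (with a log line) when it is
constant — exactly the situation when the input is already residualized —
or when it is an exact linear combination of the covariates; constant or
collinear *user* covariates are an error naming the column.

**Correlation and thresholding.** Per group, the 68 × 68 Pearson
correlation matrix of corrected thickness across subjects is binarized at
a target density D by keeping the E = round(D·N(N−1)/2) strongest
*positive* correlations as edges (negative correlations are never edges;
the diagonal is zero). Ties at the cut rank break by higher r, then
lexicographic region pair, so binarization is deterministic. Analysing
fixed densities rather than a fixed correlation threshold equalizes edge
count between the groups at every point of the comparison.

**Density range.** `select_density_range` reproduces the data-driven
rule: the lower limit is the smallest probed density at which both
groups' networks are connected (one component spanning all regions); the
upper limit is the largest at which both have small-world index
sigma > 1.2 (computed with the same seeded random-ensemble settings as
the metrics, so the selection is reproducible). The default analysis
range is 0.15–0.40 in steps of 0.01.

**Graph parameters.** On each binary network: clustering coefficient
(Cp), characteristic path length (Lp, averaged over connected pairs
only), global and local efficiency, transitivity, Newman modularity Q,
and nodal degree / clustering / betweenness (each also divided by its
network-wide mean before group comparison). gamma = Cp/⟨Cp_rand⟩,
lambda = Lp/⟨Lp_rand⟩ and sigma = gamma/lambda are normalized against an
ensemble of degree-preserving (Maslov–Sneppen edge-swap) randomized
networks. Hubs are nodes with betweenness ≥ mean + 1.5 population SD.

**Inference.** For each metric, group values are computed at each grid
density and summarized by the trapezoidal AUC over the range. The null
distribution comes from reassigning subjects to pseudo-groups of the
original sizes (default 1,000 repetitions) and re-running the full
per-group pipeline. Two-sided p-values use the add-one rule
p = (b + 1)/(m + 1) over non-missing repetitions, which never reports 0;
95% null bands are the 2.5/97.5 percentiles per density. Per-region
nodal p-values are reported uncorrected by default, with optional
Benjamini–Hochberg adjustment clearly labelled.

## Synthetic cohorts

The generator emulates the data the pipeline assumes:

    thickness = 2.5 mm + beta_age·age + beta_sex·sex + noise_sd·z

with age ~ Uniform(30, 68) years (the study population's age span),
sex ~ Bernoulli(0.5), beta_age = −0.005 mm/yr (typical adult cortical
thinning), beta_sex = 0.05 mm, noise_sd = 0.12 mm, and z a
multivariate-normal draw whose correlation follows a planted-partition
block matrix: `within_block_r` inside each of `n_blocks` blocks (default
4), `between_block_r` across blocks, settable per group. Default group
sizes are 67 and 88. Implied correlation matrices are checked for
positive semi-definiteness: violations below |min eig| ≤ 0.05 are
repaired by eigenvalue clipping with a warning; worse ones are rejected
with a diagnostic naming the offending parameters. Explicit per-group
correlation matrices (`correlation_override`) support planted designs.

**What it does not emulate:** spatial autocorrelation on the cortical
sheet, hemispheric symmetry, region-specific variance profiles,
measurement artefacts, or site effects. Passing tests therefore show the
*machinery* is correct and calibrated under a known covariance model, not
that any particular clinical contrast will reproduce.

**A structural constraint worth knowing.** Because the global mean
thickness is a regressor, each region's residual covariances sum to
exactly zero, so somewhat fewer than half of all interregional residual
correlations can be positive — and the stronger the block structure, the
more negative the between-block correlations become. Two consequences
shape defaults and experiments:

* generator defaults use modest correlations (within 0.25, between 0.10)
  so that the conventional density range up to 0.40 remains feasible
  under the positive-threshold rule;
* a high-contrast design (e.g. within 0.6) cannot fill densities near
  0.40 with positive correlations, so experiments on such designs use a
  range their networks actually support — the same data-driven logic as
  the range-selection rule.

## Validation experiments (`covnet.experiments`)

* **Type-I calibration** (`calibration_experiment`): 200 null cohorts
  (both groups from the default spec, 30/30 subjects), 200 permutations,
  grid 0.15–0.40 step 0.05; the empirical rejection rate at alpha = 0.05
  should be ~0.05 for Cp, Lp and Q AUC differences. Validity follows
  from exchangeability; the experiment checks the implementation.
* **Effect recovery** (`effect_recovery_experiment`): within-block
  correlation 0.6 vs 0.4 (8 blocks, between 0.1, 60/60), grid 0.10–0.25
  step 0.05, where the contrast is expressed — just above per-block edge
  saturation. Success = positive observed AUC difference with p < 0.05
  for clustering and modularity.
* **Hub recovery** (`hub_recovery_experiment`): group 1's correlation is
  a factor model in which one region loads on two of four block factors
  (strength 0.7), making it the near-exclusive inter-block path after
  thresholding; success = that region is a betweenness hub in the
  affected group only, at the hub density (0.15). A naive "bridge row"
  correlation matrix is not used because (a) it is grossly non-PSD and
  (b) with only two blocks the global-mean correction makes the blocks
  anti-correlated, erasing any bridge.

## Numerical and design choices

* **Shortest paths** use breadth-first search via boolean matrix
  products — the fastest exact option at N ≈ 68 — and agree with
  Floyd–Warshall enumeration on all small-graph suites. Disconnected
  pairs are excluded from Lp (keeping it finite for fragmented permuted
  networks) and contribute 0 to efficiency.
* **Modularity** is optimized by seeded Leiden runs (igraph); the
  `restarts` parameter takes the best of several seeded runs, but the
  default is a single run: it is deterministic, near-optimal at this
  graph size, and restarts multiply the cost of every permutation
  repetition. igraph draws randomness from Python's `random` module, so
  runs are seeded explicitly before each call.
* **Betweenness** uses fractional credit among equal-length shortest
  paths (igraph), each unordered pair counted once. Hub detection uses
  the population SD and an inclusive ≥ threshold; an SD of zero (all
  nodes equal) yields no hubs, since a hub must stand out.
* **Random ensembles** default to 100 members with 10 attempted swaps
  per edge and a 20× attempt budget; members whose rewiring finds no
  admissible swap (rigid graphs such as K3) are kept unchanged with a
  warning. Degree sequences are preserved exactly.
* **Nodes with degree < 2** score 0 for nodal clustering and local
  efficiency (standard toolbox convention).
* **Permutation sub-seeds** derive from (seed, repetition), so results
  are independent of execution order and the whole run is reproducible
  bit-for-bit; every output table is written deterministically (no
  timestamps), and a run's manifest records settings, seeds and the
  input checksum.
* **Problem sizes.** Simulation studies in the test suite and the
  acceptance script run at reduced sizes chosen to keep a desk-scale run
  practical (e.g. 200 permutations instead of 1,000, density step 0.05
  instead of 0.01, 50–200 simulated cohorts); each experiment's size is
  stated where it runs. The per-repetition cost is dominated by Leiden
  modularity and BFS, ~10 ms per permutation for a 68-region cohort.

## Known limitations

* Group-level networks mean there is no per-subject graph, so no
  correlation of network metrics with individual covariates.
* Binary undirected graphs only; no weighted or signed variants.
* The sigma-based range rule inherits the known instability of sigma on
  dense graphs (gamma and lambda both approach 1); the default range
  caps density at 0.40 partly for this reason.
* The permutation engine recomputes everything per repetition; at the
  published settings (1,000 repetitions, 26 densities) a run takes a few
  minutes on one core, scaling linearly in both.
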