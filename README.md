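# covnet

Structural covariance network analysis of regional cortical thickness.

Gray-matter structural covariance treats the correlation of a
morphometric measure (here, mean cortical thickness) between pairs of
brain regions, computed **across subjects within a group**, as a proxy
for shared trophic / developmental influence between those regions.
`covnet` turns a subjects × regions thickness table into group-level
binary brain graphs and tests whether two groups (e.g. patients vs
controls) differ in their network topology. It is a library first
(importable API + `examples/`), with a thin `covnet` command-line
front-end for shell use.

## The method

For each group:

1. **Correct** each region's thickness by OLS on age, sex and the
   subject's global mean thickness; residuals are the "corrected
   thickness".
2. **Correlate**: Pearson r across subjects for every region pair → an
   N × N matrix R (N = 68 Desikan–Killiany regions by default).
3. **Binarize** at a connection density D: keep the
   E = round(D·N(N−1)/2) strongest *positive* correlations as edges of an
   undirected, unweighted graph G(N, E).

On each graph, across a density range (default 0.15 ≤ D ≤ 0.40):
clustering coefficient Cp, characteristic path length Lp, global and
local efficiency, transitivity, modularity Q, and nodal
degree/clustering/betweenness. Small-world indices normalize against
degree-matched randomized networks:

    gamma = Cp / <Cp_rand>,  lambda = Lp / <Lp_rand>,  sigma = gamma / lambda

with sigma > 1 indicating small-world organization. Hubs are regions
whose betweenness exceeds the network mean by ≥ 1.5 SD.

**Inference**: each metric's curve over the density range is summarized
by its trapezoidal AUC; significance of the group difference comes from
non-parametric label permutation (default 1,000 repetitions) that reruns
the entire per-group pipeline per repetition, with two-sided add-one
p-values and 95% null bands per density.

Because no subject-level data ships with a group-level method, the
package includes a first-class synthetic cohort generator
(`SyntheticSpec` / `generate_cohort`) with block-structured, per-group
controllable covariance — every downstream stage is testable, and
planted-effect experiments have ground truth.

## Worked example

Two synthetic groups (60/60 subjects) whose only difference is stronger
within-block correlation in group 1 (0.6 vs 0.4 across 8 blocks) — a
planted increase in network segregation:

```python
from covnet import (ComparisonSettings, DensityRange, SyntheticSpec,
                    generate_cohort, permute_groups)

spec = SyntheticSpec(group_sizes=(60, 60), n_blocks=8,
                     within_block_r=(0.6, 0.4), between_block_r=0.1, seed=11)
cohort = generate_cohort(spec)
results = permute_groups(
    cohort, DensityRange(0.10, 0.25, 0.05),
    ComparisonSettings(global_metrics=("clustering_coefficient",
                                       "characteristic_path_length",
                                       "global_efficiency", "modularity")),
    n_perm=200, seed=1)
for m, r in results.items():
    print(f"{m:28s} {r.observed_auc:+.4f}  p={r.p_auc:.4f}")
```

prints

```
clustering_coefficient       +0.0270  p=0.0050
characteristic_path_length   -0.0038  p=0.9453
global_efficiency            -0.0104  p=0.0050
modularity                   +0.0178  p=0.0050
```

The planted segregation shows up exactly where it should: clustering and
modularity AUCs are significantly higher in group 1, global efficiency is
significantly lower (tighter modules integrate less), and path length —
not directly manipulated — stays null. Each `p` is the position of the
observed AUC difference in its 200-repetition permutation null
(add-one rule, so the smallest attainable value is 1/201 ≈ 0.005).

More narrative walkthroughs live in `examples/`: cohort simulation,
network construction, small-world profiles, group comparison, and hub
analysis. The same pipeline runs from the shell:

```bash
covnet simulate --seed 7 --out cohort.csv
covnet compare --config run.yaml --permutations 1000 --seed 42
covnet report --run-dir out/
```

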