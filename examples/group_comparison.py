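"""Permutation test of group differences with AUC summaries.

Group 1 is generated with stronger within-block correlation (0.6 vs 0.4),
i.e. more segregated covariance.  The test reassigns subjects to
pseudo-groups 200 times, reruns the whole per-group pipeline each time,
and locates the observed AUC difference in the null distribution.
"""
from covnet import (
    ComparisonSettings,
    DensityRange,
    SyntheticSpec,
    generate_cohort,
    permute_groups,
)

spec = SyntheticSpec(
    group_sizes=(60, 60),
    n_blocks=8,
    within_block_r=(0.6, 0.4),
    between_block_r=0.1,
    seed=11,
)
cohort = generate_cohort(spec)
grid = DensityRange(0.10, 0.25, 0.05)
settings = ComparisonSettings(
    global_metrics=("clustering_coefficient", "characteristic_path_length",
                    "global_efficiency", "modularity")
)
results = permute_groups(cohort, grid, settings, n_perm=200, seed=1)

print("metric                         AUC diff (g1-g2)      p")
for m, r in results.items():
    star = " *" if r.p_auc < 0.05 else ""
    print(f"  {m:28s} {r.observed_auc:+.4f}         {r.p_auc:.4f}{star}")

print(
    "\nPositive, significant clustering/modularity differences recover the "
    "planted segregation increase, and global efficiency drops with it — "
    "tighter modules integrate less."
)
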