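"""From a thickness table to a binary structural covariance network.

Residualize age, sex and global mean thickness per group, correlate the
corrected thickness across subjects, and keep the strongest positive
correlations up to a target connection density.
"""
from covnet import SyntheticSpec, generate_cohort, correlation_matrix, threshold_at_density
from covnet import metrics as gm
from covnet.preprocess import residualize

spec = SyntheticSpec(group_sizes=(67, 88), seed=7)
cohort = generate_cohort(spec)
resid = residualize(cohort, spec.region_names, scope="per-group")

for group in ("patient", "control"):
    corr = correlation_matrix(resid.loc[resid["group"] == group, spec.region_names])
    net = threshold_at_density(corr, 0.15)
    vals = gm.global_metrics(
        net,
        which=(
            "clustering_coefficient",
            "characteristic_path_length",
            "global_efficiency",
            "transitivity",
            "modularity",
        ),
        seed=0,
    )
    print(f"[{group}] density 0.15 -> {net.n_edges} edges "
          f"(= round(0.15 x {68 * 67 // 2}))")
    for name, v in vals.items():
        print(f"    {name:27s} {v:.4f}")

print(
    "\nCp near ~0.5 with Lp ~2 reflects the modular generator: many "
    "within-block triangles, short paths through shared blocks."
)
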