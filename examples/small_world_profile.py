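"""Small-world indices across the density range.

gamma = Cp / <Cp_random>, lambda = Lp / <Lp_random> against degree-matched
(edge-swap randomized) networks; sigma = gamma / lambda > 1 indicates
small-world organization (more clustered than random at comparable path
length).
"""
from covnet import (
    ComparisonSettings,
    DensityRange,
    SyntheticSpec,
    generate_cohort,
    metric_curves,
)

spec = SyntheticSpec(group_sizes=(67, 88), seed=7)
cohort = generate_cohort(spec)
grid = DensityRange(0.15, 0.40, 0.05)
curves = metric_curves(
    cohort,
    grid,
    ComparisonSettings(global_metrics=("gamma", "lambda", "sigma"), n_random=50),
)

print("density   gamma(pat/ctl)   lambda(pat/ctl)   sigma(pat/ctl)")
for i, d in enumerate(grid.grid):
    row = [curves[m].values[g][i] for m in ("gamma", "lambda", "sigma")
           for g in ("patient", "control")]
    print(f"  {d:.2f}    {row[0]:.2f} / {row[1]:.2f}      "
          f"{row[2]:.2f} / {row[3]:.2f}       {row[4]:.2f} / {row[5]:.2f}")

print(
    "\nsigma > 1 throughout: the block-structured covariance yields "
    "small-world networks, strongest at sparse densities."
)
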