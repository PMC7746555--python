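"""Generate a synthetic two-group cortical-thickness cohort.

The generator draws per-subject regional thickness as baseline + linear
age/sex effects + a multivariate-normal residual whose region-region
correlation follows a planted-partition (block) structure.  The printed
summary shows the table layout the rest of the pipeline consumes.
"""
import numpy as np

from covnet import SyntheticSpec, generate_cohort

spec = SyntheticSpec(group_sizes=(67, 88), seed=7)
cohort = generate_cohort(spec)

print(f"subjects: {len(cohort)}  columns: {cohort.shape[1]}")
print(cohort.groupby("group")[["age"]].agg(["mean", "min", "max"]).round(1))
print("\nfirst regions of the first patients:")
print(cohort.iloc[:3, :7].round(3).to_string(index=False))

thick = cohort[spec.region_names].to_numpy()
print(
    f"\nmean thickness {thick.mean():.3f} mm (SD {thick.std():.3f}) — "
    "values in the plausible range for adult cortex"
)
print(
    "identical spec + seed reproduces this table bit-for-bit: "
    f"{generate_cohort(spec).equals(cohort)}"
)
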