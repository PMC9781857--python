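"""Simulate a full factorial cohort and recover its group structure.

Generates one synthetic cohort (feeding AL/CR x injury sham/TBI, cell sizes
3/6/6/5) with default truth and noise, runs the complete estimation path
(standard-curve fit, body-water back-calculation, per-injection ratios,
fGNG), and prints the post-intervention group summary with the two-way
Type III ANOVA.
"""

from fgng.pipeline import PipelineOptions, estimate_frames, group_summary, run_group_stats
from fgng.simulate import SimulationConfig, simulate_cohort

bundle = simulate_cohort(SimulationConfig(seed=1))
results, curve = estimate_frames(
    bundle.design, bundle.intensities, bundle.bodywater, bundle.standard_curve,
    PipelineOptions(),
)

print(f"standard curve: slope={curve.slope:.4f} intercept={curve.intercept:.2e} "
      f"r^2={curve.r_squared:.5f}\n")

summary = group_summary(results)
summary["mean_%"] = (100 * summary["mean_fgng"]).round(2)
summary["sd_%"] = (100 * summary["sd_fgng"]).round(2)
print(summary[["timepoint", "feeding", "injury", "n", "mean_%", "sd_%"]].to_string(index=False))

stats = run_group_stats(results)
print("\npost-intervention ANOVA (Type III):")
print(stats["anova"].to_string(index=False))
# Caloric restriction roughly doubles fGNG (feeding p << 0.05); the brain
# injury itself leaves it unchanged (injury and interaction p > 0.05).
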