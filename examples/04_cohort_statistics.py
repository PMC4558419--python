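"""Generate a six-group cohort, measure it, and run the group statistics.

The default design encodes the qualitative biology: carcinoma groups
(G2-G5) get more elongated dots with smoother boundaries; benign groups
(BNH, AAH) rounder, more rugged dots.  ANOVA with Tukey HSD then asks
whether the measured silhouette FD and roundness separate pooled
carcinoma from the benign entities.
"""

from agnorfract import default_group_specs, generate_cohort, measure_cohort, run_statistics
from agnorfract.experiments import small_frame_overrides
from agnorfract.pipeline import MeasureOptions

specs = default_group_specs(**small_frame_overrides())
cohort = generate_cohort(specs, images_per_group=10, seed=42)
image_df, object_df = measure_cohort(cohort, options=MeasureOptions(compute_skeleton_fd=False))

print(image_df.groupby("group")[["mean_object_fd", "mean_roundness", "dot_count"]].mean().round(3))

report = run_statistics(image_df, metrics=("mean_object_fd", "mean_roundness"), alpha=0.01)
for metric in ("mean_object_fd", "mean_roundness"):
    pooled = report["metrics"][metric]["pooled_carcinoma"]
    a = pooled["anova"]
    print(f"\n{metric}: F({a['df_between']},{a['df_within']}) = {a['f_stat']:.2f}, "
          f"P = {a['p_value']:.2g}  (pooled carcinoma vs AAH vs BNH)")
    for pair in pooled["tukey"]:
        print(f"  {pair['group_a']:>9} vs {pair['group_b']:<9} diff {pair['mean_diff']:+.3f} "
              f"p_adj {pair['p_adj']:.2g} {'*' if pair['significant'] else ''}")
print("\n-> a negative carcinoma-vs-benign FD difference with small adjusted p "
      "recovers the designed smoother-boundary contrast.")
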