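"""Why narrowing the FD frequency analysis to [1.05, 1.09] gains sensitivity.

Silhouette-FD distributions concentrate in a narrow band just above 1;
group differences inside that band are diluted when heavy out-of-band
values enter a full-range comparison.  Restricting the ANOVA to the
closed interval [1.05, 1.09] is a pure inclusive subset filter — and on
data designed with separation inside the band it recovers what the
full-range test misses.
"""

from agnorfract.experiments import narrow_interval_experiment

res = narrow_interval_experiment(seed=0, n_per_group=50, noise_per_group=150)
full, narrowed = res["full_anova"], res["narrowed_anova"]
print(f"full range : F({full.df_between},{full.df_within}) = {full.f_stat:.2f}, P = {full.p_value:.3f}")
print(f"narrowed   : F({narrowed.df_between},{narrowed.df_within}) = {narrowed.f_stat:.2f}, P = {narrowed.p_value:.2g}")
print("-> identical group cores; only the narrowed comparison resolves them.")

for name, hist in list(res["histograms"].items())[:2]:
    inside = hist.counts[(hist.bin_edges[:-1] >= 1.05) & (hist.bin_edges[:-1] < 1.09)].sum()
    print(f"{name}: {inside} of {hist.counts.sum()} FDs inside the narrow interval")
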