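"""Monte Carlo behaviour of the measures under a no-structure null.

Bearers are repeatedly reallocated across regions proportionally to region
population, with surname sizes on a fixed grid; each replicate records the
correlation between surname size and mean pairwise value for both measures.
This is how one checks that a relatedness measure is not just an artifact of
surname population size.
"""

from surnamespace import size_sensitivity_experiment

report = size_sensitivity_experiment(
    n_surnames=200, n_regions=50, replicates=25, seed=0
)

print("mean |Spearman size-value correlation| per measure:")
for measure, value in report.mean_abs_corr.items():
    print(f"  {measure:8s} {value:.3f}")
print("Dice less size-sensitive in a majority of replicates:", report.dice_less_size_sensitive())
print("Dice more stable across replicates (per-stratum CV):", report.dice_more_stable())
print("\nbetween-replicate coefficient of variation by size stratum:")
print(report.dispersion.pivot(index="stratum", columns="measure", values="cv").round(4))

# Under the null both measures retain a residual size dependence, but the
# symmetric Dice measure shows the weaker correlation and the smaller
# replicate-to-replicate fluctuations — the reason it is the default measure.
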