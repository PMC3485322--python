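"""Planted-community recovery: can network components find known structure?

A synthetic population plants 5 communities of surnames, each enriched by a
factor gamma in its own block of regions, plus 20% spatially ubiquitous
background names.  Building the Dice network over a grid of thresholds and
comparing connected components with the planted labels (adjusted Rand index)
validates the core premise: co-concentration recovers relatedness.
"""

from surnamespace import SyntheticSpec, recovery_experiment

spec = SyntheticSpec(
    n_regions=40,
    n_surnames=500,
    n_communities=5,
    gamma=50.0,
    background_fraction=0.2,
    seed=1,
)
scores = recovery_experiment(spec)
print(scores.to_string(index=False))
best = scores.loc[scores["ari"].idxmax()]
print(f"\nbest recovery: ARI={best['ari']:.3f} at threshold d={best['threshold']:.1f}")

# Low thresholds merge everything into one component (ARI near 0); very high
# thresholds shatter the network; at intermediate thresholds the components
# coincide with the planted communities almost perfectly.
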