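# Methods

## Model and assumptions

The package treats a surname's geography as a binary signature: the set of
regions where its location quotient exceeds 1 (its *concentration set*).
The LQ is used instead of raw counts because surname subpopulation sizes
span four orders of magnitude; dividing a surname's regional share by its
national share puts every name on the same footing. Binarizing at LQ > 1
(strict inequality; a value exactly 1 means the name is distributed exactly
like the population and is *not* counted as concentrated) deliberately
discards the magnitude of over-representation: the working assumption is
that *where* a name concentrates carries the relatedness signal, not *how
strongly*. No smoothing or shrinkage is applied to the LQ for small counts;
the minimum-bearer filter is the safeguard against small-number noise.

Pairwise relatedness is the overlap of two concentration sets, either
Jaccard J = |A∩B|/|A∪B| or the symmetric Dice measure
D = min(|A∩B|/|B|, |A∩B|/|A|) = |A∩B|/max(|A|,|B|), read as the smaller of
the two conditional co-concentration probabilities. D ≥ J always; both
reach 1 only for identical non-empty sets. The default measure is D, on the
strength of the null-model experiments below.

Reference totals for the LQ are computed over the analysis table as given,
i.e. after filtering — the only population the toolkit can see. Where
register-wide shares are wanted instead, callers can pre-aggregate
externally; the manifest records which table produced the quotients.

## Filtering and the two-stage design

Standard preprocessing for a Czech-style register: feminine suffix
filtering (surnames ending in "-á" are near-duplicates of the male form
with essentially identical geography; the filter is purely orthographic and
accepts the rare exceptions as noise, since the LQ normalization makes them
immaterial), a minimum country-wide bearer count (default 50, i.e. "more
than 49") to suppress chance co-occurrence of rare names, and exclusion of
the largest units at the fine stage, where big-city mixing produces random
co-occurrence.

The full pairwise computation at fine resolution is quadratic in surnames
and noisy in tiny units, so the pipeline first runs on coarse aggregated
regions, selects *candidates* — the surnames incident to the strongest
links (default: links at ≥ 60% of the maximum observed value; threshold,
top-K and target-count rules are also available, the latter searching the
threshold to approach a requested candidate count with ties always
included) — and then recomputes everything for the candidates at fine
resolution with an absolute link threshold (default D ≥ 0.23). Stage-2 LQ
totals are recomputed over the candidate table (self-contained default);
the manifest records the convention that ran. Link thresholds compare with
≥ throughout.

Pair accounting is canonically unordered (n(n−1)/2); the ordered count is
exposed via `pair_count(..., ordered=True)` for comparison with sources
that quote ordered totals.

## Numerical and representation choices

Concentration and proximity matrices are sparse; an absent entry is an
exact zero. Intersection counts come from a boolean sparse matrix product
evaluated in surname blocks (default 2048 rows) so peak memory is bounded;
results are bit-identical for any block size, which the tests check against
a naive per-pair set-algebra oracle. Zero-valued pairs are never stored.
All values are exact ratios of small integers in double precision, so
equality comparisons in tests are exact.

Tie-breaks are deterministic and data-driven: max-LQ attribution breaks
ties by larger bearer count then lexicographic region id; hub rankings and
nearest-neighbour lists break degree/value ties lexicographically;
top-K link selection includes all values tied at the cut (K may be
exceeded, logged). Components are reported largest first, ties by smallest
member label. Degenerate inputs fail loudly: empty tables, empty
concentration sets in the scalar conditional measure, empty graphs for
statistics, single-stratum correlation — each raises or flags rather than
returning a silent default. In matrix form an undefined conditional is
reported as an unstored 0 (sparsity), while the scalar op raises
(correctness); the asymmetry is intentional.

Network statistics are reported at the conventional precision c to 1
decimal and ρ to 3 decimals. Isolated nodes are excluded from built
networks unless explicitly requested, matching the convention that only
linked surnames are drawn.

## Synthetic data generator

`SyntheticSpec`/`generate_population` emulate the structural features of a
register that drive the method, not any particular country's marginals:

* **surname sizes**: discrete power law P(k) ∝ k^−a on
  [min_bearers, max_bearers], default a = 1.7 on [50, 5000] — heavy
  right-skew with the analysis floor of 50 bearers as the lower support;
* **region populations**: log-normal (median 20 000, σ = 0.5), matching the
  roughly log-normal unevenness of real administrative units;
* **planted communities**: regions partitioned into C contiguous blocks;
  each structured surname's bearers are allocated multinomially with
  probability ∝ region population × γ inside its home block (γ ≥ 1);
* **background fraction** (default 0.2): spatially ubiquitous surnames with
  no home block, emulating names whose meaning is independent of regional
  naming practice.

γ = 1 everywhere is the no-structure null. The generator conserves drawn
surname totals exactly and is bit-reproducible given the seed. What the
generator does *not* emulate: spatial autocorrelation between neighbouring
blocks, migration gradients, multi-scale nesting of real administrative
geographies, and orthographic relationships between names. Passing tests
on synthetic data therefore validate the machinery and the core
co-concentration-implies-relatedness premise under clean conditions; they
do not certify recovery rates on real registers.

`null_model` reallocates an observed table's bearers multinomially with
probabilities ∝ observed region totals, conserving each surname's total
exactly (region totals in expectation).

## Monte Carlo experiments

**Size sensitivity.** The published account of the index-behaviour
simulations is summary-level only, so the design here is the package's own:
a fixed region universe (default 50 log-normal regions), surname sizes on a
fixed grid of strata (default 25 names in each of 8 strata from 50 to
6400), multinomial reallocation with no spatial structure each replicate,
and both measures computed per replicate (default 100). Two statistics are
the test surface: (a) the per-replicate |Spearman ρ| between a surname's
size and its mean pairwise value — Dice should show the weaker dependence
in a majority of replicates; (b) the between-replicate coefficient of
variation of per-stratum mean values — CV is scale-free, so the two
measures are comparable despite J ≤ D; Dice should have the smaller CV in a
majority of strata. Only these qualitative orderings are asserted, never
specific magnitudes.

**Community recovery.** A planted population (default 5 communities, 40
regions, 500 surnames, γ = 50, 20% background) is run through the full
chain; connected components of the Dice network at each threshold on a grid
are scored against the planted labels with the adjusted Rand index,
restricted to non-background surnames (background names carry no signal by
design; surnames absent from the network count as their own singletons).
ARI is used because it is the standard chance-corrected partition score and
is permutation-invariant. The whole grid is reported rather than one
auto-chosen threshold: the low end under-segments (one giant component,
ARI ≈ 0), the high end shatters the network, and recovery peaks in between.

## Problem sizes and determinism

Tests and the acceptance script run the experiments at the default sizes
above (200 × 50 × 100 replicates for size sensitivity; 500 × 40 for
recovery), which complete in seconds while leaving the qualitative outcomes
far from their decision boundaries. A single integer seed governs every
stochastic component; the analysis pipeline itself is deterministic, writes
byte-stable sorted outputs, and records per-stage counts, derived
thresholds and output checksums in its manifest.

## Known limitations

* Suffix-based feminine filtering is orthographic; regionally specific
  exceptions pass through (harmless under LQ normalization, but they do
  inflate the surname universe slightly).
* Binarization at LQ > 1 ignores concentration strength; two names weakly
  over-represented in the same regions score as high as two strongly
  over-represented ones.
* The Dice measure's residual size dependence is reduced, not eliminated;
  comparisons of absolute D values across very different set sizes remain
  delicate.
* Automated community detection on surname networks is unreliable;
  `detect_communities_greedy` is exploratory only, and community labels for
  hub reporting are expected to come from attribution regions or external
  delineation.
* No name-matching, transliteration or fuzzy deduplication: variant
  spellings are distinct surnames.
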