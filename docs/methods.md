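# Methods

This note documents the models and numerical choices behind `rospace`: what
each stage computes, the defaults and why, what the campaign simulator does
and does not emulate, and the known limitations.

## Data model and CSV dialect

A campaign table has one row per *candidate* experiment — the full cartesian
product of the optimization parameters — whether or not it was ever run.
Row identity is the tuple of parameter values in declaration order
(case-sensitive). Measured yield and the measuring cycle co-occur per row;
cycles are 0-based with cycle 0 the random initialization batch. Missing
values are empty CSV cells and are never conflated with 0.

Column roles are declared with brace modifiers appended to the name:
`{measured}`, `{cycle}`, `{pred,c=N}`, `{pred_std,c=N}`, `{acq,c=N}`,
`{attr,c=N,p=PARAM}`, `{desc,p=PARAM}`, `{smiles,p=PARAM}`, `{meta}`;
unmodified columns are parameters, with numeric/categorical kind inferred
from parseability (overridable). The grammar is a pragmatic reconstruction
of the conventions used by interactive RO explorers, not a compatibility
claim against any particular tool; an adapter hook on `DialectConfig` lets
callers plug in a different naming scheme. As a convenience, `{measured}`
on a column whose base name is `cycle` is read as the cycle index, so the
natural header `yield{measured},cycle{measured}` parses as intended.
Because modifier options contain commas, the parser tokenizes the header
itself, accepting both bare and RFC-4180-quoted modifier groups; data rows
are plain CSV read in chunks (default 100,000 resident rows; results are
chunk-size independent).

Enumerated spaces are capped at 5·10⁶ rows by default — combinatorial
growth is the defining scaling problem of RO and a runaway product should
fail loudly rather than exhaust memory. Filters combine per-column
predicates (membership sets, closed intervals) with *exceptions*: row keys
forced into the result so an analyst can keep specific experiments visible
outside the filtered region.

## Distances

Gower similarity handles the mixed categorical/numeric rows: per-feature
similarity (range-normalized absolute difference for numerics, match
indicator for categoricals) is weight-averaged over the features present on
both rows; distance is its complement, always in [0, 1]. Two choices
matter:

* **Ranges come from the full dataset, never a filtered subset**, so
  distances — and therefore projections — are stable under filtering. The
  cost is that adding rows can change all distances; for a fixed enumerated
  space this never happens.
* **Missing values are excluded pairwise** (the δₖ term), Gower's original
  treatment. Euclidean and Jaccard reject missing values instead, since
  their geometry has no principled exclusion.

Categorical parameters may alternatively be compared through per-level
descriptor vectors (`categorical_mode="descriptors"`): the parameter's
weight is split uniformly over its descriptor dimensions so its total
influence is unchanged. Label mode is the default — the combination rule
between labels and descriptors is genuinely open, and labels are the
assumption-free choice.

A zero-weight feature contributes to neither numerator nor denominator, so
it is exactly equivalent to removing the feature — a property the tests
assert to 1e-12. Matrices under 5,000 rows are computed in one vectorized
pass; larger ones block-wise (fixed 2,000-row blocks) to bound peak memory.

## Projection

The pipeline always embeds the whole space: `encode → [chunked incremental
PCA if > 50 features] → embedder` for vector metrics, or `distance matrix →
embedder` for gower/jaccard/precomputed. UMAP and t-SNE accept precomputed
distances; PCA requires vectors and refuses them. Embedders are standard
scikit-learn / umap-learn calls behind one narrow function — the
contribution is the surrounding pipeline, not embedder internals.

Incremental PCA processes sequential chunks (trailing short chunk folded
into its predecessor so every partial fit sees at least `n_components`
rows). With a single chunk it coincides with full-batch PCA up to component
sign. Cross-chunk-size stability of the retained subspace is only a
meaningful notion when that subspace is spectrally separated from the
remainder; on isotropic data the principal subspace is unidentified and no
estimator can agree with another. Tests therefore measure principal angles
on data with a planted dominant subspace — the regime the pre-reduction is
intended for.

Overlap removal is iterative symmetric repulsion on a uniform grid of cell
size `min_dist`: each conflicting pair is pushed apart, coincident points
are first separated along deterministic directions (angle 2π·rank/n by
stable row index), displacement is capped (default 4·min_dist) relative to
the original layout, and the pass is best-effort — if a sweep sequence ever
ends with more conflicts than it started with, the original layout is
returned, so the contract "never worse" holds unconditionally. The scheme
is a purpose-built declutterer, not a reproduction of any published
algorithm.

## Hexagonal aggregation

Pointy-top hexagons, axial coordinates, origin pinned to the extent's
lower-left corner. `radius = width / (base_bins_across · 2^zoom · √3)`
makes the horizontal hexagon count (`base_bins_across`, default 20) double
per integer zoom step; a continuous zoom factor maps to `floor(log₂ scale)`.
Containment is nearest-center (hexagons are the Voronoi cells of their
centers): cube rounding gives the candidate, and a 7-hexagon
nearest-center check resolves floating-point boundary ties toward the
lexicographically smaller (q, r). Missing values are excluded from every
aggregation function including `count`, so per-bin counts sum exactly to
the number of points with finite coordinates and a non-missing value at
every zoom level. Empty hexes are omitted from the output. Note that
re-aggregating zoom-(z+1) bins does not reproduce zoom-z aggregates for
non-additive functions (a mean of means is not the mean); only counts are
refinement-consistent.

## Palettes

The VSUP wedge has L uncertainty layers (equal-width on the uncertainty
domain by default; quantile edges optional) and b-ary value branching:
layer ℓ carries b^(L−1−ℓ) equal-width value bins, so the most uncertain
layer collapses every value into one bin. Defaults L=4, b=3 — enough hue
resolution at high certainty (27 bins) while keeping the wedge legible —
are configurable. Domains default to the observed min/max of the supplied
value/uncertainty pair; pass explicit domains when comparing layers across
cycles, otherwise the binning would shift with each cycle's range. Colors
take the value-bin midpoint through a named matplotlib colormap and blend
toward neutral gray with the layer (up to 85%); distinct bins map to
distinct colors within a palette.

## Summaries

Group summaries report level proportions for categoricals and histograms
for numerics, with histogram edges computed once on the full dataset
(default 10 equal-width bins) so any two groups are directly comparable.
Group differences are proportion-based, Δ = p_A − p_B per level or bin —
invariant to group size, antisymmetric, and zero-sum per parameter when no
values are missing. Retention keeps |Δ| ≥ 0.1 by default, or top-k for
dense parameters (a 22-level additive dilutes every per-level proportion).
Comparing consecutive batches is the composition
`group_difference(batch(c), batch(c+1))`, not a separate operation.

## Campaign simulator

The simulator generates the data the analysis stack is meant to interpret,
with structure known by construction.

**Truth.** `yield% = clamp(30 + Σ main effects + Σ synergies + ε, 0, 100)`,
ε ~ N(0, σ²) with σ = 2 percentage points by default (typical plate-scale
measurement noise). Main effects are drawn N(0, 6) per level. Planted
structure: a *dominant* level gets a fixed +40 effect; a planted *critical
combination* gets a synergy (+25 default) **and its two constituent levels
get exact moderate main effects (synergy/3 each)** — in real campaigns the
members of a winning combination tend to perform decently alone, and an
isolated synergy whose constituents look average would never surface in any
main-effect-driven top set (the top decile of an additive surface is filled
by the best main-effect combinations; a level absent from a 13-row decile
of a 125-row space already has |Δ| ≈ 0.22, which no isolated synergy
strength can reliably beat).

**Surrogate.** Nadaraya–Watson kernel regression over Gower distances with
a Gaussian kernel (bandwidth h = 0.25 on the [0, 1] distance scale — wide
enough that one shared parameter level transfers information, narrow enough
that full mismatches do not), shrunk toward a prior mean with constant
weight K(1) = e^(−1/2). Predictive sd is `prior_sd · (1 − maxᵢ K(dᵢ/h)) +
floor_sd`: near the floor (1 pt) at measured points, near the prior (25 pt)
far from all data. Queries coinciding with a training point return that
measurement exactly. **The prior mean defaults to 50, the midpoint of the
yield scale.** This is the uninformative choice, and it is load-bearing:
unmeasured regions then look *better* than mediocre measured ones, so even
pure greedy acquisition keeps exploring until it finds conditions that beat
the prior — the classic optimism-under-uncertainty design. With a
pessimistic prior, greedy exploitation can never discover a dominant level
its random initialization missed (the 5-point init covers any given
5-level value with probability ≈ 0.68 on a 125-point space), whereas with
the midpoint prior the dominant level is measured within 3 cycles in
effectively every seeded run. The surrogate is an emulation of the
Gaussian-process drivers used in real campaigns — it honors their
uncertainty semantics, not their posterior.

**Loop.** Each cycle (including cycle 0) fits the surrogate on all
measurements so far and writes prediction mean/std, acquisition and
per-parameter attribution columns for *all* rows, so every per-cycle column
family is complete from cycle 0 (where the columns reflect the prior).
Cycle 0 then measures a seeded random batch; later cycles take the top
`batch_size` unmeasured rows by acquisition (expected improvement by
default; greedy-mean and max-uncertainty alternatives), ties resolved by
row order, i.e. lexicographic parameter assignment. Batch selection is
greedy without a diversity penalty. All randomness flows from one seed;
campaigns are bitwise reproducible.

**Attributions** are occlusion-based: the prediction of the experiment
minus the uniform average of predictions with the parameter replaced by
each *other* allowed level. Exact and fast on categorical spaces, and
sharing the SHAP column schema, but a different estimator — magnitudes are
not comparable to Kernel SHAP values. Single-level parameters get 0 by
convention.

**What the simulator does not emulate:** real measured yields or any
published campaign's numbers, GP posteriors, batch-diversity strategies,
multi-objective targets, or chemistry (labels are synthetic; descriptor
vectors, when used, are arbitrary numeric features). Passing tests
demonstrate that the analysis pipeline recovers structure a campaign's data
actually contains — not that any particular chemistry conclusion is right.

## Problem sizes and determinism in the test suite

Tests run campaigns at desk scale: a 30-point mixed space (3 cycles), the
125-point space for recovery batteries (100 seeded greedy runs, 30 seeded
interaction designs), and the full 12×4×4×3×3 = 1728-point preset for the
end-to-end byte-reproducibility check, which uses t-SNE on precomputed
Gower distances (the tool's canonical mixed-data path). Recovery assertions
are rates over fixed seed batteries, not single seeds: the dominant-ligand
check passes 100/100, the interaction top-3 check 28–29/30 (asserted ≥ 85%;
the residual failures are draws where random background mains legitimately
dominate the surface — the difference view then correctly surfaces those
instead). Hypothesis-based property tests are derandomized.

## Known limitations

* Gower distances satisfy symmetry and identity but not the triangle
  inequality; no metric repair is attempted.
* Equal-width VSUP layering under heavily skewed uncertainties wastes
  layers; use quantile layering.
* The overlap remover optimizes conflict count, not layout aesthetics, and
  can leave conflicts in pathologically dense layouts (it is explicitly
  best-effort).
* Group differences on parameters with very different level counts are not
  directly comparable (proportions dilute with level count); prefer top-k
  retention per parameter family when ranking across parameters.
* Live appending of new cycles to an existing table, server APIs, and
  database persistence are out of scope.
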