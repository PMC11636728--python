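# rospace

Headless analytics for AI-guided **reaction-optimization (RO) campaigns**.

Chemists optimizing a reaction screen a combinatorial space of conditions —
categorical choices (ligand, base, solvent, additive) crossed with numeric
settings (temperature, concentration) — and increasingly let a
Bayesian-optimization loop pick each batch of experiments: a surrogate model
predicts the yield of every untried combination with an uncertainty, an
acquisition function scores them, the top batch is run, and the model is
refit. The resulting campaign tables are wide (one row per *possible*
experiment, per-cycle prediction/uncertainty/acquisition/attribution
columns) and grow multiplicatively with every parameter (three parameters at
five levels already give 5³ = 125 candidates; real screens reach 792, 1728
and far beyond). `rospace` provides the computational pipeline for making
sense of such campaigns, as a plain Python library plus a small CLI — no
server, no database, no front end.

## What it computes

* **Data model** (`rospace.ro_dataset`) — a CSV dialect for campaign tables
  (`yield{measured}`, `pred{pred,c=3}`, `attr_base{attr,c=3,p=base}` …),
  chunked parsing, full-space enumeration, filtering with per-row
  exceptions, and time-slider subsets of measured experiments.
* **Distances** (`rospace.distances`) — weighted **Gower similarity** for
  mixed categorical/numeric experiment descriptions,

  s(a, b) = Σₖ wₖ sₖ / Σₖ wₖ δₖ,  d = 1 − s,

  with sₖ = 1 − |aₖ−bₖ|/rₖ for numerics (range rₖ over the *full* dataset),
  a match indicator for categoricals, and δₖ marking features present on
  both rows; plus weighted Euclidean and Jaccard for pure numeric /
  categorical tables. Matrices are pre-computed so every projection method
  respects user weights.
* **Projection** (`rospace.projection`) — UMAP / t-SNE / PCA embedding of
  the *whole* space (optionally through chunked incremental PCA when the
  feature matrix is wide), and a deterministic scatter overlap-removal pass.
* **Hex aggregation** (`rospace.hexagg`) — pointy-top hexagonal binning of
  the embedding with zoom-adaptive radius (hex count across the view
  doubles per zoom step), exact point-in-hex assignment via cube rounding,
  and min/max/median/mean/count aggregation with strict count conservation.
* **Palettes** (`rospace.palette`) — bivariate and **value-suppressing
  uncertainty palettes (VSUP)**: (value, uncertainty) pairs are quantized
  onto a wedge whose number of distinguishable value bins shrinks
  geometrically with uncertainty — b^(L−1) bins at the most certain layer,
  one at the least, (b^L−1)/(b−1) in total.
* **Summaries** (`rospace.summaries`) — per-cycle columns pivoted to
  experiments × cycles matrices, mean ± k·σ prediction bands, group
  summaries (level proportions / shared-edge histograms) and **group
  differences** Δ = p_A − p_B filtered to the largest movers, and
  parallel-coordinates data preparation.
* **Campaign simulator** (`rospace.campaign_sim`) — synthetic campaigns
  with a planted ground-truth yield surface (main effects + pairwise
  synergies), a kernel-regression surrogate with predictive uncertainty,
  expected-improvement / greedy / max-uncertainty acquisition, and
  occlusion attributions — emitting the same CSV dialect, so the entire
  pipeline is testable without any external dataset.

## Worked example

```python
import numpy as np
import rospace as rs

# a 3x3x4x22 = 792-experiment coupling screen, 8 cycles of 5 experiments
ds = rs.simulate_campaign("buchwald792", n_cycles=8, batch_size=5, seed=3)
print("rows:", len(ds), "cycles:", ds.n_cycles)

measured = rs.measured_subset(ds, 7)
print("measured:", len(measured),
      "best yield: %.1f%%" % measured.rows[ds.measured_column].max())

# project the whole space with precomputed Gower distances
D = rs.pairwise_distances(ds, "gower")
emb = rs.project(ds, rs.ProjectionConfig(method="tsne", metric="precomputed",
                                         seed=3), distance_matrix=D)

# hex-aggregate the cycle-7 prediction mean, carrying its uncertainty
grid = rs.grid_for_zoom(emb.extent, zoom_level=1)
col = ds.columns_with_role("prediction_mean", cycle=7)[0]
std = ds.columns_with_role("prediction_std", cycle=7)[0]
layer = rs.aggregate_layer(emb, ds.rows[col].to_numpy(float), grid, "mean",
                           uncertainty_values=ds.rows[std].to_numpy(float))
print("occupied hexes:", len(layer.bins))

# VSUP-quantize the hex layer
vals = np.array(list(layer.bins.values()))
uncs = np.array([layer.uncertainty[k] for k in layer.bins])
pal = rs.VSUPPalette.from_data(vals, uncs, layers=4, branching=3)
binned = rs.quantize_layer(vals, uncs, pal)
print("palette bins used:", binned[["layer", "bin"]].drop_duplicates().shape[0],
      "of", pal.total_bins)

# which parameter levels distinguish the measured set from the rest?
top = set(measured.row_keys())
gd = rs.group_difference(ds, top, set(ds.row_keys()) - top)
for p, l, d in sorted(gd.retained, key=lambda e: -abs(e[2]))[:3]:
    print(f"  {p} = {l}: delta proportion {d:+.2f}")
```

prints

```
rows: 792 cycles: 8
measured: 40 best yield: 100.0%
occupied hexes: 40
palette bins used: 14 of 40
  base = base_02: delta proportion +0.36
  ligand = ligand_03: delta proportion +0.26
  base = base_00: delta proportion -0.19
```

The campaign measured 40 of 792 candidates and found a quantitative yield;
the difference view shows the optimizer concentrated its batches on one
base and one ligand — exactly the "critical factor" reading this tooling
exists for.

The same pipeline is available from the shell:

```sh
rospace simulate --preset arylation1728 --cycles 8 --batch 5 --seed 7 --out run.csv
rospace validate run.csv
rospace project  --input run.csv --method tsne --metric gower --seed 7 --out emb.csv
rospace hexagg   --input run.csv --embedding emb.csv \
                 --column 'pred{pred,c=7}' --uncertainty-column 'pred_std{pred_std,c=7}' \
                 --agg mean --zoom 1 --out layer.csv
rospace palette  --input layer.csv --out layer_colored.csv
rospace compare  --input run.csv --a 'ligand=ligand_00' --b 'ligand=ligand_01' --out diff.json
```

Every command writes a `.provenance.json` sidecar with the effective
configuration, and a fixed `--seed` makes outputs byte-identical across
runs.

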