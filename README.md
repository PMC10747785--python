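# chmstand

Forest stand parameter estimation from canopy height models (CHMs), aimed at
high-density photogrammetric or LiDAR surveys of conifer plantations. The
package covers the full chain a forest-inventory analyst runs after a drone
or airborne campaign:

1. **CHM generation** — max-binning a point cloud to a digital surface model
   (DSM), void filling, and differencing against a digital terrain model
   (DTM): `CHM = DSM − DTM`, clamped at 0.
2. **Individual tree detection (ITD)** — local maxima on the CHM after
   lowpass (circular mean), square-mean, or Gaussian smoothing, with a
   circular search radius or fixed square window and a 1.37 m (breast
   height) floor.
3. **Crown delineation** — Voronoi tessellation seeded at treetops: a cell
   joins crown *i* if it is nearest to seed *i*, its height is at least
   `exclusion · H_i`, and it lies within `maxcrown · H_i` of the seed
   (defaults 0.7 and 0.4).
4. **Detection scoring** — optimal one-to-one matching of detected to field
   treetops within a distance threshold, then
   `precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`,
   `F = 2·P·R/(P+R)`, plus stem density.
5. **Allometry** — basal area `BA = π/4·(DBH/100)²`, stem volume
   `V = f·BA·H` (pluggable model, default form factor `f = 0.36`), and
   carbon stock `CST = V·D·BEF·(1+R)·CF` with the Japanese inventory
   coefficients for larch (`D = 0.404`, `BEF = 1.15`, `R = 0.29`,
   `CF = 0.51`).
6. **Regression models** — DBH, volume, and carbon from canopy metrics
   (tree height, crown area, crown perimeter, nearest-neighbor distance):
   VIF > 5 pruning, bidirectional stepwise AIC selection over OLS, and
   leave-one-out cross-validation.

Because real inventory plots rarely ship with their imagery, the package
includes a first-class synthetic stand generator calibrated to an old
(century-scale) larch plantation: ~147 stems ha⁻¹ on ~0.93 ha, heights
truncated-normal N(35.2, 3.27²) on [25.8, 42.9] m, DBH N(60.94, 7.14²) cm
correlated with height, lognormal crown areas (mean 56.65 m², SD 21.27 m²),
a 19° terrain ramp, and 0.5 m rasters. Every stage is testable by parameter
recovery against this known ground truth.

## Worked example

```python
import numpy as np
import chmstand as cs

config = cs.SyntheticStandConfig(seed=1, surface_noise_sd=0.0)
trees = cs.generate_tree_list(config)           # 137 trees on 0.93 ha
dtm, dsm = cs.render_surfaces(trees, config)
chm = cs.compute_chm(dsm, dtm)

smoothed = cs.apply_filter(chm, cs.FilterSpec("lowpass", radius_or_sigma=1.0))
tops = cs.detect_local_maxima(smoothed, search_radius=2.0)
res = cs.match_treetops(
    np.column_stack([tops.x, tops.y]), tops.treetop_id,
    trees[["x", "y"]].to_numpy(), trees["tree_id"].to_numpy(), threshold=2.0,
)
p, r, f = cs.detection_scores(res)
print(len(tops), res.tp, res.fp, res.fn, round(f, 3))
# 131 131 0 6 0.978

print(round(cs.carbon_stock(3.76), 2))   # 1.15 MgC for a 3.76 m3 stem
```

131 of the 137 trees are detected with no false positives (the six misses
are subordinate trees overtopped by a taller neighbor's crown), giving
F = 0.978; the carbon line converts a mean-sized stem's volume to carbon
with the default larch coefficients.

The same chain is scriptable from a shell:

```sh
chmstand simulate --seed 1 --out stand --noise-sd 0
chmstand chm --dsm stand/dsm.asc --dtm stand/dtm.asc --out chm.asc
chmstand detect --chm chm.asc --filter lowpass --radius 1 --search-radius 2
chmstand evaluate --treetops treetops.csv --field stand/trees.csv --threshold 2
```

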