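# larvatray

Mass-release mosquito control programmes (SIT, *Wolbachia*, genetic methods)
depend on rearing *Aedes aegypti* larvae by the thousand in trays of water.
Development time, survival and the size of emerging adults depend not only on
diet and stocking density but also on the size of the rearing container and
on how larvae actually use its space — they crowd against the walls, so the
density a larva experiences can be far higher than the tray average.

`larvatray` is a Python toolkit for quantifying both effects:

- **Spatial occupancy.** Each container's water surface is partitioned into
  three regions of exactly equal area — an *edge* region touching the wall, a
  *central* region, and an *intermediate* ring between them (constant-width
  frames for rectangular trays, concentric annuli for circular ones).
  Photographs of dark larvae on light water are segmented (invert → 8-bit →
  between-class-variance threshold → 3×3 median despeckle → small-component
  removal) and the larval pixel mass in each region is turned into a
  *preference fraction* p_r (summing to 1) and a *regional density*
  p_r · N / (V/3) in larva/ml.
- **Colony productivity.** Tray-level life-history traits are combined into a
  productivity index **PI = ln(100 · F · S) / D** (F mean eggs/female, S
  larva-to-adult survival, D mean development days), with a
  hold-one-factor-constant sensitivity analysis: PI is recomputed with D, S,
  F or S&F frozen at their grand mean and a two-way fixed-effects ANOVA
  (container size × treatment) yields η² effect sizes per term, showing which
  trait carries each design effect.
- **Supporting statistics.** One-way ANOVA intra-class correlation
  (repeatability of repeated photographs) with a seeded bootstrap CI, and a
  tie-corrected Kruskal–Wallis test with Dunn pairwise post-hoc comparisons
  for regional contrasts.
- **Synthetic data with ground truth.** A photograph generator (curved
  larval strokes placed by a configurable edge/intermediate/central
  distribution, food-particle noise, illumination gradient) and a
  life-history generator (treatment-dependent development/survival/winglength
  with winglength-linked fecundity), so the entire pipeline is testable with
  no external data.

## Worked example

Partition the large rearing tray (27.00 × 20.70 cm, 1000 ml, 200 larvae),
simulate twelve photographs with the default edge-biased placement, and run
the full measurement chain back over them:

```python
import pandas as pd
import larvatray as lt
from larvatray.geometry import region_label_mask
from larvatray.imaging import process_image
from larvatray.simulate import ImageSimConfig

container = lt.study_containers()["large"]
spec = lt.region_boundaries(container)
print(spec.to_frame().round(3).to_string(index=False))

cfg = ImageSimConfig(container=container, seed=42)
images, truth = lt.generate_images(cfg, 12)
labels = region_label_mask(container, px_per_cm=cfg.px_per_cm)
frames = []
for i, img in enumerate(images):
    counts, info = process_image(img, labels)
    counts.insert(0, "image_id", truth["image_id"][i])
    frames.append(counts[counts["region"] != "total"])
occ = lt.analyze_counts(pd.concat(frames, ignore_index=True), container)
print(occ.groupby("region")[["preference", "density_larva_per_ml",
                             "crowding_ratio"]].mean()
         .reindex(["edge", "intermediate", "central"]).round(3).to_string())
```

prints

```
      region  area_cm2  wall_distance_inner_cm  wall_distance_outer_cm
        edge     186.3                   0.000                   2.146
intermediate     186.3                   2.146                   4.921
     central     186.3                   4.921                     NaN
              preference  density_larva_per_ml  crowding_ratio
region                                                        
edge               0.756                 0.453           2.267
intermediate       0.156                 0.094           0.468
central            0.088                 0.053           0.265
```

The three regions each measure 186.3 cm²; the edge region is the 2.146 cm
strip along the wall. Recovered from the images alone, ~76% of larval pixel
mass sits in the edge region — 2.27× the uniform expectation — giving
0.45 larva/ml there at this stocking level against a tray-wide average of
0.20 larva/ml. A single productivity value:

```python
>>> round(lt.productivity(F=80, S=0.9, D=9), 4)
0.9869
```

The same steps are available from a shell — `larvatray regions`,
`simulate-images`, `analyze-images`, `simulate-lifehistory`, `productivity`,
`sensitivity`, `report` — each reading a YAML/JSON run config and writing a
reproducibility manifest (effective settings, seed, output checksums).

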