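# tlsmeta

Metaproperty analysis of terrestrial laser scanner (TLS) scans.

A ground-based lidar scan is a population of hundreds of thousands of laser
pulses, each recording up to two ranged returns.  Rather than reconstructing
objects from the point cloud, *metaproperty analysis* treats that population
statistically: a handful of pulse-level and geometric summaries of one scan
turn out to carry a surprising amount of information about the ecosystem
the instrument was standing in.  `tlsmeta` is for ecologists and remote
sensing scientists who want to classify scan locations (enclosed spaces vs.
vegetation, structurally distinct forest types) from those summaries, and
for anyone who wants a fully synthetic, seeded test bed for such methods.

## The six metaproperties

For a scan with zenith angle θ (0° = up, 90° = the horizontal optical
plane), first-return distances dᵢ and intensities Iᵢ:

| metric | definition | pulse subset |
|---|---|---|
| mean distance | mean dᵢ of first returns (m) | θ ≤ 90° |
| mean intensity | mean Iᵢ of first returns | θ ≤ 90° |
| 1st:2nd returns | #first returns / #second returns | θ ≤ 90° |
| no-return : pulses | #pulses with no return / #pulses (a gap-fraction analogue) | 30° ≤ θ ≤ 35° |
| optical plane area (OPA) | shoelace area (m²) of the polygon joining the (x, y) positions of first returns at the optical plane, vertices in azimuth order | θ = 90° (±0.5°) |
| rugosity | Σ area of Delaunay triangles lifted to (x, y, z) / planar footprint area | θ ≤ 30°, first returns |

## The classification workflow

The Metaproperty Classification Model (`tlsmeta.mcm`) is a ten-stage binary
classification workflow over per-scan metaproperty vectors:

1. graphical/logit assessment of each variable, 2. complete-separation
detection, 3. (discretionary) natural-log transforms, 4. a power analysis
sizing the testing set, n = ⌈N·x / ((N−1)E² + x)⌉ with x = Z²r(100−r),
5. a proportional stratified split, 6. binomial logistic regression —
Firth's Jeffreys-prior penalized fit whenever a predictor completely
separates the classes (the standard MLE then diverges), 7. (discretionary)
standardized-residual and Cook's-distance diagnostics, 8. (discretionary)
backward model reduction, 9. prediction, 10. evaluation: confusion
counts, accuracy, chance accuracy 100·Σ(nᵢ/N)², goodness-of-fit χ², and
ROC / precision-recall curves with seeded bootstrap 95% CIs.

It is exposed statsmodels-style: `MetapropertyClassifier(table, config)`
is the model, `.fit()` returns an `MCMResults` with a `summary()`.

A seeded ray-casting simulator (`tlsmeta.simulate`) generates room scans
(enclosing box, bright continuous surfaces, no gaps) and forest scans
(canopy layer with gaps, exponential understory free paths, trunk
cylinders, frequent second returns, 40 m range clip) so the whole pipeline
runs without field data.

## Worked example

```python
from tlsmeta import (MCMConfig, MetapropertyClassifier,
                     generate_labeled_dataset)
from tlsmeta.metaproperties import extract_table

scans = generate_labeled_dataset(32, 56, base_seed=7)   # rooms=0, forests=1
table = extract_table(scans)
print(table.head(3).round(3).to_string())

cfg = MCMConfig(full_population_mode=True,
                predictors=("mean_distance", "mean_intensity",
                            "opa", "rugosity"),
                seed=7)
print(MetapropertyClassifier(table, cfg).fit().summary())
```

```
    scan_id  label  mean_distance  mean_intensity  first_second_ratio  no_return_ratio     opa  rugosity
0  room_000      0          3.340           0.794              80.889              0.0  73.044     2.228
1  room_001      0          3.045           0.706             165.455              0.0  65.262     2.431
2  room_002      0          3.057           0.771              79.130              0.0  84.029     2.580

Metaproperty Classification Model
============================================================
regression method : firth  (penalized: complete separation present)
predictors        : mean_distance, mean_intensity, opa, rugosity
...
testing set (n=88): accuracy 100.00%  (chance 53.72%)
  sensitivity 1.0000  specificity 1.0000
  chi-squared 0.0000 (1 df)
  ROC AUC 1.0000 (95% CI: 1.000-1.000)
```

Reading the output: the room rows show the archetypal contrasts — short
mean distances (an enclosed box), bright surfaces, a huge 1st:2nd returns
ratio and a zero gap fraction.  The two ratio metaproperties completely
separate rooms from forests, so they are excluded as predictors (a single
threshold on either already classifies perfectly) and the remaining four
are fitted with Firth's penalized regression, which classifies all 88
scans correctly — far above the 53.72% expected by chance.

The same pipeline is available from the shell:

```sh
metaprop simulate -c scene.yaml -o scans/ --seed 5
metaprop extract  -i scans/ -o table.csv
metaprop mcm      -i table.csv -o result.json --seed 5 --full-population
```

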