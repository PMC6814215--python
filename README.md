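# fuzzyrisk

A fuzzy-logic decision-support pipeline for assessing climate-driven
biomass loss risk from gridded vegetation-model ensembles.

Raw per-cell variables (biomass burned, fire frequency, total and live
biomass, vegetation-type departure, observed biomass) are normalized to
fuzzy truth in [0, 1] with two-threshold linear ramps and combined cell by
cell through a declarative logic tree of And (minimum), Or (maximum), and
Union (mean) operators. The tree is evaluated independently for every
member of a climate-future ensemble; cross-member reducers produce mean,
minimum, and maximum risk maps plus an uncertainty layer (the per-cell
population standard deviation rescaled to fuzzy space with thresholds 0
and 0.5). Driver-attribution statistics split the study area into
zero-risk, fire-dominated, and mortality-dominated fractions and relate
each member's share of the ensemble extremes to its climate deltas.
A synthetic data generator emulates the full input bundle — ensembles over
scenarios and time periods, baseline layers for threshold derivation, an
observed-biomass layer with an exact zero fraction — so the entire analysis
runs offline.

## Layout

| module | role |
| --- | --- |
| `fuzzyrisk.grid_io` | grid data model (layers, stacks, departure table) and GeoTIFF/NetCDF/CSV readers and writers |
| `fuzzyrisk.fuzzy` | linear fuzzification and the And/Or/Union operators with per-cell source attribution |
| `fuzzyrisk.tree` | declarative logic tree, validation, vectorized cell-independent evaluation |
| `fuzzyrisk.vegetation` | modal vegetation type and departure scoring |
| `fuzzyrisk.ensemble` | min/mean/max reducers, variability layer, area-weighted summaries, scenario-pair uncertainty |
| `fuzzyrisk.drivers` | fire-vs-mortality difference maps, dominance fractions and counts, member extremes, climate deltas |
| `fuzzyrisk.synthetic` | deterministic synthetic input bundles and their on-disk form |
| `fuzzyrisk.pipeline` | threshold derivation, scenario runs, cross-scenario comparison tables |

The default logic tree ships as
`src/fuzzyrisk/data/biomass_loss_risk.yaml` (11 nodes, 6 fuzzified inputs)
with the frozen published threshold profile; thresholds can also be
re-derived as baseline-period percentiles (default 10th/90th).

## CLI

```sh
# generate a synthetic input bundle (writes manifest.json)
fuzzyrisk gen-data --rows 100 --cols 100 --members 20 --seed 0 --out data/

# derive conversion thresholds from the baseline layers
fuzzyrisk derive-thresholds --manifest data/manifest.json --out thresholds.json

# run one scenario/period: writes risk maps (mean/min/max/uncertainty),
# driver maps, and summary/dominance/extremes tables
fuzzyrisk run --manifest data/manifest.json --scenario rcp85_nfs \
    --period late --out out/

# run every scenario/period and write the comparison tables
fuzzyrisk compare --manifest data/manifest.json --out out/
```

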