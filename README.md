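# cytoquant

Per-cell cytoplasmic fluorescence quantification for multi-channel
immunofluorescence images. The pipeline mirrors a common semi-automated
workflow for dense tissue such as pancreatic islets:

1. **Load** a calibrated multi-channel TIFF (up to 5 channels, single-plane
   or Z-stack; Z-stacks are collapsed by max- or mean-projection).
2. **Segment** nuclei on the nuclear channel (deterministic classical
   backend by default; optional StarDist adapter), optionally restricted to
   a polygon region of interest.
3. **Expand** every nucleus label by a physical distance (default 1 µm) to
   capture the perinuclear cytoplasmic interspace. Two modes: `independent`
   (per-label dilation, overlaps allowed — faithful to per-ROI enlargement
   in interactive tools, including its double-positive artifact for
   touching cells) and `exclusive` (nearest-label partition, the
   mitigation).
4. **Measure** each cell twice — nucleus only and expanded footprint — and
   write paired `{sample}_ch{k}_without_enlargement.csv` /
   `..._with_enlargement.csv` files.
5. **Classify**: derive each cell's new mean intensity (ring mean
   `(IntDen_with − IntDen_without) / (Area_with − Area_without)` by
   default), call a cell positive for a channel when the intensity strictly
   exceeds the configured threshold, and summarize totals, per-channel
   positives, exclusive singles, multi-positive combinations and
   all-negative cells per sample.

A synthetic-image module (`cytoquant.simulate`) generates densely packed
fields with known per-cell marker status for testing, including an
adjacency scenario that probes the false double-positive mechanism.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(oracle equivalence for expansion and ring means, end-to-end ground-truth
recovery, the double-positive artifact direction, threshold monotonicity,
worked arithmetic, format round-trips).

## CLI

```bash
# generate a synthetic field + matching config
cytoquant simulate --out sim/ --seed 7 --n-cells 50

# full pipeline: TIFFs -> paired CSVs -> summary.csv (+ manifest.json)
cytoquant run sim/simulated.tif --config sim/config.yaml --out results/

# or the two stages separately
cytoquant measure img1.tif img2.tif --config config.yaml --out csvs/
cytoquant classify --csv-dir csvs/ --config config.yaml --out summary.csv
```

Config (YAML, reusable across runs):

```yaml
channels:
  - {channel_index: 1, name: cpep, threshold: 40.0, enabled: true}
  - {channel_index: 2, name: gcg, threshold: 50.0, enabled: true}
  - {channel_index: 2, name: gcg_high, threshold: 150.0, enabled: true}
intensity_method: ring        # or expanded_mean
nuclear_channel: 0
projection: max               # or mean
segmentation:
  backend: classical          # or stardist
  params: {smooth_sigma_um: 0.5, min_area_um2: 4.0}
expansion:
  distance_um: 1.0
  mode: independent           # or exclusive
# roi: {polygon: [[0, 0], [0, 400], [400, 400], [400, 0]]}   # optional
```

Thresholds are conventionally derived as 0.6 × a manually measured
representative intensity (`cytoquant.derive_threshold`). "High-expressing"
populations are just extra rules on the same channel with a higher
threshold.

## Library use

```python
import cytoquant as cq

img, truth = cq.simulate_image(cq.SimulationParams(n_cells=50, seed=1))
labels = cq.segment_nuclei(img)
fp = cq.expand_labels(labels, cq.ExpansionSettings(distance_um=1.0))
without = cq.measure_cells(img, labels, channels=[1])
with_enl = cq.measure_cells(img, fp, channels=[1])
ci = cq.compute_cell_intensity(without, with_enl, method="ring")
cfg = cq.ClassificationConfig(channels=[cq.ChannelRule(1, 50.0, "marker1")])
summary = cq.summarize(cq.classify_cells(ci, cfg), cfg)
```
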