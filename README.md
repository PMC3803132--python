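# spermwave

Sperm-head morphology classification from micrographs.  The pipeline
segments sperm heads by gray-level thresholding, transforms each head
contour into a one-dimensional waveform (centroid-to-edge distances, or
symmetric-pair distances), encodes waveforms with a start-point-invariant
rank-order binary code compared via a normalized rank-difference
dissimilarity (D_m), extracts gray-level features along a square-spiral
("roundabout") scan of the head, and classifies with:

* single-feature dividing-line rules (average rank difference, darkness
  percentage),
* a joint criterion `C = alpha * dARD + (1 - alpha) * 255 * P` with an alpha
  sweep,
* a fused RBF C-SVC over 256 gray-spiral word ranks plus the dARD scalar,
* K-nearest-neighbour and ellipse-ovality baselines.

Because the original image archive is unavailable, a first-class synthetic
fixture module generates micrographs with the structure the method assumes
(bright background, darker elliptical heads with tails; normal heads are
smooth mid-dark ovals, abnormal heads are too round / too slim /
rough-edged / abnormally pale or dark) together with per-sperm ground-truth
masks and labels.

## CLI

The `spermwave` entry point exposes each stage plus a full run:

```sh
# synthetic scene with ground truth (image.png, masks/, manifest.csv)
spermwave simulate --n-normal 80 --n-abnormal 80 --seed 7 --out-dir scene/

# per-stage processing via plain PNG/CSV files
spermwave segment --input scene/image.png --out-dir crops/
spermwave waveform --crops-dir crops/ --method centroid --out waveforms.csv
spermwave rank --waveforms waveforms.csv --m 5 --out ranks.csv
spermwave grayfeat --crops-dir crops/ --out gray.csv
spermwave classify --method ellipse --crops-dir crops/
spermwave sweep-alpha --features features.csv --out sweep.csv

# everything at once (simulate -> segment -> features -> all classifiers)
spermwave run --seed 7 --out-dir runs/demo
```

`spermwave run` accepts a YAML config (`--config run.yaml`); every
parameter has a default matching the published settings where one exists
(rank window widths m=5 for contour waveforms and m=8 for gray spirals,
alpha grid 0.1–0.9, C-SVC/RBF with cost 1, eps 0.001, cache 40 MB,
shrinking on, gamma = 1/k, ovality band 1.2–1.8, k=10 neighbours).
Unknown config keys are rejected.  The joint-criterion and fused-SVM
classifiers need ground-truth labels, which simulate mode provides; images
mode reads them from a manifest CSV.

## Layout

* `src/spermwave/fixtures.py` — synthetic scenes with ground truth
* `src/spermwave/segment.py` — thresholding, components, tail removal, crops
* `src/spermwave/contour.py` — Moore boundary tracing and both waveforms
* `src/spermwave/rankcode.py` — rank binarization, word histograms, D_m, dARD
* `src/spermwave/grayfeat.py` — gray statistics and the square-spiral scan
* `src/spermwave/classify.py` — dividing lines, alpha sweep, fused SVM, baselines
* `src/spermwave/config.py`, `pipeline.py`, `cli.py` — orchestration
* `tests/` — unit, property and acceptance suites (`tests/_oracles.py` holds
  the independent brute-force oracles)
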