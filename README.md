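# decmscore

Residual-nucleus versus impurity assessment for decellularized extracellular
matrix (dECM) sections.

dECM biomaterials must be free of donor cell nuclei: residual nuclei carry
immunogenic cargo, so regulatory QC requires stained sections with "no
visible nuclei". In practice the call is confounded by particulate
contamination — dust picked up during embedding and staining looks remarkably
like a pyknotic nucleus under hematoxylin-eosin. `decmscore` implements a
desk-scale, fully reproducible version of a multidimensional morphometry +
semi-quantitative scoring workflow for this problem, for QC engineers and
image-analysis researchers working on decellularization assessment:

* **Six-parameter morphometry** of every suspicious object: area, perimeter,
  Feret (longest caliper diameter), MinFeret (shortest caliper width),
  Feret ratio = Feret/MinFeret, and average grayscale
  ḡ = (1/N) Σᵢ I(i). Caliper diameters are exact rotating-calipers
  statistics of the pixel-corner convex hull, verified against a brute-force
  oracle.
* **Scoring criterion 1 (single suspicious point).** Each parameter x is
  scored against a reference-nucleus benchmark (μ ± σ per parameter):
  3 if |x−μ| ≤ σ, 2 if ≤ 2σ, 1 if ≤ 3σ, else 0. Parameter scores average
  within their dimension (size / shape / color) and the dimension scores
  combine with importance weights into a total (0–9 at unit weights); a
  point is called a nucleus above a threshold (default 60% of maximum, or
  calibrated on labeled samples).
* **Scoring criterion 2 (whole section).** Three counts — suspicious points
  overall, points called nuclei by criterion 1 (double-weighted), points in
  the extracellular matrix — are binned into 0–4 component scores; total
  s_overall + 2·s_nucleus + s_ecm ∈ [0, 16].
* **Multi-stain consensus.** Section scores from HE, Feulgen, acetocarmine
  and DAPI stains combine into one call: alarms on ≥2 stains ⇒ residual
  nuclei; exactly one alarming stain ⇒ contamination suspect (the classic
  single-stain false positive); none ⇒ decellularized.
* **Feature classifier.** A standardized logistic regression (or small
  random forest) over the same six features, with a 6:2:2
  train/validation/test split and recall/accuracy reporting.
* **Synthetic slide simulator.** Seeded renderer for all four stain
  appearances with exact ground truth: elongated/curved nuclei (Feret ratio
  > 2 under brightfield stains), rounder and darker dust with larger size
  variance, out-of-focus dust, and DAPI fields on which dust is invisible.
  Every stage of the pipeline is testable with no external data.

## Worked example

```python
from decmscore import (RunConfig, run_pipeline)

report = run_pipeline(RunConfig(master_seed=2, n_sections=3))
print(report.summary())
```

prints

```
decmscore run 6e30130462518762 (seed 2)
slides: 60  stains: he, feulgen, acetocarmine, dapi
detection recovery (visible ground truth): 99.7%  DAPI dust detections: 0
mean section score by group: negative=1.6  positive_1=13.7  positive_2=13.7  sample_1=1.6  sample_2=1.7
single-point scoring accuracy (calibrated threshold): 98.7%
classifier test accuracy: 1.000  recall: impurity=1.00  nucleus=1.00
consensus decisions: {'decellularized': 9, 'residual_nuclei': 6}
```

Reading this: the synthetic study renders 5 groups (two decellularized
samples, two cellular positive controls, one acellular negative control) ×
4 stains × 3 sections. Detection recovers 99.7% of the visible ground-truth
objects and finds zero dust on DAPI slides (dust has no DNA to bind the
probe). Positive-control sections score ~13.7/16 on criterion 2 while
nucleus-free groups stay ≤ ~2, so every sample-level consensus call is
correct; the calibrated criterion-1 threshold separates dust from reference
nuclei with 98.7% accuracy, and the learned classifier is perfect on its
held-out test split.

The same stages are scriptable from the shell:

```bash
decmscore simulate --stain feulgen --out sim --seed 4
decmscore detect --in sim/slide_feulgen_4.png --stain feulgen --out points.json
decmscore measure --points points.json --image sim/slide_feulgen_4.png \
    --stain feulgen --out features.csv
decmscore benchmark --features features.csv --stain feulgen --out bench.json
decmscore score-point --features features.csv --bench bench.json --out scores.csv
decmscore score-section --n-overall 12 --n-nucleus 3 --n-ecm 7
decmscore run-demo --seed 2 --n-sections 3
```

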