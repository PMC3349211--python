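# mcica

Computer-aided detection of **clustered microcalcifications** — tiny bright
calcium deposits whose grouping (three or more within about 1 cm²) is one of
the earliest mammographic signs of breast cancer — in optical-density (OD)
mammogram images. The package is aimed at medical-image-analysis researchers
who want a fully inspectable, deterministic reference pipeline that runs
end-to-end on synthetic phantoms, with no proprietary image data required.

## Method

Each pixel is characterized by the independent-component coefficients of its
square neighbourhood: training patches form a data matrix **X**, each column
is mean-centred, a prewhitening matrix **K** projects onto the leading
principal directions with unit variance, and FastICA estimates an orthonormal
unmixing rotation **W** with **XKW = S**. A window **R** then maps to the
feature vector

&nbsp;&nbsp;&nbsp;&nbsp;**F** = ((**R** − column means) **K**) **W**,

optionally augmented by the patient's age scaled linearly from [27, 91] years
onto [−1, +1]. A single-hidden-layer MLP trained with resilient
backpropagation (RPROP), selected over a hidden-size sweep with random
restarts, classifies every pixel into {malignant microcalcification, isolated
microcalcification, normal} via SNNS-style analyzers (the `402040` rule, or
winner-takes-all `WTA0–WTA3`). Detections are cleaned of isolated pixels and
artifacts, grouped into objects, and a density map counts objects in the
1 cm² neighbourhood of every pixel; support with density ≥ 3 becomes disjoint
regions of interest (ROIs). ROIs are scored against ground-truth regions:
sensitivity = TP/(TP+FN) and FPi = false positives per image, traced as FROC
operating points across analyzers. Details and design rationale are in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
from mcica.pipeline import ExperimentConfig, run_phantom_experiment

result = run_phantom_experiment(ExperimentConfig(), seed=0)
print(f"sensitivity={result.sensitivity:.3f}  FPi={result.fpi:.2f}")
print(result.sweep_report)
```

prints (exactly, for seed 0):

```
sensitivity=1.000  FPi=0.00
   n_hidden  restart  seed  val_score  epochs
0        50        0     0   0.940000      31
1        50        1     1   0.945000      47
2       100        0  7919   0.943333      48
3       100        1  7920   0.936667      27
```

Twenty phantoms are generated and split 10/5/5 by image into learning,
validation and test sets; an ICA basis (9-px window, 20 components) is fitted
on learning-split patches; four networks (hidden sizes 50 and 100, two
restarts each) are trained with RPROP and the best validation success rate
(here 0.945, the 50-unit second restart) is kept; the five test images are
diagnosed pixel-by-pixel with the WTA1 analyzer and pushed through the ROI
builder. All five malignant clusters are found (sensitivity 1.0) with no
false-positive ROIs (FPi 0.0).

The same pipeline is scriptable from the shell (`mcica phantom`,
`mcica convert`, `mcica fit-basis`, `mcica train`, `mcica diagnose`,
`mcica rois`, `mcica evaluate` — see `mcica --help`).

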