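# agnorfract

Quantification of **argyrophilic nucleolar organizer regions (AgNORs)** in
brightfield prostate histology: segmentation of the silver-stained
nucleolar dots from RGB images, per-dot morphometry (count, area,
diameters-ratio roundness), **box-counting fractal dimension** of dot
silhouettes and of skeleton-filtered dot maps, and the ANOVA/Tukey
statistics that compare pathology groups (benign nodular hyperplasia,
atypical adenomatous hyperplasia, Gleason patterns 2–5).

AgNOR count and morphology track proliferative activity, and nucleolar
shape changes are a long-standing subjective observation in prostate
carcinoma. The package makes those observations measurable with explicit,
reproducible operators — and, because clinical image sets are rarely
shareable, it ships a seeded **synthetic-histology generator** with
pixel-exact ground truth so every stage of the chain can be validated by
parameter recovery.

## The quantities

For a binary set observed at box sizes *s*, the box-counting dimension is
the least-squares slope

&nbsp;&nbsp;&nbsp;&nbsp;FD = d log *N*(*s*) / d log (1/*s*),

with *N*(*s*) the number of occupied grid boxes, minimized over grid
offsets at each size. Planar curves give FD in (1, 2): a smooth dot
outline measures near 1, a rugged one higher. Roundness is the
diameters ratio — major/minor axis of the second-moment-equivalent
ellipse (1 = circle). Per-image records also carry dot count, mean dots
per nucleus, density (dots/mm²), and total normalized AgNOR-positive
area (ppm of image area). Values flagged degenerate (zero area,
undefined roundness, FD = 1) are excluded before any averaging, and
averaging is strictly hierarchical: image → patient → group.

## A worked example

```python
from agnorfract import SyntheticSpec, generate_image, measure_image

image, truth = generate_image(
    SyntheticSpec(seed=7, noise_sd=0.0, fixed_dot_count=True, stromal_dots_mean=0.0)
)
meas, objects = measure_image(
    image, nucleus_mask=truth.nucleus_mask, epithelium_mask=truth.epithelium_mask
)
print(meas.raw_dot_count, meas.dot_count, round(meas.mean_roundness, 3),
      round(meas.mean_object_fd, 3))
```

prints

```
30 28 1.206 1.171
```

— all 30 rendered dots are segmented (`raw_dot_count`); the FD = 1 value
filter then drops 2 dots whose outline shows no measurable complexity;
the survivors average a roundness of 1.206 (mildly elliptical) and a
silhouette FD of 1.171 (rugged boundaries — this benign-style spec uses
ruggedness amplitude 0.15).

A six-group cohort comparison
(`python examples/04_cohort_statistics.py`) measures 60 synthetic images
and recovers the designed contrast: pooled carcinoma has lower
silhouette FD than AAH and BNH (F(2,57) = 104.8, P ≈ 8e-20, both Tukey
pairs significant) and higher diameters-ratio roundness — smoother,
more elongated nucleoli in the malignant groups.

The `examples/` directory has one short script per capability
(calibration shapes, image synthesis, segmentation + morphometry, cohort
statistics, narrowed-interval FD analysis). A thin CLI covers the same
pipeline from a shell:

```bash
agnorfract simulate -o cohort/ --images-per-group 5 --seed 1
agnorfract measure -i cohort/ -l cohort/labels.csv -o results/
agnorfract run -c config.yaml
```

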