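# icspectrum

Quantification of the **intercapillary space spectrum** on en-face optical
coherence tomography angiography (OCTA) images of the retina.

On an en-face image of the superficial capillary plexus, every dark region
fully enclosed by vessels is an *intercapillary space* — from the small
polygonal pockets of a healthy capillary mesh, through spaces enlarged by
transient capillary plugging, to frank nonperfusion areas (NPAs) of diabetic
ischemia, with the foveal avascular zone (FAZ) as the one physiological
member that is excluded from statistics.  Treating all of these as a single
continuum and measuring every one of them yields per-eye parameters (space
count, mean area/perimeter/diameters, counts above fixed size and shape
thresholds) that discriminate diabetic retinopathy (DR) severity.  The
package is aimed at ophthalmic image-analysis researchers who want a
reproducible, scriptable version of this measurement chain plus a synthetic
testbed with exact ground truth.

## Method

For each eye the pipeline follows four steps on a nominal 3 × 3 mm en-face
slab digitized to 1024 × 1024 px:

1. **Normalization / averaging** — intensities min–max scaled to [0, 1];
   optional pixel-wise averaging of 2–4 repeat frames.  Comparing a single
   frame against the average exposes capillaries with *transient* flow-signal
   loss (vessel in the average, absent in the raw frame).
2. **Denoising** — Gaussian blur, radius 2 px (σ = 2).
3. **Binarization** — Phansalkar adaptive local thresholding; pixel *I* is
   vessel iff *I* > *t* with

   *t* = *m* · (1 + *p*·e^(−*q*·*m*) + *k*·(*s*/*r* − 1)),

   where *m*, *s* are the local mean and standard deviation over a circular
   window (defaults *k* = 0.25, *r* = 0.5, *p* = 2, *q* = 10, window radius
   15 px).
4. **Morphometry** — connected dark components inside the central 2-mm
   circle are labeled; per space: area (px count · pitch²), perimeter
   (8-directional chain code with weights 1/√2 plus outline closure), minimum
   and maximum Feret diameters (rotating calipers on the pixel-corner hull)
   and the area/perimeter ratio.  The space containing the image center is
   the FAZ and is excluded from all summaries.

Cohort statistics mirror the clinical analysis: median (IQR) per severity
grade, Kruskal–Wallis with Bonferroni-corrected pairwise Mann–Whitney tests,
Spearman rank correlation, exact two-sided Fisher tests of 2 × 2 criterion
tables, and empirical ROC/AUC (ties credited 0.5; Hanley–McNeil standard
error) for grade groupings such as referable DR (moderate NPDR or worse).

A first-class synthetic generator (`icspectrum.synthetic`) builds a planar
capillary mesh (Poisson-disc points, Delaunay edges, protected FAZ ring and
trunk vessels), removes edges to emulate permanent capillary dropout, blanks
edges per frame to emulate transient loss, and rasterizes the result with
additive noise — while exposing the exact face polygons as ground truth.

## Worked example

```bash
python examples/02_quantify_intercapillary_spaces.py
```

simulates a moderately diseased eye (20 % capillary dropout, 10 % per-frame
transient loss, speckle noise) and analyzes it end to end:

```
spaces detected (FAZ excluded): 318
mean area:        5.395 x10^-3 mm^2
mean perimeter:   0.316 mm
mean min/max diameter: 0.067 / 0.117 mm
spaces > 0.03 mm^2:          2
spaces with A/P > 0.025:     27
FAZ area:                    0.2591 mm^2
pixels with transient flow-signal loss: 2866
```

Fewer and larger spaces than a healthy eye (~460 spaces of ~3 × 10⁻³ mm²
each at these settings), 27 spaces above the 0.025 area/perimeter
remodeling threshold, and a correctly recovered 0.3 mm-radius FAZ.  The
other examples cover ground-truth inspection (`01`), cohort severity
statistics with ROC/AUC (`03`) and the Fisher contingency analysis of the
high-ratio criterion (`04`).

A thin CLI wraps the same library calls:

```bash
icspectrum simulate --out eye0 --seed 7 --dropout 0.2
icspectrum analyze eye0/frames.tif --out eye0/analysis --grade moderate_npdr
icspectrum cohort cohort.csv grades.csv --out report
```

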