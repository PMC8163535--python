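# Methods

## Problem and approach

Coronal histological sections of rodent brain stained with
hematoxylin–eosin show the hippocampus as a thin (a few pixels at working
resolution), darkly stained, irregularly curving band. Delimiting it by hand
is slow and requires expertise. `hippopix` frames the task as *pixel-wise
binary classification*: every pixel inside an annotated bounding box is
described by a 14-dimensional feature vector and assigned to class C1
(hippocampal) or C0 (background) by a trained classifier.

The method has four stages: image preprocessing, feature extraction,
balanced dataset construction, and classification, with a shared evaluation
suite. A seeded synthetic-image generator stands in for real sections so the
whole chain is testable and reproducible without microscope data.

## Preprocessing

Input is an RGB section plus a manually annotated bounding box (conditioning
— rotation, centring, resizing — is assumed done upstream; the box is an
input, not a detection). Four deterministic stages:

1. **Value channel.** `I_V = max(R, G, B)` per pixel (the HSV value
   channel, 0–255), cropped to the box. This removes dependence on stain hue
   and amount: pink and purple tissue reduce to the same grey scale.
2. **Negation.** `I_NV = 255 − I_V`, so the stained band becomes *bright*.
3. **Background homogenization.** Slow illumination and staining gradients
   are removed from `I_NV`: a 3×3 mean filter, a 9×9 Gaussian kernel
   (σ = 1.8), subtraction of a background estimate from a large mean filter
   (default 69×69), then a histogram shift that maps the residual's mode to
   mid-grey (128), clipped to [0, 255]. All window sizes are configuration
   parameters; the large-window size must not exceed the crop.
4. **Enhancement.** White top-hat `I_HE = I_H − opening(I_H, disc r = 8)`.
   The disc is `{(i,j): i² + j² ≤ 64}` (197 pixels). Opening removes every
   bright structure the disc fits inside, so the subtraction keeps only
   structures thinner than ~17 px — the band — and flattens wide tissue
   regions.

All filters and the morphology use reflect padding, so crops have no
zero-halo artifacts at their borders. Every stage is shape-preserving and
bitwise deterministic.

## Feature extraction

Each pixel `(x, y)` yields `F = (f1 … f14)`:

* `f1–f5` from `I_HE`, using the 9×9 window `S` centred at the pixel:
  `f1 = I(x,y) − min S`, `f2 = max S − I(x,y)`, `f3 = I(x,y) − mean S`,
  `f4 = std S` (population σ), `f5 = I(x,y)`.
* `f6, f7`: the 17×17 patch around the pixel is multiplied elementwise by a
  Gaussian weight matrix (σ = 1.7, peak normalized to 1; its central 9×9
  block carries ≈98.6% of the total weight, so the weighting localizes the
  computation). From the weighted patch the first two Hu moment invariants
  are computed with intensity-weighted moments: central moments about the
  intensity centroid, `η_pq = μ_pq / μ00^{1+(p+q)/2}`, `φ1 = η20 + η02`,
  `φ2 = (η20 − η02)² + 4η11²`. A zero-mass patch returns (0, 0). The
  features are the signed logs `sign(φ)·ln|φ|`, with |φ| < 1e−30 mapped
  to 0 to avoid overflow. Natural log is used; the base is a monotone
  per-feature rescaling that standardization largely absorbs.
* `f8–f14`: the same seven quantities computed from `I_NV`. These retain
  the *pre-enhancement* brightness context, which is what separates the
  band from look-alike structures embedded in differently shaded
  surroundings.

Images are reflect-padded so every pixel of the crop is featurizable.
Features are standardized to zero mean and unit (population) variance with
statistics fitted on the training split only; a constant feature is flagged
degenerate and mapped to 0.

## Dataset construction

All mask-positive pixels across the corpus are featurized as C1; an equal
total number of negatives is sampled uniformly without replacement from the
remaining pixels of the cropped regions (pooled across images by default; a
per-image-balance option exists). The balanced set is split 70/20/10 per
class — `floor(0.7 n)` / `floor(0.2 n)` / remainder — by a seeded shuffle,
so stratification and exact balance hold in every split. Pixel coordinates
and source-image names travel with the tables for debugging but are never
model inputs.

## Classifiers

Seven fixed configurations (hyperparameters are the final values of the
original search, hard-coded as defaults):

| family | configuration |
|---|---|
| MLP | 14→31→68→13→7→1, ReLU hidden, sigmoid output, Adam + binary cross-entropy, 37 epochs; 3,644 trainable parameters |
| RBFN | 71 Gaussian hidden units; centres by seeded k-means; shared width σ = d_max/√(2k) (switchable to the literal d_max/2k); sigmoid output trained by mini-batch RMSprop on MSE, 200 epochs |
| RF | gini, ⌊√F_n⌋ = 3 features per split, min 1 sample per leaf, unbounded depth |
| SVM linear | C = 182, squared hinge, l2 |
| SVM poly-features | linear SVC (C = 172) on the full degree-2 monomial basis (120 columns for 14 inputs, bias included) |
| SVM poly-kernel | degree 3, C = 2.1, γ = 1/(C_n·σ²) with C_n = 14 and σ² the training-feature variance, independent term b = 40 |
| SVM RBF | C = 182, γ = 1/(C_n·σ²) |

Notes on choices that the printed configurations leave open or state
inconsistently:

* **RBFN centre selection** is k-means (k = 71). A nearest-neighbour rule
  is not a clustering algorithm; k-means is the standard construction for
  an RBFN hidden layer built unsupervised.
* **RBFN width.** The d_max/2k form gives widths an order of magnitude too
  narrow for 71 centres; the Broomhead–Lowe form d_max/√(2k) is the
  default, with `sigma_rule="literal"` available. Either way the heuristic
  presumes data of low intrinsic dimension (as correlated pixel features
  are); on isotropic high-dimensional inputs the hidden layer goes silent.
* **RF minimum samples per split** is 2: a 1-sample node cannot split, so
  2 is the smallest value with identical behaviour.
* **MLP/RBFN training details not fixed by the configuration** (batch size
  32, Adam/RMSprop at their conventional defaults, seeded initialization)
  are configurable; every stochastic element is seeded, and training twice
  with the same seed is bitwise reproducible.
* **Scores.** `predict` returns values in [0, 1]: class probabilities
  where the estimator provides them, otherwise the decision margin through
  a sigmoid — a strictly monotone map, so SVM ROC curves are those of the
  raw margins. Hard labels threshold the score at 0.5 (margin 0).
* A 7-feature ablation mode (`n_features=7`, the `I_HE`-derived features
  only) is supported by every family for the feature-set comparison.

## Evaluation

Standard definitions throughout: recall (TPR) = TP/(TP+FN),
precision = TP/(TP+FP), FPR = FP/(FP+TN), accuracy = (TP+TN)/total, F1 the
harmonic mean of precision and recall, with zero-denominator cases returning
0 and a degeneracy flag. The ROC sweeps all distinct score thresholds in
descending order (tied scores form one step); AUC is the trapezoidal area,
which equals the Mann–Whitney pair-ordering probability with ties counted
half. The feature-set comparison table reports per-family test accuracy at
7 and 14 features, their difference, and the cross-family mean.

## Synthetic image generator

The generator emulates the conditions that make real sections hard, not
their photorealism:

* pink textured background (smooth Gaussian-filtered noise), per-image
  brightness gradient of random direction (0–30%), hue/saturation jitter;
* one target band: a cubic spline through control points on a randomly
  jittered C/S arc, stroked at a thickness drawn from 3–8 px, darkened by
  40–70% of the local background, with a 1.5 px feathered edge (fuzzy
  boundaries). Exactly these pixels form the ground-truth mask;
* look-alike distractors (default 1): the same band generator, drawn
  elsewhere, *excluded* from the mask, and embedded in a diffuse darkened
  halo — after background removal the distractor band resembles the
  target, but its `I_NV` context differs, which is what gives the second
  seven features their value;
* Gaussian pixel noise (σ = 4 grey levels) and occasional bright streak
  artifacts (rate 0.3);
* the bounding box encloses the target with a 20 px margin, mirroring a
  manual annotation.

Colour ratios are chosen so `max(R,G,B)` equals the constructed brightness
field exactly; palettes are configuration, not claims. Defaults are
512×416 px per image and 25 images per corpus (a typical digitized study
series). What the generator does **not** model: staining chemistry, cell
morphology and texture at the band scale, out-of-focus blur, or spatial
correlation between neighbouring sections — so passing benchmarks show the
pipeline's mechanics and relative feature value, not clinical performance
on real tissue.

## Benchmark profile and problem sizes

The end-to-end benchmark used by the test suite and by
`scripts/acceptance.py` (`pipeline.benchmark_config`) runs the generator at
256×208 px with 25 images. At that resolution each band covers roughly
1,000 px, so the balanced dataset lands near the ~50k-feature scale of a
full pixel-classification study while keeping the four kernel-SVM fits
tractable on a single CPU; a run takes a few minutes. Reproducibility is
verified byte-for-byte on a smaller 4-image corpus, since determinism does
not depend on problem size.

## Numerical choices and degenerate inputs

* Population (÷N) standard deviation everywhere (`f4` and
  standardization).
* Homogenization's histogram correction uses the mode of the
  integer-rounded residual; a constant image maps to a constant 128.
* Top-hat output is clipped to [0, 255]; it is non-negative and pixelwise
  ≤ its input by construction.
* An all-positive mask (no negatives to sample), coincident RBFN centres,
  single-class ROC inputs, empty confusion tables, and stage-order
  violations all raise informative errors rather than returning numbers.
* Split fractions must be positive and sum to 1 (tolerance 1e−9); each
  class needs at least 10 members.

## Known limitations

* The synthetic benchmark is easier than real histology: reported
  accuracies there (~0.97–0.99) exceed what real sections yield and should
  be read only through the *relative* statements the tests make (every
  family trains; 14 features ≥ 7 features on average).
* Bounding-box annotation and image conditioning are inputs by design;
  there is no automatic hippocampus localization.
* Only φ1 and φ2 of the Hu family are used; no feature selection or
  ensembling is provided.
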