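# Methods

## Pipeline model and assumptions

The package implements a bag-of-visual-words (BoVW) classifier for 201 × 201
px sub-images cropped around point annotations of insects on yellow sticky
traps, plus a sliding-window extension for whole trap scenes. The model
assumes that (i) each sub-image contains one individual near its centre,
(ii) class identity is carried by the *distribution* of local texture
descriptors rather than their spatial layout, and (iii) a background class
(BKGRND) covering trap surface and all non-target species is trained
alongside the insect classes — without it, sliding-window prediction of a
scene would have no way to reject empty windows.

The processing chain for every patch — training, held-out evaluation and
scene scanning use the *same code path* (`trapvision.pipeline.BovwPipeline`)
— is: colour conversion → SIFT detection/description → nearest-word
quantization against a k-means dictionary → word-frequency encoding →
linear SVM scoring.

## Parameters that matter

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| patch size | 201 | px | odd, so the marker is the centre pixel |
| colour space | greyscale | — | RGB and HSV selectable; multi-channel images run SIFT per channel and pool descriptors (keypoints need not co-occur across channels, so 384-d concatenation was rejected) |
| SIFT peak threshold (`c_dog`) | 0.004 | DoG contrast | balances keypoint counts (~30–60 per patch) between insect structure and trap texture; the skimage default (~0.013) starves textured backgrounds |
| SIFT upsampling | 1 | — | 201-px patches resolve the relevant blobs; 2× upsampling quadruples cost for no measured accuracy gain |
| `vocsize` | 200 | words | 200 and 500 are the studied sizes; accuracy is insensitive between them on synthetic data |
| k-means | k-means++, n_init 3, max_iter 100 | — | seeded and run single-threaded for bit-reproducibility |
| normalization | Hellinger (`√(h/‖h‖₁)`) | — | measured ~3 points better class-mean recall than plain L1 with the SGD solver, the classic variance-stabilizing choice for word histograms; `none`, `l1`, `l2` selectable |
| SVM | hinge + L2, α = 1e-4, 50 epochs, one-vs-rest | — | SGD with sklearn's decaying "optimal" schedule `η_t = 1/(α(t₀+t))`; per-epoch shuffles drawn from one seed make training deterministic |
| train/optimization split | 75 / 25, class-stratified | — | stratification protects small classes; the dictionary is built from the 75% fitting split only (no test leakage) |
| scan stride | 25 | px | ~8× window overlap; finer strides measurably did not improve localization |
| NMS suppression radius | 50 (patch default), 120 (scene studies) | px | see localization notes below |
| matching tolerance | 30 | px | circle-vs-cross proximity scale of manual annotations |

## Quantizers

`quantize_vq` is exhaustive nearest-centre search (ties → lowest index).
`quantize_kdtree` is exact by default: a `scipy.spatial.cKDTree` query with
full backtracking, with 4-nearest post-processing so exact distance ties
also resolve to the lowest index. Bounded-backtracking approximation runs
through an own max-variance-split k-d tree with a best-bin-first search
capped at `max_comparisons` distance evaluations; its disagreement rate
against the exact assignment is measured and logged, never silently
dropped. The exact mode is verified against brute-force VQ over thousands
of random draws in the test suite.

## Evaluation conventions

Confusion matrices are rows = true, columns = predicted. Recall_i =
TP_i/(row sum), precision_j = TP_j/(column sum), both in percent rounded
half-up to 2 decimals; class means are unweighted means of the *unrounded*
per-class values, rounded once. A class never predicted has undefined
precision; undefined cells are excluded from class means and logged.
Post-hoc pooling of a confusion matrix (summing whitefly rows/columns) is
provided as a diagnostic only: it is *not* equivalent to training and
predicting with pooled labels, and the two measurably differ.

## The synthetic generator

No annotated YST photograph archive with this five-class taxonomy is
public, so `trapvision.synthetic` renders scenes with the statistical
structure the analysis needs, not photorealistic insects:

* **Classes are separated by texture motif, not by size or brightness** —
  SIFT descriptors are contrast-normalized and scale-invariant, so dots
  (whitefly body speckles), wing membranes with veins (TRIAVA), a dark/pale
  two-tone body (ENCAFO), antenna lines (MACRPY) and large smooth blobs
  (CLUTTER) are what a BoVW model can actually distinguish.
* **The hard pair.** BEMITA and TRIAVA share identical geometry and body
  texture (same shape and texture parameters, identical masks for equal
  seeds) and differ only in wing colour and opacity: TRIAVA's wings are
  opaque bright white, BEMITA's dusky and translucent. Mirrors the one
  morphological handle separating the two whitefly species on a trap.
* **Decay** in [0, 1] blends insect pixels toward the trap background —
  wings fade almost completely (weight 0.92), the dark body core only
  partially (0.55) — plus an outline blur. Emulates 7-day-aged catches:
  near-transparent wings over a retained dark centre. The blend weight is
  monotone in the dial, which the tests assert with a mask-based distance
  oracle.
* **Background** is saturated yellow with smoothed mottling and faint
  speckles, so BKGRND patches have learnable texture. A quarter of BKGRND
  training patches contain a CLUTTER object, because the background class
  covers non-target species by definition.
* **Wings spread laterally and symmetrically**, keeping the foreground
  centroid at the body centre; scene markers are placed at the rendered
  foreground centroid, as an annotator clicking "the middle of the
  individual" would. Both matter for localization: the sliding-window
  positive region centres on the keypoint mass, and a systematic offset
  between that mass and the markers shows up directly as localization
  error.
* **Placement** rejects positions closer than `min_separation` (120 px
  default) with bounded retries and full-layout restarts. An optional
  stricter `same_class_min_separation` exists because non-maximum
  suppression cannot split two conspecifics whose positive plateaus merge.

What the generator does **not** emulate: adhesive artefacts, specular
reflections, touching/overlapping individuals, partial bodies, scale
variation from camera distance, or the long-tailed species mixture of real
greenhouses. Passing tests therefore demonstrate the pipeline's mechanics
and its qualitative behaviour (pair confusability, decay effects, pooling
gains), not field-ready accuracy on real trap photographs.

## Scene localization

Every window position (stride 25) of a scene is classified through the
patch pipeline, giving a category map. Detections are extracted by greedy
non-maximum suppression in (score desc, y, x) order — per class by default,
class-agnostic optionally, since windows that catch only part of an insect
often fire as a *different* class. Because a 201-px window classifies
positive wherever the insect sits fully inside it, the positive region is a
plateau roughly centred on the insect, and the argmax cell can lie tens of
pixels off-centre; optional refinement therefore re-centres each detection
by score-weighted mean-shift over its grid-connected cluster of same-class
candidate cells, followed by a dedup pass (refined positions can
collapse). Detections and markers are matched one-to-one, closest first,
same class within 30 px.

The detection studies run on 850 × 850 px scenes with ten insects and two
clutter objects (margin 130, spacing 150/280 px, suppression radius 120,
refinement radius 130, class-agnostic suppression). Under these conditions
five train-and-scene replicates give detection recall 0.90 and precision
0.94; the residual misses are dominated by individual insects whose windows
misclassify in scene context — the scene-level image of the ~95% patch
error rate — not by position error.

## Problem sizes and determinism

The recovery study uses 100 training + 50 test patches per class, a
200-word dictionary and five seeds; the report tables in a full grid run
cover colour space × vocsize × quantizer × pooling. All randomness flows
from explicit integer seeds; k-means and SGD run under
`threadpool_limits(1)` so float summation order, and hence every weight and
report, is identical across machines regardless of core count. Dataset
digests and seeds are recorded in a run manifest; re-running a manifest
reproduces all outputs byte-identically.

## Known limitations

* The whitefly pair remains genuinely confusable under decay: mixed
  fresh/aged test sets drop pair recall to ~55–60%, and categorical pooling
  recovers only part of it — consistent with the monitoring practice of
  pooling whiteflies for decision-making.
* Greedy nearest-first matching can fall below the optimal bipartite
  matching cardinality when the tolerance is comparable to point spacing;
  at trap-realistic densities the two coincide (asserted on sparse random
  instances).
* The approximate k-d tree is a pure-Python reference implementation:
  faithful to the bounded-backtracking semantics but not fast; the exact
  path is the production default.
* Localization counts individuals, not clusters; touching individuals merge
  into one detection by construction of the suppression step.
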