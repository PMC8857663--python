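# Methods

`spinepost` implements the downstream half of an automatic thoracolumbar
spine-delineation workflow on CT: everything that happens *after* a
segmentation network has produced voxelwise predictions. The networks
themselves are out of scope; a plug-in seam (any command or callable that
maps a CT volume to a binary and/or level-coded labelmap) is where they
would attach. The bundled stand-in is a synthetic corruption model applied
to phantom ground truth, which makes the entire pipeline testable offline.

## Problem setting

Automatic spine delineation splits into *segmentation* (vertebra voxels vs
background) and *labeling* (which vertebral level each vertebra is:
T1–T12, L1–L5). Network output commonly fails in characteristic ways:
adjacent vertebrae fused into one region, small spurious islands, eroded or
dilated boundaries, and locally wrong level votes. The post-processing here
repairs the segmentation, then derives one consistent level sequence.

Two strategies are supported:

- **sequential**: geometry from a dedicated binary segmentation, levels
  from a separate level-coded prediction;
- **combined**: a single level-coded prediction supplies both — it is
  binarized, refined identically, and then re-consulted for levels.

Both share the refinement code path by construction.

## Conventions

Arrays are `(x, y, z)` with axis 2 craniocaudal and increasing index
superior. Instance ids run 1..n from superior to inferior, so level codes
(1 = T1 … 17 = L5) increase with instance id. All distances are in mm
using voxel spacing; voxel centres sit at `index * spacing`.

## Preprocessing

`resample_isotropic` maps to an isotropic grid of shape
`ceil(shape × spacing / t)` — linear interpolation for intensities, nearest
neighbour for labels (labels are never blended). The default target is
1 mm, the resolution regime the pipeline is designed for.
`normalize_intensity` maps a CT window affinely onto [−0.5, 1.5] and clips;
the window is a free parameter with default (−1000, 1000) HU, a symmetric
2000-HU window spanning air to dense bone. Nothing downstream of the demo
CLI depends on intensities, so the choice of window only affects what a
network plug-in would see.

## Instance refinement

`refine_binary` = extract → filter → split → filter.

1. **Components** under 26-connectivity by default (bulky objects; diagonal
   leaks are the realistic fusion mode). Ids assigned craniocaudally.
2. **Candidate filter**: volume within [5, 120] cm³, a wide bracket around
   a thoracolumbar vertebral body (~10–25 cm³ at typical sizes); instances
   touching the volume boundary are exempted down to 1 cm³, because partial
   vertebrae can be arbitrarily truncated. Centroids must lie within 25 mm
   of a fitted spine axis (least-squares quadratic `x(z)`, `y(z)` through
   the size-passing centroids; skipped below three candidates). Removals
   are logged with voxel counts.
3. **Fusion splitting**: an instance whose craniocaudal extent exceeds
   1.6 × the expected body height (default 28 mm) is a suspected fusion.
   Markers are the craniocaudal peaks of the interior Euclidean distance
   transform (per-slice maxima, peaks closer than 0.8 × expected height
   suppressed; ties to the larger distance value, then the lower index),
   and a marker-controlled watershed on the negated distance transform
   partitions the voxel set exactly — no voxel is lost or gained, which is
   asserted at run time. A suspect with a single distance peak passes
   through unchanged with a warning. The watershed floods with the same
   connectivity as component extraction, otherwise diagonal-only necks
   would be left unassigned.

All thresholds live in `RefineConfig`. The kinds of criteria (size,
position, inter-region distance) are fixed by the design; the numeric
defaults are this package's own calibration for vertebral bodies and are
deliberately loose.

Refinement never adds foreground and is idempotent on its own output; both
properties are tested.

## Level assignment

Per instance, `level_consensus` takes the modal nonzero predicted level and
its fraction of the instance's predicted-foreground voxels. Instances with
consensus ≥ 0.95 (configurable) are **anchors** and considered true.

`propagate_labels` then picks one *winning* anchor — highest confidence,
ties to the most superior — and labels every instance by counting positions
from it: `level_i = winner_level + (i − winner_index)`. Alternatives
existed here: each anchor could keep its own level, with propagation only
filling gaps. That variant cannot reproduce the pipeline's characteristic
failure mode, in which a single merge shifts *every* vertebra on one side
of it by one level even where local consensus was perfect — a mechanism
that requires confident votes to be overridable by the global count. The
single-winner rule reproduces it mechanically, is deterministic, and every
overridden anchor is logged. If no anchor exists, labeling fails loudly
rather than guessing; a sequence running past T1 or L5 is an error.

## Evaluation

- `dice`: 2|A∩B|/(|A|+|B|), 1.0 when both masks are empty.
- `hausdorff`: classical maximum over both directed surface-to-surface
  distances, surfaces being foreground voxels with a background 6-neighbour
  (grid borders count as background). A 95th-percentile variant is
  available but not the default. Undefined for empty masks; callers record
  those as missing.
- `match_and_score`: each fully visible ground-truth vertebra is matched to
  the predicted instance of maximal overlap (ties by centroid distance —
  the matching rule is a package choice). Edge-contacting vertebrae are
  excluded from scoring by default. Label bookkeeping separates *causal*
  rows (inside a merge, or missing) from *offset-attributed* rows: maximal
  runs of ≥ 2 consecutive vertebrae sharing one signed nonzero offset,
  adjacent to a causal row. Offset rows keep their geometric DSC/HD — they
  are scored as if their labels were correct — while causal rows are not
  offset-eligible. Vertebrae with no overlapping prediction score DSC 0
  with HD flagged missing and `not_evaluable` set.
- Statistics: labeling accuracy with a Wilson binomial CI; paired DSC/HD
  comparisons with a two-sided Wilcoxon signed-rank test (Pratt
  zero-handling; all-zero differences flagged degenerate with p = 1);
  review contingency tables with chi-squared (Yates continuity correction
  on 2×2 by default). All method choices are configurable and recorded.

## Subjective review protocol

`build_review_session` draws, per level T1..L5, three slices with a human
contour and three with an automatic contour from caller-supplied pools
(102 items for a full 17-level protocol), shuffles them with a seeded
permutation, and stores the blinding map separately from the presented
list. Ratings use a 4-point scale (1 large obvious errors; 2 minor errors
needing correction for high-precision radiotherapy; 3 minor, clinically
not significant; 4 precise); clinical acceptability is a rating of 3–4.
`analyze_review` reports source-identification accuracy, per-source rating
distributions and acceptability, and chi-squared comparisons. A simulated
random guesser converges to 0.5 identification accuracy, which the tests
use as a calibration check.

## Synthetic phantoms

`generate_phantom` emulates the geometry the pipeline cares about, not
radiological realism. Vertebral bodies are superellipsoids (exponent 4 —
squat rounded boxes, the shape family that makes watershed behaviour
representative) with default semi-axes (16, 14, 11) mm, stacked along the
craniocaudal axis with a 4 mm disc gap (centre pitch 26 mm), consecutive
levels from a configurable first level. `partial_at_edges` truncates the
top and bottom bodies at the volume faces and records the contact.
Intensities are cosmetic: soft tissue ≈ 40 HU, trabecular interior
≈ 250 HU, a ~2 mm cortical shell ≈ 700 HU, Gaussian noise σ = 20 HU.
Default voxel size 1 mm isotropic.

`corrupt_prediction` turns ground truth into simulated network output:
cylindrical bone bridges (default radius 3 mm) fusing chosen adjacent
pairs; per-instance random erosion/dilation up to a magnitude in mm;
per-instance voxel dropout; spurious islands (3–8 mm radius) placed clear
of the spine, as distant false positives are in practice; and, in the
level output only, mislabel mixing that flips a chosen fraction of an
instance's voxels to a substitute level. One seed drives everything;
identical spec + seed is bit-identical.

What the phantoms do *not* model: real trabecular texture, pathology
(metastases, fractures), posterior elements, curvature of a scoliotic
spine, slice-thickness anisotropy artefacts. Passing the phantom suites
therefore demonstrates the correctness of the post-processing logic, not
clinical-grade performance; on clinical data the upstream network, not
this pipeline, dominates error rates.

## Problem sizes and determinism

Test and acceptance phantoms are generated at 1.5 mm isotropic spacing
with the physical geometry unchanged (grids of roughly 38×35×(80–330)
voxels); this is the package's chosen working size for its verification
suites, and every suite is seeded. The acceptance script derives all
randomness from the single `--seed` argument. The test suite runs in about
half a minute; `scripts/acceptance.py` in about 20 seconds.

## Known limitations

- The winning-anchor rule means one confidently mislabeled instance that
  happens to win can shift the whole sequence; the logs expose this, the
  pipeline does not attempt to detect it (error-detection post-processing
  is an explicit non-goal).
- The spine-axis fit is plain least squares and can be pulled by a large
  off-axis blob when candidates are few; size filtering removes most such
  blobs first.
- Watershed marker detection scans craniocaudal distance-transform peaks;
  a fused pair truncated at the volume edge can present a single peak and
  pass through unsplit (logged).
- Only axis-aligned geometry is supported; reorientation beyond flips and
  permutations is out of scope, as are DICOM series and RT-STRUCT I/O.
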