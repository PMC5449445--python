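# Methods

## Model of the data

A microfluidics time-lapse series is modelled as a rigid motion of a static
chamber observed through a noisy sensor: frame *t* shows the chamber content
of frame 1 mapped by an unknown rotation + translation (drift), with the
biological foreground (a bacterial colony that doubles per generation)
changing freely on top. Registration therefore needs anchors that are (a)
fixed relative to the chamber and (b) detectable under low SNR — the
chamber's spacers, large square-like structural elements. Everything else
(cells, background texture, illumination) is treated as a distractor.

The estimated correction per frame is a full 2×3 affine transform. Three
point correspondences determine it exactly; using the affine family rather
than a constrained rigid family costs nothing when the motion is rigid and
absorbs small residual shear from detection error.

## Pipeline and its assumptions

**Preprocessing** (per frame): grayscale → bilateral filter → CLAHE →
adaptive mean threshold → 3×3 dilation → border clearing → central circular
mask. Parameters, with defaults:

| parameter | default | units | role |
|---|---|---|---|
| `sigma_spatial`, `sigma_range` | 75, 75 | px, intensity | bilateral kernel widths; at these values the filter is close to a box mean over the neighborhood, suppressing sensor noise ~9× while preserving edges stronger than the range scale |
| `bilateral_diameter` | 10 | px | neighborhood diameter (circular) |
| `clahe_tile`, `clahe_clip` | 10, 2 | px, bin-ceiling multiple | local contrast boost; clip 2 limits noise amplification |
| `thresh_block`, `thresh_const` | 11, 2 | px, intensity | pixel vs. local block mean − c |
| `dilation_window` | 3 | px | closes small gaps in the binarized structures |
| `mask_diameter_fraction` | 0.6 | of image rows | keeps only central components, where spacers live |
| `invert` | False | — | threshold polarity, see below |

**Threshold polarity.** With foreground = *below* local mean − c (dark
structures), white sensor noise at σ = 8 leaves ≈1–2 % of background pixels
foreground; after 3×3 dilation these speckles percolate into chains that
merge with spacer outlines and randomly delete cues. The default is
therefore foreground = *above* local mean − c: the background becomes one
giant component that border clearing removes wholesale, noise dips become
interior holes (invisible to outer-boundary tracing), and each spacer
survives as its cleanly enclosed interior plateau. The polarity is a config
switch because real chambers vary; the dark-foreground mode remains
available and correct for low-noise data.

**Polygon finding.** Moore-neighbor border following (8-connectivity,
Jacob's stopping criterion) extracts one closed outer boundary per
component, in raster discovery order. Inner boundaries (holes) are never
emitted. Components with fewer than 5 boundary pixels or enclosing less
than 0.5 px² are discarded as noise. Perimeter is the Euclidean length of
the closed pixel chain; area is the absolute shoelace sum. The cue filter
keeps polygons with perimeter/area strictly below 5·10⁻² px⁻¹ and falls
back to the full polygon list when nothing passes, so a frame with any
polygon always keeps a candidate.

**Cue anchors.** A cue's anchor is the *area (shoelace) centroid* of its
boundary polygon, not the vertex mean: border-following chains are ragged
at the pixel level, and a noise notch contributes many boundary vertices
but almost no area. Measured on the synthetic preset, the vertex mean
jitters by up to ±2.6 px per frame while the area centroid stays within
about ±0.3 px — the difference between a usable and an unusable anchor at
sub-pixel accuracy targets.

**Correspondence and its trust radius.** Cues of consecutive frames are
matched by optimal assignment (Hungarian) on their anchors. A matched pair
is trusted only if its displacement is below half the smallest inter-cue
spacing: the method assumes the cues of consecutive frames are "the same
ones", and beyond half the spacing a vanished cue would silently pair with
a *different* spacer. Untrusted pairs are dropped; the surviving common
subset is used for the solve. The same mechanism bridges boundaries where
the cue count J changes, so length-1 runs do not break the chain. A
displacement at or above half the image width raises an error outright —
past that shift the original cues may have left the visual field entirely.

**Control points.** J = 1: the first three corners of the cue's minimum-area
oriented bounding box (rotating calipers; corners ordered counterclockwise
starting nearest the polygon's own min-x/min-y anchor, which makes the
ordering translation-equivariant). J = 2: the first OBB corner of each cue
plus the second corner of the first — two cues alone give only two points,
and this third point is non-collinear for any non-degenerate OBB. J ≥ 3:
cue centers, reduced to the three spanning the maximum-area triangle
(deterministic, ties broken lexicographically). The triple's index set is
pinned once per constant-J run: using the *same* three cues in every
pairwise solve makes the composed chain exact on the control cues
(pairwise exactness telescopes), while the max-area choice minimizes
extrapolation leverage at the remaining cues. Control triples whose
triangle area falls below 1 px² abort the pair with a degeneracy error.

**Solve, chain, refine.** Each pairwise transform is the exact solution of
the 6×6 linear system from three correspondences (residual verified below
1e-9 px). Pairwise transforms are composed left-to-right to the reference
frame; the chained transform then serves only to establish which detected
cue corresponds to which reference cue, and the final per-frame transform
is re-solved in one step against the reference frame's cue set — by the
exact three-point solve when three cues match, by least squares over all
matched cue centers when more do. The one-step re-solve removes the random
walk that per-pair detection jitter would otherwise accumulate at
non-control cue positions (measured on the preset: worst-case ground-truth
error drops from ≈0.66 px to ≈0.36 px). Frames whose chain is broken (no
cues, untrustworthy correspondence) are flagged `unregistered` and passed
through unwarped — never silently dropped.

**Warping** is inverse-mapped bilinear resampling with zero fill, applied
channel-wise to RGB payloads; binary masks use nearest-neighbor to stay
binary. Transforms are kept in double precision end-to-end; warping is the
only lossy step.

## Evaluation metrics

Per registered frame, rmsd is the root mean square Euclidean distance
between its cue anchors and the reference frame's, matched by optimal
assignment (so cue labels are irrelevant); the mean runs over frames 2…T
because the reference's self-comparison is identically zero. Image
closeness Φ = 100 − rmsd·100/r (r = image rows) rescales rmsd to a percent
score, 100 at perfect registration, affine in rmsd with slope −100/r.
Elapsed seconds per frame are recorded and reported but never used as a
quality criterion — they are hardware-dependent.

The probabilistic Hough baseline reduces each frame to Canny edges
(σ = 3, absolute thresholds 6/14 — permissive enough for soft chamber
edges under σ = 8 noise, strict enough not to drown in noise edges), runs
the probabilistic Hough transform (minimum segment length 100 px, gap 3,
votes 30), collapses near-duplicate segments into infinite lines (angle
within 5°, offset within 12 px), and takes the four strongest pairwise
line intersections inside the image as feature points — "a best fitted
subset of points": raw probabilistic segment endpoints are unstable along
the line direction, whereas line intersections (chamber corners) are
stable. Points are matched across frames by assignment and a rigid
(rotation + translation, unit scale — the instrument fixes scale)
transform fitted by least squares. Fewer than two lines or four stable
intersections in any frame raises `BaselineFailureError` naming the frame:
this failure on line-free scenes is the baseline's documented,
*expected* behavior, and benchmark reports record it as `failed` rather
than as a zero score.

## The synthetic scene generator

`synthetic_data` renders what the pipeline needs to be tested against:
1004×1002 px frames; four dark square spacers (side 115–140 px, soft
edges of σ = 1 px) on a ring of radius 165 px around the image center —
inside the circular mask for the whole drift range, outside the colony's
final extent; a colony of bright ellipses growing from one cell with a
doubling period of 10 frames, capped at 300 cells (a structured distractor
with no role in the ground truth, exactly its role in real data); a
background illumination gradient fixed in chamber coordinates; rigid drift
as a *cumulative random walk* (≤3 px translation and ≤0.3° rotation per
frame — thermal drift, not i.i.d. jumps); and per-frame additive Gaussian
noise of σ = 8 intensity levels, added after the geometric mapping because
sensor noise is not transformed. Geometry is transformed analytically and
then rasterized, so the recorded ground-truth transforms and spacer
anchors are exact. All randomness flows from one seed; renders are
bit-identical across runs.

Spacer sides default to 115–140 px because the *detected* cue is the
spacer's interior plateau, 10–14 px smaller than the drawn square, and
pixel-chain raggedness inflates the measured perimeter by ≈10 %; sides in
this range keep every spacer's measured ratio safely below the 5·10⁻²
filter, which is the defining property of a cue spacer. Options exercise
specific behaviors: `cue_count_schedule` changes the number of visible
spacers per frame (interval adaptability), `spacer_shape="disk"` produces
a line-free scene (baseline failure mode), `chamber_walls=True` adds a
straight-edged rectangle (baseline success mode), `drift_mode` switches
between random walk, linear translation and none.

What the generator does **not** emulate: phase-contrast halo artifacts and
the point-spread function, focus drift over time, background texture of
real chamber surfaces, cell motility and death, and intensity
nonstationarity. Passing tests therefore demonstrate correct geometry
recovery under realistic noise, drift and foreground growth — not
robustness to every optical artifact of real microscopes; on real data the
preprocessing constants (particularly polarity, circle-mask fraction and
threshold constant) are the knobs to revisit.

## Test problem sizes

The test suite runs the full-size preset (1004×1002, T = 30, five seeds)
for drift recovery, a 12-frame full-width scene for the 4→6 cue-count
switch, 5- and 3-frame scenes for the baseline's success and failure
modes, and an 8-frame zero-drift scene for the no-op check; unit tests use
512×512 scenes (spacers unchanged in size, circle mask widened to 0.9 so
they fit) and ≤64×64 images for the double-loop filter oracles. The
static no-op scene uses σ = 1 noise: its purpose is to verify that no
motion is invented when none exists, a property that detection jitter at
full noise would mask; noise robustness itself is covered by the σ = 8
drift-recovery test.

## Known limitations

* Registration accuracy is bounded by cue-anchor measurement error (~0.2–
  0.4 px per frame on the synthetic preset), and the reference frame's own
  detection error enters every frame's correction.
* The affine is fitted from at most the matched cue set; scenes with a
  single cue rely on OBB corner stability, which degrades for near-square
  cues under rotation (corner identity can swap near 45° symmetry).
* A frame with no trustworthy correspondence breaks the chain for all
  downstream frames; there is no global (bundle-adjustment style)
  re-optimization, by design.
* Deformable motion, scale change and intensity-based refinement are out
  of scope.
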