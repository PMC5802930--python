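# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of the `ridgetrack` pipeline, in the
order the data flows through it.

## Imaging model and coordinate conventions

The device and camera are fixed, so frames share a static background up
to slow illumination drift; no registration or deformation correction is
attempted. All pixel coordinates are 0-based with the origin at the
top-left corner; `x` is the column index and points along the flow
(left → right; a config flag flips the sign for mirrored recordings),
`y` is the row index. Centroids are real-valued under the pixel-center
convention — sub-pixel motion matters for scoring. Color input is
reduced by the channel mean (recordings are expected to be grayscale;
any reduction is a fallback). Uncalibrated recordings report speeds in
px/frame and distances in px; physical units are used only when a frame
rate and pixel size are supplied, never fabricated.

## Foreground identification

* **Background** (`window`, default 300 frames): per-pixel temporal
  median over an index window centred on the frame, clipped (not
  shifted) at the sequence ends so boundary frames use the available
  subset. The window is expressed in frames, not seconds: the method is
  insensitive over a wide range, but a cell stalled for more than about
  half the window bleeds into the background estimate.
* **Detection** (`sd_k`, default 3): the frame is regressed on its
  background by ordinary least squares with intercept over all pixels,
  which absorbs global gain/offset drift and makes the mask invariant to
  affine intensity rescaling of the frame/background pair. Residuals are
  fitted by a Gaussian using the plain sample moments (not a robust
  estimator — the foreground fraction is small and the moments are the
  simplest faithful fit); pixels beyond `sd_k` standard deviations are
  foreground. The threshold is two-sided by default since cells can be
  brighter or darker than background; one-sided modes exist. A
  zero-variance background degrades to an intercept-only fit.
* **Cleaning**: a `median_size` (default 5×5) binary median filter
  removes speckle and, as a side effect, anything smaller than ~4 px; an
  explicit `min_pixels` (default 4) guard makes that contract testable
  independently of the filter. Holes — background regions not connected
  to the border — are filled to recover low-contrast cell interiors.
  Note the filter erodes up to 3 px at sharp corners of a rectangular
  region (a 12×12 square retains 132/144 px); blob-shaped cells lose
  only a thin boundary ring.
* **Events**: connected components (8-connectivity by default;
  4-connectivity available for sensitivity checks) with features
  computed from the member pixels of the original intensity frame.
  `event_id` follows raster order; `cell_id` starts unassigned.

## Matching and scoring

Candidate links require the target to be *nearby* — center distance
within `nearby_factor` (default 5) times the larger of the two radii,
which sets the maximum trackable speed — and downstream up to a slack.
The effective slack is `max(upstream_slack, larger radius)` with
`upstream_slack` defaulting to 1 px: the 1-px term absorbs sub-pixel
jitter of slow cells, while the radius term is required because the
centroid of a freshly formed collision aggregate lies up to its radius
*behind* its forward-most member; with a constant 1-px slack the leading
cell of every collision would be forced to "disappear".

All admissible matching sets are enumerated exactly: subsets of the
candidate adjacency in which no connected component links ≥ 2 sources
with ≥ 2 targets. Admissibility is downward closed, so the subset
recursion prunes as soon as a component becomes multiple-to-multiple,
and a guard (`max_edges_per_component`, default 20) bounds the per-
component work. Because the set score is a product, the argmax
decomposes over adjacency components; the optimizer exploits this and is
verified against exhaustive enumeration.

Scores are evaluated as printed in the README with two regularizations,
both configurable: size differences and per-axis displacements are
floored at 1 px (`size_floor`, `distance_floor`) — the raw expressions
are singular for identical events — and the intensity factors use
absolute differences floored at `factor_floor` = 1e-6, since the raw
form can go negative when the target is brighter than the source and a
product score must stay positive. Comparisons are done in the log
domain; exact ties are broken by the lexicographically smallest sorted
edge encoding, so results are platform-independent.

## Linking

The forward pass seeds unique IDs in frame 0 and applies the best set
pair-by-pair. Merge decisions use an agglomerative process with
**max-linkage**: the separation of a merged entity to any other is the
maximum over its constituents' pairwise maximal historical center
distances, thresholded by the radius of the "one" event. Cells that
never co-exist have separation 0 — absence of evidence of separation
forces the merge. Fresh IDs come from a global monotone counter and are
never reused, so the merge/split provenance log stays unambiguous.

Aggregate splitting places the member shapes (rigid translation only —
shapes are not rescaled or rotated individually) at centroid offsets
shrunk by s ∈ {0.30, 0.35, …, 1.00} and rotated by θ over 36 even steps
of [−π, π), aligned to the aggregate centroid with integer-rounded
translations. The grid resolution is adequate for blob-scale shapes
(per-frame rotations in a colliding doublet are ≲ 15°). Overlap ties
prefer larger s, then θ closest to 0. Each aggregate pixel goes to the
member whose nearest template pixel is closest; a pixel inside several
template members (distance 0 to each) goes to the member with the
nearest template centroid, implemented as an ε-weighted tie term far
below the pixel quantum — a fixed-index tie rule would systematically
starve one identity over consecutive collision frames. A member left
with no pixels is re-seeded with its single nearest pixel so no
propagated identity silently disappears. Splits conserve pixels exactly.

The backward pass is the exact time-mirror of the forward pass with two
differences: direction reversed, and separation matrices computed over
all frames (identities resolved late thereby propagate into earlier
aggregates). Matchings are recomputed from the post-forward event
geometry, not cached, because forward merges and splits change the
events. Exactly one forward and one backward sweep are performed.

A structural limitation worth knowing: when two colliding cells have
byte-identical shapes and sizes, the overlap objective cannot
distinguish a template from its π-rotation, and the per-frame split
orientation is decided by segmentation noise. This is a property of the
overlap criterion itself; in practice cells differ in size, which
resolves the ambiguity (the bundled scenarios use radii 4 and 5 px).

## Trajectories and metrics

A trajectory is *correct* iff its first and last centroid are within
`margin` (default 10 px, about one cell diameter — cells enter partially
clipped) of any image edge. Speeds are displacement magnitude per frame
by default (`speed_mode="x"` restricts to the flow component — the
choice is exposed because either reading is defensible); a step belongs
to a ridge iff its midpoint x lies in the ridge interval, which is
unambiguous for boundary-straddling steps. Per-ridge speeds are
normalized by the first *traversed* ridge. Categories with no steps are
reported as missing, never as zero. y-drift is last-minus-first row,
sign-flipped so physical "up" is positive.

## Synthetic data

The generator emulates: a flat background plus static ridge stripes and
a slow sinusoidal illumination drift; cells as anti-aliased disks of
configurable radius (≥ 2 px) and intensity offset, advancing along +x
with separately scripted gap and ridge speeds (integrated with 10
sub-steps per frame so boundary crossings blend correctly) and a linear
y-drift; scripted collisions that hold two cells as a touching doublet
(center distance r_a + r_b − 1, guaranteeing a single connected
component) around a uniformly advancing joint centroid while the offset
rotates to π for swapped detachment; transient dropouts; and sub-4-px
debris at 2–3× cell speed with low contrast. Overlapping cells occlude
(per-pixel maximum) rather than add, matching touching cells in
brightfield-like recordings. Everything is deterministic given the
seed; only the Gaussian pixel noise consumes random numbers.

What the generator does **not** model: hydrodynamics or contact
mechanics (kinematics are scripted), cell shape change under ridge
compression, defocus, shot-noise statistics, or background texture.
Passing tests therefore demonstrate the identity logic and metric
recovery under the stated phenomenology, not performance on any
particular microscope.

Study-condition defaults, chosen once: cell radii 4–5 px at an intensity
offset of 60 over Gaussian noise of SD 2 (contrast 30× noise — high-
speed brightfield recordings of cells are high-contrast); gap speed
4 px/frame with stiff cells at 2 px/frame on ridges and soft cells
unchanged; ridge stripes 36 px wide with 28-px gaps; cohort drifts
+0.30 px/frame (stiff, up) and −0.08 px/frame (soft). The bundled
four-frame merge/split scenario conserves total cell area (~178 px)
across frames, as a real recording would.

## Problem sizes

The bundled analyses run at desk scale: the collision-swap clip is 84
frames of 80×160 px with two cells; each cohort is 110 frames of
64×240 px with three cells and three ridges. These sizes keep the full
test suite and the acceptance script fast while exercising every code
path (collision, rotation, swap, ridge crossings, dropout-free entry and
exit through both edges).

## Known limitations

* Matching is strictly pairwise-frame greedy, as designed; there is no
  multi-frame global optimization, so a wrong best set cannot be
  revisited except by the backward sweep.
* A cell that disappears for several frames (dropout) re-enters as a new
  identity; the resulting mid-field trajectory endpoints are flagged
  `incorrect` rather than re-linked.
* The (1/⌊ΔP⌋)² size factor is sharp: a 2-px size fluctuation between
  frames costs a factor of 4, so segmentation size noise can dominate
  sub-pixel distance differences in near-ties.
* Dataset-level statistics of real recordings require the original
  videos and exact parameter parity; the package reproduces the method's
  desk-scale worked results and its behaviour on synthetic data with
  known ground truth.
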