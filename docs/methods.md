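# Methods

This note records the model behind each processing stage, the
parameters that matter, the interpretive choices that were genuinely
open, and what the synthetic validation does and does not establish.

## Coordinate and unit conventions

All indices are 0-based; `x` is the column (rightward), `y` the row
(downward); frames are indexed in acquisition order. Pixel size (µm)
and frame interval (ms) always come from the run configuration rather
than TIFF tags, because camera models and binning vary and an explicit
value beats an inferred one. Intensities after normalization live on a
0–255 gray scale.

## Stabilization model

The tracking substrate is the cell spine: an intensity-weighted centre
of mass of each image column, with weights raised to the power 1.5 to
bias the centre toward the bright cytoplasm. Background statistics
(`b`, population σ) come from a user-chosen off-cell rectangle pooled
over all frames; the population SD is used so small-fixture arithmetic
is exact. Only pixels strictly above `b + 3σ` contribute.

Curvature is computed per frame with Savitzky–Golay derivative filters
along x. Window 11 and order 3 are the defaults: the window must be
long enough to suppress centre-of-mass noise but short against the
length scale of genuine bends (tens of columns); output is
interior-only (no polynomial extrapolation in the half-window at each
end), since extrapolated second derivatives at the span ends are
unreliable. Columns with no above-threshold signal strictly inside the
cell span are filled by linear interpolation before differentiation and
flagged.

Contraction matching slides the template window over all frame offsets
and scores the mean absolute curvature difference over the template's
column range, ignoring undefined entries pairwise. A window start is
accepted when it is a local minimum of this score and at most
`match_threshold/100` of the worst candidate score, so a larger
threshold admits more matches — the direction of sensitivity users
expect. Accepted windows are constrained non-overlapping, keeping the
lowest score among contenders. Matching is performed on the curvature
map, not raw intensities: curvature is the quantity conserved under
contraction, which is the premise of the whole approach.

Bends are replayed aligned to each window's start, relying on the
stereotyped shape of contractions; offsets are interpolated linearly
between polyline vertices and are zero outside the polyline's frame
range. The mesh places apexes purely vertically at ±h from each base
midpoint (the cell is assumed approximately x-parallel, and vertical
offsets keep the topology stable under bending). Warping is backward
(iterate over reference pixels, bilinearly sample the moving frame),
which avoids holes; the point map itself only defines the
correspondence, not the resampling direction, so this is a choice.
Pixels on shared edges resolve to the lowest triangle index for
deterministic output; pixels outside the mesh are filled with the
background mean; source samples outside the frame are clamped to the
border and counted in the log. The reference frame is caller-chosen
(config key), defaulting to frame 0.

## Detection model

Conditioning order is fixed: Max-Filter mask → 0–255 normalization →
transient subtraction (once, no second rescale — repeated rescaling
would silently change threshold semantics) → optional despeckle (3×3
median, then 3×3 mean; kernel size is not prescribed anywhere, 3×3 is
the conventional speckle kernel) → differential filter. The spatial
average truncates its window at the mask and image boundary (mean over
available in-mask pixels only), so the dark background never dilutes
the average at cell edges. The differential image is defined as 0 at
frame 0 rather than fabricating a predecessor.

**Noise scales.** Two SDs over all cell pixels and frames are kept:
`sigma_cell`, the SD of the differential image D, and `sigma_fnt`, the
SD of the transient-free intensity F_nt. Each user threshold is a
factor of the SD *of the signal that the test examines*: detection
tests `D > sd_detection × sigma_fnt`, termination tests
`mean(F_nt) < sd_termination × sigma_fnt`. This unified reading makes
the two defaults of 1 SD self-consistent. The alternative — scaling
both tests by the SD of D — is structurally broken on clean data: the
SD of D (a difference of window means) is ≈ `σ_px·√(2/(2d+1)²)`
≈ 0.2 σ_px, while the mean of clipped (non-negative) noise in F_nt is
≈ 0.4 σ_px, so termination at 1 SD of D could never fire and events
would be immortal; and a per-pixel cut at 1 SD of D admits ~16 % of
pixels, whose spatially correlated excursions form 100–300 px clusters
indistinguishable from events by size or summed intensity.

**Birth tests.** Candidate pixels (with the 7-of-8 neighbor fill, one
simultaneous pass) are grouped into 4-connected clusters — "common
borders" read literally as shared edges, while the fill uses the full
8-neighborhood as stated. A cluster may found a new event only if its
pixel count ≥ `size_threshold` AND its summed intensity ≥
`intensity_threshold` (Boolean AND); failing clusters may still extend
existing events. The brightness sum is taken over the *differential
image*: an event is born where the signal changes sufficiently fast
over a sufficiently large area, so the test measures the newly
appearing signal mass. Summing the static intensity instead lets any
persistently bright patch pass regardless of dynamics, which defeats
the test's purpose wherever loading is not perfectly uniform.

**Lifecycle.** Association between frames is overlap or 4-adjacency
with the event's previous-frame footprint. A cluster bridging two or
more events triggers a collision: the event with the larger
previous-frame footprint absorbs everything (ties to the lower id —
"largest survives" needs a timepoint and a tie rule to be
deterministic). Separation keeps one identity across all fragments. An
event receiving no cluster carries its footprint forward while it
decays; termination then removes it. Transient suspension (the
`% Transient Cutoff`) starts at the first frame of a cycle where the
whole-cell trace reaches `nadir + cutoff% × (peak − nadir)` and runs
through the peak; an event alive at the first suspended frame is
recorded as dead-by-transient (whether an event could survive an
aborted transient is not specified anywhere; terminating at first
suspension is the simpler deterministic rule). Durations are inclusive
(`death − birth + 1`; a one-frame event has duration 1). Cycle-relative
parameters use the nadir of the inter-peak interval containing the
birth (making the early/late sign rule well defined); with transients
disabled they are reported as NaN and only birth-from-start is
populated. Half-max amplitude is measured on F_nt (0–255), the only
scale the detector sees.

## False-positive control

The detector runs twice: on the cell, and on an off-cell rectangle
treated as the "cell area". The rate is
`100 × (control_events/control_area) × cell_area / cell_events`,
0 when both counts are 0. Two unit decisions make the comparison
meaningful: the control substack is normalized with the *cell run's*
anchors (re-anchoring 0–255 to the control's own noise floor would
stretch pure noise to full scale — a ~7× unit change in the bundled
fixtures — and silently redefine every absolute threshold), and the
control run sets `transients_present` off, since the whole-cell
transient does not reach an off-cell region.

## The simulator and what passing tests show

`simulate_movie` composes, in a stationary reference geometry: an
elongated cell (flat-topped plateau, ~1 px smoothstep edges, a gently
bending centerline that provides curvature landmarks), a periodic
multiplicative transient (4-frame linear upstroke, exponential decay
with a 10-frame time constant, 50-frame cycle), seeded events
(isotropic Gaussian blobs, σ = 2.5 px ≈ 1.5 µm FWHM; 2-frame linear
rise; 3-frame exponential decay; optional centroid drift at
0.5 px/frame), an optional forward piecewise-affine contraction through
a known mesh (longitudinal shortening plus slight bend, synchronized
with the transient), and finally additive Gaussian camera noise with
optional salt-and-pepper speckle. Defaults describe the standard study
condition: 100 frames of 64×256 px at 10 ms/frame, two cycles, 10
events per cycle, event amplitude 5× the noise SD (amplitude 20 over
noise SD 4). Everything is reproducible from one seed, and the truth
object records births, centroid paths, amplitudes, anchor frames, and
the deformation mesh.

Modeling choices worth knowing:

* **Flat-topped cell.** The decay filter subtracts a single whole-cell
  mean per frame, so any static brightness structure leaves a residual
  pedestal in F_nt that scales with the transient. A plateau with
  narrow edges emulates uniform dye loading, the regime the detector
  family targets; with soft-shouldered cells the pedestal floods the
  detector during transient decay. This is a real limitation of the
  method for cells with strongly nonuniform loading, not an artifact
  of the simulator.
* **Event placement.** Events of one cycle sit on a jittered staggered
  lattice in the central plateau with ≥ ~14 px separation, and
  temporally neighboring births go to spatially distant sites. Nearly
  concurrent releases closer than ~16 px share a single 1-SD candidate
  contour and are genuinely detected as one propagating/merging event —
  which is correct detector behavior but makes one-to-one ground-truth
  scoring ill-posed. The recovery results therefore quantify accuracy
  for *well-separated* events; they say nothing about deconvolving
  overlapping releases, which the method does not attempt.
* **Events live in the plateau interior.** In the dim tapering ends the
  global-mean subtraction clips sub-pedestal signals, so releases there
  are structurally invisible to this detector.
* **Transient cutoff default 20 %.** With a 4-frame upstroke this
  suspends detection from the first rising frame; at ≥ 25 % the first
  upstroke frame escapes suspension and the whole cell briefly becomes
  one giant candidate cluster that collides with every live event.

What the simulator does **not** model: photobleaching, dye kinetics and
buffering, photon shot noise calibrated to a camera, amplitude coupling
between events and local loading, whole-dish translational drift, and
out-of-focus fronds. Passing recovery tests therefore demonstrate the
algorithmic chain is correct and well-calibrated under its own
assumptions, not that any particular real recording will yield these
accuracies.

Scoring is greedy one-to-one nearest matching: a pair is admissible if
births differ by ≤ 2 frames and the detected path-bounding-box centre
lies within 8 px of the truth centroid averaged over the event's
lifetime (the detected box spans the whole propagation path, so its
centre tracks the path middle rather than the birth site). With no
detections, precision is 1 (no false claims).

## Numerical choices and degenerate inputs

Savitzky–Golay derivatives agree with central finite differences to
1e-6 on polynomial spines of degree ≤ order. The affine solver rejects
reference triangles with |det| below 1e-12 (scaled); the
point-in-triangle test includes edges with a 1e-9 barycentric
tolerance. Uniform stacks are rejected by the Max Filter (empty mask)
and by normalization (zero dynamic range). Writing clips to the
declared bit depth and logs the number of clipped samples. The
differential filter reproduces an explicit per-pixel window oracle to
1e-9.

## Problem sizes used in the bundled validation

The test suite and the acceptance script run the simulator at its
default geometry (100×64×256), with ten seeded movies for recovery
scoring and twenty event-free movies for the false-positive bound;
oracle-equivalence checks use 100 random 16×16×10 stacks. These sizes
keep the full validation in the tens of seconds on a single core while
exercising every code path at the defaults.
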