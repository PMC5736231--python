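# Methods

`bronchoreach` asks a geometric question about transbronchial access: given
a tool of diameter T that can only advance down airways at least as wide as
itself, what fraction of lung lesions can it touch without leaving the
airway lumen, and how far must it travel through parenchyma ("off-road")
otherwise?  The package answers it on simulated anatomy: a deterministic 3D
airway tree grown inside a two-lobed lung volume, plus randomly placed
spherical lesions.

## Airway tree generation

The tree is grown by recursive duct branching with space division, in the
style of deterministic morphogenesis models of the bronchial tree:

* **Space division.** Every branch tip owns a region of lung (represented as
  the set of lung voxels at 3 mm pitch).  Expanding a tip splits its region
  with a plane through the tip that contains the branch direction; the plane
  normal is the direction of largest spatial extent of the owned voxels
  perpendicular to the branch, so each split cuts the region across its
  widest dimension.  Each half becomes one child's territory.  When the
  plane through the tip would leave one side empty (tips near a region
  boundary), the split falls back to the median of the voxels along the same
  normal.
* **Flow and diameters.** Air flow divides in proportion to sub-region
  volume (voxel counts).  Child diameters follow Murray's law,
  `d_child = d_parent * q^(1/3)` with `q` the child's flow share, so
  `d1^3 + d2^3 = d_parent^3` holds exactly at every bifurcation.
* **Lengths and directions.** A child points from the tip toward its
  sub-region's center of mass, with length `3 * d_child` (the classic
  length-to-diameter ratio of conducting airways), shortened deterministically
  when the endpoint would leave the lung.  The trachea and main bronchi are
  exempt from clipping because they legitimately traverse the mediastinal
  corridor between the two lung components.
* **Termination.** A tip stops growing when a child diameter would fall
  below 0.1 mm or its sub-region is smaller than 2 voxels.  Tips are
  expanded in order of decreasing flow (ties broken by insertion order), so
  the global cap of 3311 branches removes only the smallest-flow periphery.
  Growth adds children in pairs, which keeps flow (and Murray volume)
  conservation exact and makes the 3311-branch cap land exactly.

Everything above is deterministic: identical configuration and region give a
bit-identical tree.  With the default configuration the tree has 3311
branches, trachea 14.5 mm, main bronchi 11.3/11.7 mm, lobar bronchi
~9 mm, and terminal diameters of ~1.1 mm and up.  Note the termination
profile: with volume-proportional flow splits the branch-count cap binds
long before the 0.1 mm diameter floor, so terminal diameters cluster near
1 mm rather than spreading down to 0.1 mm.  The reference airway model this
emulates reaches 0.1 mm in places; its terminal-diameter distribution is not
published, and this is the main known structural difference (see
*Limitations*).

## Lung volume and respiratory phases

The lung is two disjoint convex components — ellipsoids truncated by a basal
plane (diaphragm) and a mediastinal plane — with the right lung holding ~53%
of the volume.  The full-inspiration shape (capacity fraction 1.0) encloses
~6.0 L, an adult total lung capacity.  Other capacities scale all linear
dimensions by `capacity^(1/3)` about the lung-box center; expiration uses
capacity 0.35.  The expiration tree is the inspiration tree under the same
isotropic scaling (coordinates and diameters), which preserves topology and
is the simplest deformation consistent with volume scaling; no
time-resolved breathing motion or airway-specific compliance is modeled.

## Lesion sampling

Lesion centers are drawn per lung side (right lung probability 0.55), then
per axis from histogram PDFs on the side's bounding box: x (medial→lateral,
mirrored between sides) puts half the mass in the lateral third, y
(caudal→cranial) puts 62% in the cranial half, z is uniform.  These are
qualitative stand-ins for the lesion-location distribution reported by the
NELSON screening trial — the trial's histograms are not published as
numbers, so the defaults encode only the documented structure (peripheral
and upper-lobe predominance, right-lung excess) and are fully overridable
from a plain-text config file.  Sampling is uniform within a bin.  Points
are contained in the per-side *bounding boxes*, not the lung volume itself;
that mirrors the original procedure and means some lesions land in box
corners outside the lung (rejection sampling into the lung volume is
available via `clip_to_region`).  The study design is 3 replicate sets of
1000 lesions per phase, each with a sub-seed derived from the master seed by
fixed integer offsets; expiration sets are drawn fresh against the
expiration boxes.

## Contact, reachability, off-road distance

Each airway branch is a capsule (segment with radius).  A lesion sphere of
radius r touches a branch when the center-to-axis distance minus the branch
radius (its surface *clearance*) is at most r.  The analytic fast path
computes all lesion-branch clearances by vectorized point-to-segment
distance and derives, per lesion, the largest contacted airway diameter for
every lesion diameter on the 1-50 mm grid (1 mm steps).  A mesh path —
triangulated airway tubes, per-face local diameters found by casting a ray
from each face centroid to the opposite wall (40 mm search cutoff, NaN when
undetermined), lesion icospheres, containment by generalized winding number
— implements the same query the way a mesh-based pipeline would, and the
test suite cross-checks the two.

* **Percent reachable** at tool T and lesion diameter L is the share of
  lesions whose contact set at L includes an airway of diameter >= T.  The
  comparison is `>=` uniformly (for both reachability and off-road).
* **Off-road distance** for a lesion of radius `r1` and tool T is
  `max(r2 - r1, 0)`, where `r2` is the smallest grid radius at which the
  growing lesion sphere first touches an airway >= T.  Lesions that touch no
  qualifying airway within the 25 mm maximum grid radius are marked
  unreachable, excluded from means, and counted separately.  A continuous
  variant (nearest qualifying airway surface distance minus `r1`) agrees
  with the grid value to within one grid step and serves as its oracle.
* **Summaries** report mean +/- SD per (lesion size in {10,20,30,40,50} mm,
  tool size in 1-9 mm by 0.5 mm), flagging cells where more than half the
  lesions are unreachable.  Because unreachable lesions are excluded, the
  summary mean is *not* guaranteed monotone in tool size (dropping the
  farthest lesions can lower a wider tool's mean); per lesion, and on the
  subset reachable by both tools, the distance is monotone, and that is the
  property the tests assert.

## CT comparison stage

CT-measured lesions arrive as one row per lesion: axis diameters, offset
from the lung-box center, contact-airway diameter (empty = touches none),
and distances to the nearest airway of >= 1, 2, 4, 6 mm diameter, which are
taken as directly comparable to the simulated off-road distance.  The
package reads CSV or spreadsheet tables, computes cohort summaries
(min/max/mean/median diameter, contact histogram), reachability curves per
diameter bin (0.7-1.3 cm and 1.7-2.3 cm by default), and per-tool off-road
points for overlay on the simulated curves.  `place_points_in_model` maps
measured lesion offsets into model coordinates and reports, per tool size,
the nearest qualifying airway's distance and diameter.

A seeded synthetic table generator stands in for measured data in tests.
Its diameters are lognormal truncated to [8, 40] mm, calibrated analytically
(untruncated median 9.0 mm, sigma 0.74) so the truncated distribution is the
closest such lognormal to the measured cohort's printed statistics (mean
16 mm, median 13 mm, range ~10-36 mm; the truncated optimum is mean ~15.6,
median ~13.5 — a truncated lognormal cannot hit both printed values
exactly).  Contact status, contact diameters (mostly 1-2 mm) and
threshold-monotone distances emulate the documented measurement structure.
It is synthetic: it reproduces scale and schema, not patient anatomy.

## Numerical choices

* Winding-number containment uses the van Oosterom–Strackee signed solid
  angle, threshold 0.5 with boundary resolved as inside; single-ray crossing
  parity is kept as an independent test oracle.
* Opposite-face search excludes cap faces and non-opposing hits
  (`dot(normal_hit, ray) <= 0`), cutoff 40 mm.
* Sub-seeds: `master + 100000 * phase + 1000 * replicate`, kept below 2^31.
* Lung voxelization pitch 3 mm (volume within 5% of the analytic shape at
  2 mm in tests); splitting degenerates below 2 voxels.
* CSV floats are written with `%.9g`, making reruns byte-identical.

## Problem sizes

The full study — two 3311-branch trees, 6 x 1000 lesions, 50 lesion
diameters, 17 tool sizes — runs in a few seconds on one CPU via the analytic
fast path (the clearance matrix is 1000 x 3311 per replicate).  Mesh-path
operations (face diameters, winding numbers) are dense O(faces x rays) and
are used at fidelity-test scale (single tubes, icospheres, ~50-branch
trees).

## What passing tests do and do not show

The synthetic study reproduces the *structure* of the published results:
sparse contact at small lesion sizes, the reachability bounds for 1 mm and
6.3 mm tools, off-road means below the published ceiling, and monotonicity
in tool and lesion size.  It does not validate against real anatomy: the
lung shape is idealized, the airway generator is a re-specification (not the
original implementation), the lesion PDFs are qualitative stand-ins, and
airway deformation by the advancing tool is not modeled (reachability is
therefore conservative).  Two quantitative consequences observed at the
default conditions: the no-contact count for 5 mm lesions runs ~3% above the
published 918/1000 (the re-specified tree has less sub-millimeter airway
surface), and the per-cell replicate spread can exceed 5 percentage points
at n = 1000 simply from binomial noise, so those two strict test bands can
fail while every bound-type result holds.
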