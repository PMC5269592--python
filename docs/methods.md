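# Methods

## Problem and model

Transcranial brain-mapping techniques (fNIRS, TMS) place probes on the
scalp using the international 10/20 system: 21 landmarks defined by
fractional arc lengths along scalp curves anchored at four cranial
reference points — nasion (Nz), inion (Iz) and the left/right preauricular
points (AL, AR).  Manual measurement of these landmarks is slow and
unreliable.  This package implements the computational half of a
semi-automatic alternative: reconstruct the subject's head surface from a
small set (~21) of roughly uniformly digitized scalp points, then measure
all 21 landmarks *virtually* on the reconstruction.

All computation happens in the **nasion-ear frame**: origin at the AL–AR
midpoint, +x toward AR, +y toward Nz (orthogonalised within the Nz/AL/AR
plane), +z up.  Inputs in any rigid pose are normalised into this frame
from their reference points before measurement, so results commute with
rigid motions.  Iz is not used in frame construction; it anchors the
reconstruction boundary and the sagittal measurement curve only.

## Sparse-sample surface reconstruction (S3R)

1. **Crust triangulation.**  The unordered sample cloud (the four reference
   points plus N ≥ 10 reconstruction points) is triangulated with a
   Voronoi-pole crust: Delaunay tetrahedralisation of the samples together
   with their Voronoi poles, keeping the triangles whose three vertices are
   all samples.  Faces are oriented outward, near-vertical "lid" faces
   closing the cap from below are dropped (unit-normal z below −0.2), a
   greedy pass resolves over-shared edges in favour of the most radially
   aligned faces, and the largest connected component is kept.  The result
   must be a manifold cap using every input point with a single boundary
   loop; otherwise the implementation falls back to the cap-facing
   convex-hull triangulation, which is valid for head-like convex clouds
   (the fallback is recorded in the mesh provenance).  Exactly co-spherical
   inputs are degenerate for the Delaunay step; a deterministic jitter of
   1e-9 × scale (fixed internal seed) is applied to the working copy when
   the best-fit-sphere residual detects this, with outputs always reported
   in the original coordinates.
2. **Spherization.**  Each triangle is subdivided 1-to-4 for five levels.
   A new point on edge V1–V2 lies on the ray from the origin O through the
   point M12 where the internal bisector of angle V1-O-V2 crosses the edge
   (M12 divides the edge as |OV1| : |OV2|), at radius (|OV1| + |OV2|)/2.
   Midpoints are computed once per undirected edge — with lexicographically
   canonicalised endpoints, so shared edges agree bitwise — and original
   vertices are never moved.  A sphere centred at O is an exact fixed point
   of this rule, which is why it suits ellipsoid-like smooth heads; on a
   semi-ellipsoid with 3 mm bumps it is several times more accurate than
   plain midpoint subdivision of the same crust.  After L levels a mesh
   with V vertices, E edges and F faces has
   V + (2^L−1)E + (2^L−1)(2^L−2)/2·F vertices and 4^L F faces.

## Virtual 10/20 measurement

Scalp curves are realised as plane–mesh intersections: the mesh section is
chained into polylines, the route containing both endpoints and passing
nearest the third anchor point is selected, trimmed and parameterised by
arc length.  Cz is the fixed point of alternating 50 % measurements on the
Nz→Iz and AL→AR curves (initialised at the highest vertex; tolerance
0.01 mm, at most 50 iterations).  The landmark scheme is then:

* sagittal Nz→Iz through Cz: Fpz, Fz, Cz, Pz, Oz at 10/30/50/70/90 %;
* coronal AL→AR through Cz: T3, C3, Cz, C4, T4 at the same fractions;
* two half-circumference curves Fpz→Oz anchored through T3 and T4:
  Fp1, F7, T5, O1 (left) and Fp2, F8, T6, O2 (right) at 10/30/70/90 %;
* F3/F4 and P3/P4 as midpoints of the half-arcs of the transverse curves
  F7→F8 through Fz and T5→T6 through Pz.

T3/T4 are defined on the coronal curve (the classical rule); the
circumference halves are anchored *through* them, and on left-right
symmetric heads the coronal and circumference definitions coincide.

Three robustness mechanisms matter on reconstructed caps, whose boundary
between the reference points can bulge through a cutting plane:

* **boundary bridging** — when a section breaks into arcs at the boundary,
  gap ends are joined along the boundary polyline (the shorter of the two
  alternating matchings); a boundary path that strays more than 3 % of the
  head scale from the plane, or is more than twice the gap chord, is
  replaced by the chord;
* **fold removal** — scalp curves are star-shaped about the frame origin,
  so any retrace (the spherized surface can fold near deep boundary
  notches at the reference points) is removed by enforcing monotone
  angular progress, keeping the outermost sheet;
* **slab marching** — if a tangential plane misses an endpoint's
  neighbourhood entirely (it can touch a notch tip in a single point), the
  curve is rebuilt by angular marching through a thin vertex slab around
  the plane, taking the outermost vertex per angular bin.  This fallback is
  approximate to within the slab half-width (~1.5 median edge lengths).

The 5 %-resolution candidate grid extends the same machinery: sagittal,
coronal and circumference curves at 5 % steps plus transverse curves at
every 5 % level between 15 % and 85 %, deduplicated at 0.5 mm.  Candidates
are partitioned into ten region subsets of roughly equal coverage
(midline-frontal/posterior, and per side frontal, central, temporal,
parieto-occipital), assigned by scalp position so that every subset holds
at least 11 candidates and balanced draws up to n = 110 are feasible.

## Sampling simulators

* `uniform_sample` draws n distinct candidates under four constraints:
  candidates only, all unique, at least one per subset, subset counts
  differing by at most one.  Counts are base = n div 10 with the remainder
  distributed at random.
* `cap_perturb` emulates EEG-cap-guided sampling: each landmark is replaced
  by a mesh vertex drawn uniformly from those within 13 mm Euclidean
  (chord) distance — at this radius the chord/geodesic difference on a head
  is negligible.  Vertices, not arbitrary surface points, keep the draw
  uniform and on-surface; ground-truth meshes therefore carry ≥ 5,000
  vertices (default head resolution 144 azimuthal steps, ~10,000 vertices).
  Collisions between neighbouring landmarks are re-drawn.
* the uniformness index is UI = 1 / SD(crust edge lengths), sample SD with
  n−1 (edge counts are small); all edges equal gives +infinity.

## Synthetic heads

Ground-truth heads are UV-meshed caps: rings of constant polar angle with
one projected centre vertex per quad, which keeps the triangulation exactly
mirror-symmetric (measurement symmetry tests rely on this) and all vertices
exactly on the analytic surface, with the four reference points and the
vertex as exact mesh vertices.  `make_sphere_head` is the analytic fixture;
`make_ellipsoid_head` is the head-like condition — a semi-ellipsoid
(defaults near a = 80, b = 95, c = 85 mm) with a seeded sum of
low-frequency cosine fields as radial bumps, windowed by squared unit
height so the reference points stay fixed, rescaled so the maximum
displacement equals the requested amplitude (3 mm in the studies: the scale
of gentle cranial shape variation).  These surfaces emulate the smooth,
convex geometry of the upper head; they carry no hair, ears, facial
features, digitisation noise or MRI segmentation artefacts, so passing
simulations bound method error under ideal sampling of a smooth scalp, not
performance on real digitizer data.

## Studies and problem sizes

All studies are deterministic given (config, master seed); per-run seeds
are master + run index (mod 2^31).  Failed runs (a pathological sample the
crust cannot triangulate) are excluded from aggregates and counted.

* **Size sweep**: for each size, repeated uniform draws through the full
  pipeline against ground truth measured directly on the head; mean error
  (ME, mean over the 21 landmarks of Euclidean error) per run, a power-law
  fit y = a·x^b by least squares in log–log space (R² on the log scale;
  constant data degrades to b = 0, R² = 0 with a warning), and the
  fraction of runs under the 3 mm accuracy criterion (10 % of fNIRS
  spatial resolution).  The acceptance script sweeps
  sizes {10, 15, 21, 30, 40, 60, 80} × 10 repeats; the library default is
  the full 10–110 × 20.
* **Uniformness study**: repeated 21-point samplings; UI and ME per
  repeat, Pearson r (two-sided t-approximation p-value) between them.
* **Cap study**: 20 repeats of 0–13 mm cap-perturbed sampling of the 21
  landmarks; per landmark the Error (distance of the mean estimated
  position to ground truth) and the Variance (pooled three-coordinate sum
  of squared deviations over n−1, in mm²; a square-root display option
  exists since the field sometimes reports the root).

On the bumpy semi-ellipsoid these yield mean landmark errors around
1–1.5 mm at n = 21 and a clearly negative power-law exponent; the numbers
printed by `scripts/acceptance.py` are recomputed from scratch on every
run.

## Numerical choices and limitations

* Section chaining merges endpoints at 1e-7 × scale; curve endpoints must
  lie within 1e-3 × scale of a route; refs are snapped to the surface by
  exact point-to-triangle projection (vectorised, KD-tree accelerated,
  verified against a brute-force scan).
* The one-sided reconstruction accuracy (mean vertex-to-truth distance) is
  the default; a symmetric variant is available via a flag.
* Landmark accuracy on synthetic heads is limited by mesh discretisation
  (~0.02 mm at the default resolution), far below the 3 mm criterion.
* The physical navigation system, digitizer calibration, MRI scalp
  extraction and MNI registration are out of scope; the operator-variance
  statistics (total / inter / intra) are implemented for externally
  collected landmark grids.
* The crust falls back to the convex-hull cap on many non-spherical sample
  sets; for convex head-like clouds the two coincide up to sliver faces,
  and the fallback is flagged in provenance rather than hidden.
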