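"""Sparse Sample Surface Reconstruction (S3R).

Two stages turn an unordered, sparse scalp sample into a dense head surface:

1. *Crust* triangulation (Amenta-style): Delaunay tetrahedralisation of the
   samples together with their Voronoi poles; the triangles whose three
   vertices are all samples approximate the surface.  A manifold cap is then
   extracted (outward orientation from the nasion-ear origin, near-vertical
   lid faces removed, largest component kept).
2. *Spherization*: five levels of edge subdivision where each new point lies
   on the angular bisector ray from the origin at the average radius of the
   edge endpoints.  A sphere about the origin is a fixed point of this rule,
   which is what makes it effective for ellipsoid-like smooth heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, Voronoi

from .head_model import (
    GeometryError,
    ReferenceSet,
    TriangleSurface,
    closest_surface_points,
)

__all__ = [
    "ReconstructionError",
    "SamplePointCloud",
    "CrustMesh",
    "DenseSurface",
    "crust_reconstruct",
    "bisector_interpolate",
    "spherize",
    "reconstruction_accuracy",
    "upward_hull_faces",
]

ORIGIN = np.zeros(3)


class ReconstructionError(RuntimeError):
    """Surface reconstruction failed (degenerate input, non-manifold crust)."""


@dataclass
class SamplePointCloud:
    """Unordered digitised reconstruction points plus the four references,
    all in nasion-ear coordinates."""

    points: np.ndarray
    refs: ReferenceSet

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 10:
            raise ReconstructionError(
                f"need at least 10 reconstruction points, got {len(self.points)}"
            )
        from scipy.spatial.distance import pdist

        if len(self.points) > 1 and pdist(self.points).min() <= 1e-6:
            raise ReconstructionError("reconstruction points are not pairwise distinct")

    @property
    def n(self) -> int:
        return len(self.points)

    def all_points(self) -> np.ndarray:
        """Refs (first four rows: Nz, Iz, AL, AR) followed by the samples."""
        return np.vstack([self.refs.as_array(), self.points])


@dataclass
class CrustMesh:
    """Interpolating crust of the sample cloud: vertices are exactly the
    input points (4 refs first, then the reconstruction points)."""

    surface: TriangleSurface
    provenance: dict = field(default_factory=dict)

    @property
    def n_triangles(self) -> int:
        return self.surface.n_faces

    def edge_lengths(self) -> np.ndarray:
        e = self.surface.edges_unique()
        v = self.surface.vertices
        return np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)


@dataclass
class DenseSurface:
    """Spherized dense surface DP; ``provenance`` records levels and source
    mesh counts."""

    surface: TriangleSurface
    provenance: dict = field(default_factory=dict)

    @property
    def n_dp(self) -> int:
        return self.surface.n_vertices


# ---------------------------------------------------------------------------
# crust
# ---------------------------------------------------------------------------

def _fit_sphere_residual(pts: np.ndarray) -> float:
    """Max |r_i - r| of the algebraic best-fit sphere (degeneracy detector)."""
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    r = np.sqrt(max(sol[3] + centre @ centre, 0.0))
    return float(np.abs(np.linalg.norm(pts - centre, axis=1) - r).max())


def _voronoi_poles(pts: np.ndarray) -> np.ndarray:
    """Voronoi poles of a 3-D point set (Amenta's construction).

    For samples with bounded Voronoi cells the positive pole is the farthest
    cell vertex; for unbounded cells the outward direction is the mean of the
    incident convex-hull facet normals.  The negative pole is the cell vertex
    farthest in the opposite half-space.
    """
    vor = Voronoi(pts)
    hull = ConvexHull(pts)
    # outward hull-facet normal accumulated per vertex
    centroid = pts.mean(axis=0)
    v_norm = np.zeros_like(pts)
    for simplex, eq in zip(hull.simplices, hull.equations):
        n = eq[:3]
        if np.dot(n, pts[simplex[0]] - centroid) < 0:
            n = -n
        v_norm[simplex] += n
    poles = []
    for i in range(len(pts)):
        region = [r for r in vor.regions[vor.point_region[i]] if r != -1]
        verts = vor.vertices[region] if region else np.empty((0, 3))
        unbounded = -1 in vor.regions[vor.point_region[i]]
        if unbounded:
            n_plus = v_norm[i]
            nn = np.linalg.norm(n_plus)
            n_plus = n_plus / nn if nn > 0 else np.array([0.0, 0.0, 1.0])
        else:
            d = np.linalg.norm(verts - pts[i], axis=1)
            j = int(np.argmax(d))
            poles.append(verts[j])
            n_plus = verts[j] - pts[i]
            nn = np.linalg.norm(n_plus)
            if nn == 0:
                continue
            n_plus /= nn
        if len(verts):
            proj = (verts - pts[i]) @ n_plus
            j = int(np.argmin(proj))
            if proj[j] < 0:
                poles.append(verts[j])
    return np.array(poles).reshape(-1, 3)


def _candidate_crust_triangles(pts: np.ndarray) -> np.ndarray:
    """All-sample triangles of the Delaunay tetrahedralisation of samples
    plus poles."""
    poles = _voronoi_poles(pts)
    cloud = np.vstack([pts, poles]) if len(poles) else pts
    tet = Delaunay(cloud)
    n = len(pts)
    faces = []
    face_ids = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    for simplex in tet.simplices:
        for ids in face_ids:
            tri = simplex[list(ids)]
            if tri.max() < n:
                faces.append(np.sort(tri))
    if not faces:
        return np.empty((0, 3), dtype=np.int64)
    return np.unique(np.array(faces, dtype=np.int64), axis=0)


def upward_hull_faces(pts: np.ndarray, origin=ORIGIN, min_normal_z: float = -0.2) -> np.ndarray:
    """Convex-hull triangulation restricted to cap-facing faces.

    Faces are oriented outward from ``origin``; faces whose outward unit
    normal has z-component below ``min_normal_z`` (the near-vertical "lid"
    closing the cap from below) are dropped.  Serves both as the fallback
    reconstruction for convex clouds and as the oracle the crust is checked
    against on convex data.
    """
    hull = ConvexHull(pts)
    ref = _orient_reference(pts, origin)
    faces = _orient_outward(pts, hull.simplices.astype(np.int64), ref)
    return _drop_lid(pts, faces, min_normal_z)


def _orient_reference(pts, origin):
    """Interior reference point for outward orientation: the nasion-ear
    origin raised into the cap solid, so faces lying in the rim plane
    (which contains the origin itself) orient stably and get dropped as
    downward-facing lid."""
    ref = np.asarray(origin, dtype=float).copy()
    ref[2] += 0.25 * float(np.ptp(pts[:, 2])) + 1e-9
    return ref


def _orient_outward(pts, faces, origin):
    tri = pts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    outward = np.einsum("ij,ij->i", normals, tri.mean(axis=1) - origin) < 0
    faces = faces.copy()
    faces[outward] = faces[outward][:, ::-1]
    return faces


def _drop_lid(pts, faces, min_normal_z):
    tri = pts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nz = normals[:, 2] / np.maximum(np.linalg.norm(normals, axis=1), 1e-300)
    return faces[nz > min_normal_z]


def _extract_manifold_cap(pts, faces, origin):
    """Greedy manifold extraction: resolve over-shared edges by keeping the
    faces best aligned with the outward radial direction, then keep the
    largest edge-connected component."""
    if len(faces) == 0:
        return faces
    tri = pts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-300)
    radial = tri.mean(axis=1) - origin
    radial /= np.maximum(np.linalg.norm(radial, axis=1, keepdims=True), 1e-300)
    quality = np.einsum("ij,ij->i", normals, radial)

    keep = np.ones(len(faces), dtype=bool)

    def edge_map():
        m: dict[tuple[int, int], list[int]] = {}
        for fi in np.nonzero(keep)[0]:
            a, b, c = faces[fi]
            for e in ((a, b), (b, c), (a, c)):
                m.setdefault(tuple(sorted(map(int, e))), []).append(fi)
        return m

    for _ in range(len(faces)):
        over = [(e, fl) for e, fl in edge_map().items() if len(fl) > 2]
        if not over:
            break
        e, fl = over[0]
        order = sorted(fl, key=lambda fi: quality[fi], reverse=True)
        for fi in order[2:]:
            keep[fi] = False

    kept = faces[keep]
    if len(kept) == 0:
        return kept
    # largest connected component via shared edges
    emap: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(kept):
        for e in ((a, b), (b, c), (a, c)):
            emap.setdefault(tuple(sorted(map(int, e))), []).append(fi)
    parent = list(range(len(kept)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for fl in emap.values():
        for fi in fl[1:]:
            ra, rb = find(fl[0]), find(fi)
            if ra != rb:
                parent[rb] = ra
    roots = np.array([find(i) for i in range(len(kept))])
    best = np.bincount(roots).argmax()
    return kept[roots == best]


def crust_reconstruct(
    cloud: SamplePointCloud,
    origin=ORIGIN,
    min_normal_z: float = -0.2,
) -> CrustMesh:
    """Crust triangulation of refs + reconstruction points.

    Falls back to the cap-facing convex-hull triangulation (valid for
    head-like convex clouds) when pole filtering does not yield a manifold
    single-boundary cap using every input point; ``provenance`` records
    which route produced the result.
    """
    pts = cloud.all_points()
    origin = np.asarray(origin, dtype=float)
    scale = float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).max())
    if scale <= 0:
        raise ReconstructionError("degenerate point cloud")
    rank = np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9 * scale)
    if rank < 3:
        raise ReconstructionError("points are coplanar/collinear: no surface to reconstruct")

    work = pts
    jittered = False
    if _fit_sphere_residual(pts) < 1e-7 * scale:
        work = pts + np.random.default_rng(171717).normal(size=pts.shape) * 1e-9 * scale
        jittered = True

    provenance = {
        "jittered": jittered,
        "used_fallback": False,
        "n_input": len(pts),
        # coordinates actually triangulated (jitter included) so oracles can
        # recompute the triangulation on identical input
        "effective_points": work,
    }

    faces = None
    ref = _orient_reference(pts, origin)
    try:
        cand = _candidate_crust_triangles(work)
        cand = _orient_outward(pts, cand, ref)
        cand = _drop_lid(pts, cand, min_normal_z)
        cand = _extract_manifold_cap(pts, cand, ref)
        if _cap_ok(pts, cand):
            faces = cand
    except (QhullError, np.linalg.LinAlgError):
        pass

    if faces is None:
        try:
            cand = upward_hull_faces(work if jittered else pts, origin, min_normal_z)
            cand = _extract_manifold_cap(pts, cand, ref)
        except QhullError as exc:
            raise ReconstructionError(f"convex-hull fallback failed: {exc}") from exc
        if not _cap_ok(pts, cand):
            raise ReconstructionError(
                "reconstruction failed: no manifold single-boundary cap covering "
                f"all {len(pts)} points (got {len(cand)} faces)"
            )
        faces = cand
        provenance["used_fallback"] = True

    surf = TriangleSurface(pts, faces)
    provenance["n_triangles"] = len(faces)
    return CrustMesh(surface=surf, provenance=provenance)


def _cap_ok(pts, faces) -> bool:
    if len(faces) == 0:
        return False
    if len(np.unique(faces)) != len(pts):
        return False
    surf = TriangleSurface(pts, faces, validate=False)
    if not surf.is_manifold():
        return False
    return len(surf.boundary_loops()) == 1


# ---------------------------------------------------------------------------
# spherization
# ---------------------------------------------------------------------------

def bisector_interpolate(v1, v2, o=ORIGIN) -> np.ndarray:
    """Angular-bisector edge interpolation.

    M12 is where the internal bisector of angle V1-O-V2 crosses segment
    V1-V2 (it divides the segment as |OV1| : |OV2|); the result lies on the
    ray O->M12 at radius (|OV1| + |OV2|)/2.  Endpoints are canonicalised
    (lexicographic order) so the result is bitwise symmetric in (v1, v2).
    """
    v1 = np.asarray(v1, dtype=float).reshape(3)
    v2 = np.asarray(v2, dtype=float).reshape(3)
    o = np.asarray(o, dtype=float).reshape(3)
    if tuple(v2) < tuple(v1):
        v1, v2 = v2, v1
    r1 = np.linalg.norm(v1 - o)
    r2 = np.linalg.norm(v2 - o)
    seg = np.linalg.norm(v2 - v1)
    if r1 < 1e-12 or r2 < 1e-12 or seg < 1e-12:
        raise GeometryError("bisector interpolation: coincident points or zero radius")
    m12 = v1 + (r1 / (r1 + r2)) * (v2 - v1)
    d = m12 - o
    nd = np.linalg.norm(d)
    if nd < 1e-12 * max(r1, r2):
        raise GeometryError("bisector interpolation: origin lies on the edge line")
    return o + d * ((r1 + r2) / 2.0 / nd)


def _subdivide_once(vertices: np.ndarray, faces: np.ndarray, o: np.ndarray):
    """One level of 1-to-4 subdivision with bisector midpoints, one midpoint
    per undirected edge (shared by both incident faces)."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    edges, inverse = np.unique(e, axis=0, return_inverse=True)

    p1 = vertices[edges[:, 0]]
    p2 = vertices[edges[:, 1]]
    r1 = np.linalg.norm(p1 - o, axis=1)
    r2 = np.linalg.norm(p2 - o, axis=1)
    if np.any(r1 < 1e-12) or np.any(r2 < 1e-12):
        bad = edges[(r1 < 1e-12) | (r2 < 1e-12)][0]
        raise GeometryError(f"spherize: zero radius at edge {tuple(bad)}")
    t = (r1 / (r1 + r2))[:, None]
    m = p1 + t * (p2 - p1)
    d = m - o
    nd = np.linalg.norm(d, axis=1)
    if np.any(nd < 1e-12 * np.maximum(r1, r2)):
        bad = edges[nd < 1e-12 * np.maximum(r1, r2)][0]
        raise GeometryError(f"spherize: origin on edge line at edge {tuple(bad)}")
    mid = o + d * (((r1 + r2) / 2.0) / nd)[:, None]

    mid_idx = len(vertices) + np.arange(len(edges))
    new_vertices = np.vstack([vertices, mid])
    nf = len(faces)
    m01 = mid_idx[inverse[:nf]]
    m12 = mid_idx[inverse[nf : 2 * nf]]
    m20 = mid_idx[inverse[2 * nf :]]
    f0, f1, f2 = faces[:, 0], faces[:, 1], faces[:, 2]
    new_faces = np.vstack(
        [
            np.column_stack([f0, m01, m20]),
            np.column_stack([f1, m12, m01]),
            np.column_stack([f2, m20, m12]),
            np.column_stack([m01, m12, m20]),
        ]
    )
    return new_vertices, new_faces


def spherize(mesh: CrustMesh | TriangleSurface, origin=ORIGIN, levels: int = 5) -> DenseSurface:
    """Iterative bisector subdivision of the crust (default 5 levels).

    Original vertices are untouched; each level quadruples the face count.
    For a source mesh with V vertices, E edges and F faces the vertex count
    after L levels is V + (2^L - 1) E + (2^L - 1)(2^L - 2)/2 F.
    """
    surf = mesh.surface if isinstance(mesh, CrustMesh) else mesh
    if levels < 0:
        raise GeometryError("levels must be >= 0")
    o = np.asarray(origin, dtype=float).reshape(3)
    v, f = surf.vertices.copy(), surf.faces.copy()
    for _ in range(levels):
        v, f = _subdivide_once(v, f, o)
    out = TriangleSurface(v, f, validate=False)
    prov = {
        "levels": levels,
        "source_vertices": surf.n_vertices,
        "source_edges": len(surf.edges_unique()),
        "source_faces": surf.n_faces,
    }
    return DenseSurface(surface=out, provenance=prov)


def reconstruction_accuracy(
    dense: DenseSurface | TriangleSurface,
    truth: TriangleSurface,
    symmetric: bool = False,
) -> float:
    """Mean distance (mm) from the reconstruction's vertices to the truth
    surface; with ``symmetric=True`` the average of both directions."""
    d_surf = dense.surface if isinstance(dense, DenseSurface) else dense
    _, d = closest_surface_points(truth, d_surf.vertices)
    fwd = float(d.mean())
    if not symmetric:
        return fwd
    _, d2 = closest_surface_points(d_surf, truth.vertices)
    return 0.5 * (fwd + float(d2.mean()))
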