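"""Head geometry: reference points, the nasion-ear frame, triangle surfaces,
synthetic head models and mesh/point file I/O.

All coordinates are millimetres.  Computation happens in the *nasion-ear
frame*: origin at the midpoint of the two preauricular points, +x from AL
toward AR, +y toward the nasion (orthogonalised), +z up.  Points are plain
``(3,)`` float64 numpy arrays; point sets are ``(n, 3)`` arrays.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "GeometryError",
    "ReferenceSet",
    "NasionEarFrame",
    "TriangleSurface",
    "HeadModel",
    "build_nasion_ear_frame",
    "make_sphere_head",
    "make_ellipsoid_head",
    "load_surface",
    "save_surface",
    "closest_surface_point",
    "closest_surface_points",
    "load_points_csv",
    "save_points_csv",
]


class GeometryError(ValueError):
    """Degenerate geometric configuration (collinear refs, empty mesh, ...)."""


def as_point(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise GeometryError(f"non-finite coordinates: {p}")
    return p


@dataclass(frozen=True)
class ReferenceSet:
    """The four 10/20 reference points: nasion, inion, left/right preauricular."""

    nz: np.ndarray
    iz: np.ndarray
    al: np.ndarray
    ar: np.ndarray

    def __post_init__(self):
        for name in ("nz", "iz", "al", "ar"):
            object.__setattr__(self, name, as_point(getattr(self, name)))
        pts = self.as_array()
        for i in range(4):
            for j in range(i + 1, 4):
                if np.linalg.norm(pts[i] - pts[j]) < 1e-9:
                    raise GeometryError("reference points must be pairwise distinct")
        if _collinear(self.nz, self.al, self.ar):
            raise GeometryError("Nz, AL, AR are collinear")

    def as_array(self) -> np.ndarray:
        return np.array([self.nz, self.iz, self.al, self.ar])

    @property
    def names(self):
        return ("Nz", "Iz", "AL", "AR")

    def transform(self, fn) -> "ReferenceSet":
        return ReferenceSet(fn(self.nz), fn(self.iz), fn(self.al), fn(self.ar))


def _collinear(a, b, c, tol: float = 1e-9) -> bool:
    v1, v2 = b - a, c - a
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < tol or n2 < tol:
        return True
    return np.linalg.norm(np.cross(v1, v2)) < tol * n1 * n2


@dataclass(frozen=True)
class NasionEarFrame:
    """Rigid transform between world coordinates and the nasion-ear frame.

    ``rotation`` rows are the frame axes expressed in world coordinates, so
    ``to_frame(p) = rotation @ (p - origin)``.
    """

    origin: np.ndarray
    rotation: np.ndarray  # (3, 3), rows = x, y, z axes

    def to_frame(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.origin) @ self.rotation.T

    def to_world(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation + self.origin

    @property
    def axes(self) -> np.ndarray:
        return self.rotation


def build_nasion_ear_frame(nz, al, ar) -> NasionEarFrame:
    """Frame from the nasion and the two preauricular points.

    Origin at the AL-AR midpoint, +x toward AR, +y toward Nz within the
    Nz/AL/AR plane, +z = x cross y.
    """
    nz, al, ar = as_point(nz), as_point(al), as_point(ar)
    if _collinear(nz, al, ar):
        raise GeometryError("cannot build frame: Nz, AL, AR collinear or coincident")
    origin = 0.5 * (al + ar)
    x = ar - al
    x = x / np.linalg.norm(x)
    y = nz - origin
    y = y - np.dot(y, x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise GeometryError("cannot build frame: nasion on the inter-aural axis")
    y = y / ny
    z = np.cross(x, y)
    return NasionEarFrame(origin=origin, rotation=np.array([x, y, z]))


class TriangleSurface:
    """A triangle mesh: ``vertices`` (n, 3) float64, ``faces`` (m, 3) int."""

    def __init__(self, vertices, faces, validate: bool = True):
        self.vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if validate:
            self._validate()

    def _validate(self):
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise GeometryError("empty surface")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise GeometryError("face index out of range")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        scale = max(np.ptp(self.vertices, axis=0).max(), 1.0)
        if np.any(areas < 1e-14 * scale**2):
            raise GeometryError("degenerate (zero-area) faces present")

    # -- connectivity -----------------------------------------------------
    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges, each row sorted, (e, 2)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_face_counts(self):
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def boundary_edges(self) -> np.ndarray:
        uniq, counts = self.edge_face_counts()
        return uniq[counts == 1]

    def boundary_loops(self):
        """Boundary as lists of vertex indices, one per closed loop."""
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        adj: dict[int, list[tuple[int, int]]] = {}
        for ei, (a, b) in enumerate(be):
            adj.setdefault(int(a), []).append((int(b), ei))
            adj.setdefault(int(b), []).append((int(a), ei))
        used: set[int] = set()
        loops = []
        for start in sorted(adj):
            if all(ei in used for _, ei in adj[start]):
                continue
            loop = [start]
            cur = start
            while True:
                nxt = next(((v, ei) for v, ei in adj[cur] if ei not in used), None)
                if nxt is None:
                    break
                used.add(nxt[1])
                cur = nxt[0]
                if cur == start:
                    break
                loop.append(cur)
            loops.append(loop)
        return loops

    def is_manifold(self) -> bool:
        _, counts = self.edge_face_counts()
        return bool(counts.max() <= 2)

    # -- conversions ------------------------------------------------------
    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def copy(self) -> "TriangleSurface":
        return TriangleSurface(self.vertices.copy(), self.faces.copy(), validate=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def __repr__(self):
        return f"TriangleSurface({self.n_vertices} vertices, {self.n_faces} faces)"


@dataclass
class HeadModel:
    """A head surface plus its four 10/20 reference points (nasion-ear frame)."""

    surface: TriangleSurface
    refs: ReferenceSet
    label: str = "head"

    def __post_init__(self):
        _, d = closest_surface_points(self.surface, self.refs.as_array())
        if d.max() > 1e-3:
            raise GeometryError(
                f"reference points are not on the surface (max {d.max():.4f} mm)"
            )


# ---------------------------------------------------------------------------
# synthetic heads
# ---------------------------------------------------------------------------

def _uv_cap_unit(cut_z: float, n_azimuth: int):
    """Unit-sphere cap as a mirror-symmetric UV mesh.

    Rings of ``n_azimuth`` points at constant polar angle, a pole vertex, and
    one projected centre point per quad (fan split keeps the triangulation
    symmetric under x -> -x and y -> -y, which measurement symmetry tests
    rely on).  Azimuth 0 is +x, so the four cardinal equator points
    (+-1,0,0), (0,+-1,0) are exact vertices whenever n_azimuth % 4 == 0.
    """
    if n_azimuth % 4 != 0 or n_azimuth < 8:
        raise GeometryError("n_azimuth must be a multiple of 4, >= 8")
    if not (-1.0 <= cut_z <= 0.0):
        raise GeometryError("cut_z must lie in [-radius, 0]")
    dtheta = 2 * np.pi / n_azimuth
    theta_eq = np.pi / 2
    theta_max = np.arccos(cut_z)
    k_eq = n_azimuth // 4
    thetas = [k * dtheta for k in range(1, k_eq + 1)]  # includes equator exactly
    t = theta_eq
    while t + dtheta < theta_max - 1e-12:
        t += dtheta
        thetas.append(t)
    if theta_max > theta_eq + 1e-12:
        thetas.append(theta_max)
    thetas = np.array(thetas)

    phis = np.arange(n_azimuth) * dtheta
    verts = [np.array([0.0, 0.0, 1.0])]  # pole = index 0
    ring_start = {}
    for j, th in enumerate(thetas):
        ring_start[j] = len(verts)
        st, ct = np.sin(th), np.cos(th)
        ring = np.column_stack([st * np.cos(phis), st * np.sin(phis), np.full(n_azimuth, ct)])
        verts.extend(ring)
    faces = []
    # pole fan
    r0 = ring_start[0]
    for a in range(n_azimuth):
        b = (a + 1) % n_azimuth
        faces.append((0, r0 + a, r0 + b))
    # quads between rings, split by a projected centre vertex
    for j in range(len(thetas) - 1):
        ra, rb = ring_start[j], ring_start[j + 1]
        for a in range(n_azimuth):
            b = (a + 1) % n_azimuth
            quad = [ra + a, ra + b, rb + b, rb + a]
            centre = np.mean([verts[q] for q in quad], axis=0)
            centre = centre / np.linalg.norm(centre)
            ci = len(verts)
            verts.append(centre)
            for k in range(4):
                faces.append((quad[k], quad[(k + 1) % 4], ci))
    return np.array(verts), np.array(faces, dtype=np.int64)


def make_sphere_head(radius: float, cut_z: float = 0.0, n_azimuth: int = 144) -> HeadModel:
    """Spherical head cap of the given radius, refs at the cardinal equator
    points: Nz=(0,r,0), Iz=(0,-r,0), AL=(-r,0,0), AR=(r,0,0); Cz pole (0,0,r).
    """
    if radius <= 0:
        raise GeometryError("radius must be positive")
    v, f = _uv_cap_unit(cut_z / radius, n_azimuth)
    surf = TriangleSurface(v * radius, f)
    refs = ReferenceSet(
        nz=(0, radius, 0), iz=(0, -radius, 0), al=(-radius, 0, 0), ar=(radius, 0, 0)
    )
    return HeadModel(surf, refs, label=f"sphere(r={radius:g})")


def make_ellipsoid_head(
    a: float,
    b: float,
    c: float,
    bump_amplitude: float = 0.0,
    seed: int = 0,
    cut_z: float = 0.0,
    n_azimuth: int = 144,
) -> HeadModel:
    """Semi-ellipsoid head cap (semi-axes a: left-right, b: front-back,
    c: vertical) with optional smooth low-frequency radial bumps.

    The bump field is a fixed sum of low-frequency cosines with seeded random
    directions and phases, windowed by the squared unit height so it vanishes
    on the equator (where the reference points sit) and is strongest near the
    vertex; displacement is rescaled so its maximum equals ``bump_amplitude``.
    With ``bump_amplitude=0`` and a=b=c the result equals ``make_sphere_head``.
    """
    if min(a, b, c) <= 0:
        raise GeometryError("semi-axes must be positive")
    if bump_amplitude < 0:
        raise GeometryError("bump_amplitude must be >= 0")
    u, f = _uv_cap_unit(cut_z / c, n_azimuth)
    v = u * np.array([a, b, c])
    if bump_amplitude > 0:
        rng = np.random.default_rng(seed)
        field_vals = np.zeros(len(u))
        for _ in range(6):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            freq = rng.uniform(1.5, 4.0)
            phase = rng.uniform(0, 2 * np.pi)
            field_vals += rng.uniform(0.3, 1.0) * np.cos(freq * (u @ d) + phase)
        window = u[:, 2] ** 2
        g = field_vals * window
        disp = np.abs(g) * np.linalg.norm(v, axis=1)
        m = disp.max()
        if m > 0:
            g *= bump_amplitude / m
        v = v * (1.0 + g)[:, None]
    surf = TriangleSurface(v, f)
    refs = ReferenceSet(nz=(0, b, 0), iz=(0, -b, 0), al=(-a, 0, 0), ar=(a, 0, 0))
    return HeadModel(surf, refs, label=f"ellipsoid(a={a:g},b={b:g},c={c:g},bump={bump_amplitude:g})")


# ---------------------------------------------------------------------------
# mesh file I/O (trimesh-backed; ASCII PLY is the canonical output)
# ---------------------------------------------------------------------------

def load_surface(path) -> TriangleSurface:
    try:
        mesh = trimesh.load_mesh(str(path))
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise GeometryError(f"cannot parse mesh file {path}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise GeometryError(f"no geometry in {path}")
        mesh = trimesh.util.concatenate(geoms)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise GeometryError(f"no triangle faces in {path}")
    return TriangleSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def save_surface(surface: TriangleSurface, path) -> None:
    path = str(path)
    mesh = surface.as_trimesh()
    if path.lower().endswith(".ply"):
        data = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
        with open(path, "wb") as fh:
            fh.write(data)
    else:
        mesh.export(path)


# ---------------------------------------------------------------------------
# exact closest point on a triangle surface
# ---------------------------------------------------------------------------

def _closest_on_triangles(tri: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` on each triangle of ``tri`` (m, 3, 3) -> (m, 3).

    Vectorised region-based point-triangle projection (Ericson).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(tri), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    t = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    t = np.where(np.abs(d2 - d6) > 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def closest_surface_point(surface: TriangleSurface, p) -> tuple[np.ndarray, float]:
    """Exact closest point on any triangle of the surface, and its distance."""
    pts, d = closest_surface_points(surface, np.asarray(p, dtype=float).reshape(1, 3))
    return pts[0], float(d[0])


class _SurfaceProximity:
    """KD-tree accelerated exact closest-point queries against one surface."""

    def __init__(self, surface: TriangleSurface):
        from scipy.spatial import cKDTree

        self.tri = surface.vertices[surface.faces]
        self.centroids = self.tri.mean(axis=1)
        # circumscribing radius bound per triangle (max centroid-to-vertex)
        self.radii = np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2).max(axis=1)
        self.rmax = float(self.radii.max())
        self.vtree = cKDTree(surface.vertices)
        self.ctree = cKDTree(self.centroids)

    def query(self, points: np.ndarray):
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        out_p = np.empty_like(points)
        out_d = np.empty(len(points))
        upper, _ = self.vtree.query(points)  # distance to nearest vertex bounds the answer
        for i, (p, ub) in enumerate(zip(points, upper)):
            idx = self.ctree.query_ball_point(p, ub + self.rmax + 1e-12)
            cand = self.tri[idx] if idx else self.tri
            cp = _closest_on_triangles(cand, p)
            dd = np.linalg.norm(cp - p, axis=1)
            j = int(np.argmin(dd))
            out_p[i], out_d[i] = cp[j], dd[j]
        return out_p, out_d


def closest_surface_points(surface: TriangleSurface, points) -> tuple[np.ndarray, np.ndarray]:
    """Batch exact closest points; returns ((n,3) points, (n,) distances)."""
    if surface.n_faces == 0:
        raise GeometryError("empty surface")
    return _SurfaceProximity(surface).query(points)


# ---------------------------------------------------------------------------
# point-file I/O: CSV with header name,x,y,z (mm)
# ---------------------------------------------------------------------------

_REF_NAMES = {"nz": "nz", "iz": "iz", "al": "al", "ar": "ar"}


def load_points_csv(path) -> tuple[ReferenceSet, np.ndarray, list[str]]:
    """Read a labelled point file.  Returns (refs, other points, other names).

    Reference rows are identified by the names Nz, Iz, AL, AR
    (case-insensitive); every other row is a reconstruction point.
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise GeometryError(f"point CSV must have columns name,x,y,z; got {list(df.columns)}")
    refs = {}
    pts, names = [], []
    for _, row in df.iterrows():
        key = str(row["name"]).strip().lower()
        p = np.array([row["x"], row["y"], row["z"]], dtype=float)
        if key in _REF_NAMES:
            refs[key] = p
        else:
            pts.append(p)
            names.append(str(row["name"]).strip())
    missing = set(_REF_NAMES) - set(refs)
    if missing:
        raise GeometryError(f"missing reference points in {path}: {sorted(missing)}")
    cloud = np.array(pts).reshape(-1, 3)
    return ReferenceSet(**refs), cloud, names


def save_points_csv(path, refs: ReferenceSet | None, points=None, names=None, header_comment: str | None = None) -> None:
    rows = []
    if refs is not None:
        for name, p in zip(("Nz", "Iz", "AL", "AR"), refs.as_array()):
            rows.append((name, *p))
    if points is not None:
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if names is None:
            names = [f"P{i + 1}" for i in range(len(points))]
        for name, p in zip(names, points):
            rows.append((name, *p))
    df = pd.DataFrame(rows, columns=["name", "x", "y", "z"])
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
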