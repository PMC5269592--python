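"""Virtual 10/20 measurement on a triangle surface.

The 10/20 landmarks are defined by fractional arc lengths along scalp curves
cut by planes through anchor points:

* sagittal curve Nz -> Iz (plane through Cz): Fpz, Fz, Cz, Pz, Oz at
  10/30/50/70/90 %;
* coronal curve AL -> AR (plane through Cz): T3, C3, Cz, C4, T4;
* two half-circumference curves Fpz -> Oz anchored through T3 (left) and T4
  (right): Fp1, F7, T5, O1 and Fp2, F8, T6, O2 at 10/30/70/90 %;
* transverse curves F7-Fz-F8 and T5-Pz-T6 supply F3/F4 and P3/P4 as the
  midpoints of their half-arcs.

Cz itself is the fixed point of alternating 50 % measurements on the
sagittal and coronal curves.  The same machinery at 5 % resolution yields
the dense candidate grid from which sparse samples are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .head_model import (
    GeometryError,
    ReferenceSet,
    TriangleSurface,
    build_nasion_ear_frame,
    closest_surface_point,
    closest_surface_points,
)

__all__ = [
    "CurveError",
    "ConvergenceError",
    "SurfaceCurve",
    "LandmarkSet",
    "CandidateGrid",
    "LANDMARK_NAMES",
    "plane_surface_curve",
    "point_at_fraction",
    "locate_cz",
    "measure_1020",
    "measure_105_grid",
]

LANDMARK_NAMES = (
    "Fpz", "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T3", "T4",
    "Pz", "P3", "P4", "T5", "T6", "O1", "O2", "Oz",
)


class CurveError(GeometryError):
    """Plane-surface intersection did not yield a usable curve."""


class ConvergenceError(RuntimeError):
    """Iterative Cz localisation failed to converge."""


@dataclass
class SurfaceCurve:
    """Ordered polyline on a surface with cumulative arc length (mm)."""

    points: np.ndarray            # (k, 3)
    arclength: np.ndarray = field(init=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise CurveError("curve needs at least two points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])
        if self.arclength[-1] <= 0:
            raise CurveError("zero-length curve")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, f: float) -> np.ndarray:
        return point_at_fraction(self, f)


def point_at_fraction(curve: SurfaceCurve, f: float) -> np.ndarray:
    """Point at arc-length fraction ``f`` in [0, 1] (linear within segment)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {f}")
    s = f * curve.length
    i = int(np.searchsorted(curve.arclength, s, side="right") - 1)
    i = min(max(i, 0), len(curve.points) - 2)
    s0, s1 = curve.arclength[i], curve.arclength[i + 1]
    t = 0.0 if s1 == s0 else (s - s0) / (s1 - s0)
    return curve.points[i] + t * (curve.points[i + 1] - curve.points[i])


# ---------------------------------------------------------------------------
# plane-surface intersection
# ---------------------------------------------------------------------------

def _chain_segments(segments: np.ndarray, tol: float):
    """Chain unordered 3-D segments into polylines / closed loops.

    Endpoints are merged on a grid of pitch ``tol``.  Returns a list of
    (points (k,3), closed: bool).
    """
    if len(segments) == 0:
        return []
    ends = segments.reshape(-1, 3)
    key = np.round(ends / tol).astype(np.int64)
    _, node_of = np.unique(key, axis=0, return_inverse=True)
    node_pos: dict[int, np.ndarray] = {}
    adj: dict[int, list[tuple[int, int]]] = {}
    for si in range(len(segments)):
        a, b = int(node_of[2 * si]), int(node_of[2 * si + 1])
        if a == b:
            continue
        node_pos.setdefault(a, ends[2 * si])
        node_pos.setdefault(b, ends[2 * si + 1])
        adj.setdefault(a, []).append((b, si))
        adj.setdefault(b, []).append((a, si))
    used = set()
    out = []

    def walk(start, first):
        path = [start]
        cur, prev_seg = start, None
        while True:
            nxt = None
            for nb, si in adj[cur]:
                if si not in used:
                    nxt = (nb, si)
                    break
            if nxt is None:
                return path, False
            used.add(nxt[1])
            cur = nxt[0]
            path.append(cur)
            if cur == start:
                return path, True

    # open chains first (start at odd-degree nodes)
    for node in sorted(adj):
        deg_free = sum(1 for _, si in adj[node] if si not in used)
        if deg_free == 1:
            path, closed = walk(node, None)
            if len(path) > 1:
                out.append((np.array([node_pos[p] for p in path]), closed))
    # remaining closed loops
    for node in sorted(adj):
        if any(si not in used for _, si in adj[node]):
            path, closed = walk(node, None)
            if len(path) > 1:
                out.append((np.array([node_pos[p] for p in path]), closed))
    return out


def _locate_on_polyline(points: np.ndarray, p: np.ndarray):
    """(arc position, distance) of the closest point of a polyline to p."""
    a = points[:-1]
    b = points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", p - a, ab) / np.where(denom == 0, 1, denom)
    t = np.clip(t, 0, 1)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - p, axis=1)
    i = int(np.argmin(d))
    seg = np.linalg.norm(ab, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s[i] + t[i] * seg[i], float(d[i]), proj[i]


def plane_surface_curve(S: TriangleSurface, a, b, c) -> SurfaceCurve:
    """Curve from ``a`` to ``b`` along the intersection of the surface with
    the plane through ``a``, ``b``, ``c``.

    For closed intersection loops the arc passing nearer to ``c`` is taken
    (this is how circumference halves are anchored through T3/T4).
    """
    a = np.asarray(a, dtype=float).reshape(3)
    b = np.asarray(b, dtype=float).reshape(3)
    c = np.asarray(c, dtype=float).reshape(3)
    scale = max(float(np.ptp(S.vertices, axis=0).max()), 1.0)
    if np.linalg.norm(a - b) < 1e-9 * scale:
        raise CurveError("curve endpoints coincide")
    normal = np.cross(b - a, c - a)
    nn = np.linalg.norm(normal)
    if nn < 1e-12 * scale**2:
        raise CurveError("plane anchors are collinear")
    normal = normal / nn

    mesh = trimesh.Trimesh(S.vertices, S.faces, process=False)
    segments = trimesh.intersections.mesh_plane(mesh, normal, a)
    if len(segments) == 0:
        raise CurveError("plane does not intersect the surface")
    chains = _chain_segments(np.asarray(segments), tol=1e-7 * scale)

    # the plane may exit the surface near its boundary (open caps whose rim
    # bulges through the cutting plane between the reference points); merged
    # chains continuing along the mesh boundary are additional candidates
    candidates = list(chains)
    if any(not closed for _, closed in chains):
        bridged = _bridge_chains_along_boundary(S, chains, scale, normal, a)
        if bridged:
            candidates.extend(bridged)

    # every route containing both endpoints is a candidate; the route
    # passing nearest the third anchor c wins (this is how circumference
    # halves are steered through T3/T4)
    tol_end = 1e-3 * scale
    best = None        # (d_c, sub)
    best_miss = np.inf
    for pts, closed in candidates:
        sa, da, _ = _locate_on_polyline(pts, a)
        sb, db, _ = _locate_on_polyline(pts, b)
        miss = max(da, db)
        best_miss = min(best_miss, miss)
        if miss > tol_end:
            continue
        for sub in _routes(pts, closed, sa, sb):
            _, d_c, _ = _locate_on_polyline(sub, c)
            if best is None or d_c < best[0]:
                best = (d_c, sub)
    if best is None:
        # tangential planes (e.g. through the tip of a boundary notch) can
        # miss an endpoint's neighbourhood entirely; fall back to angular
        # marching through a thin vertex slab around the plane
        sub = _slab_march_curve(S, a, b, c, normal, scale)
        if sub is None:
            raise CurveError(
                f"no intersection component contains both endpoints (miss {best_miss:.4g} mm)"
            )
        best = (0.0, sub)
    sub = best[1]
    # orient a -> b
    if np.linalg.norm(sub[0] - a) > np.linalg.norm(sub[0] - b):
        sub = sub[::-1]
    # reconstructed caps can fold near deep boundary notches; scalp curves
    # are star-shaped about the frame origin, so enforce monotone angular
    # progress, keeping the outermost sheet
    sub = _drop_folds(sub, normal)
    # snap exact endpoints
    sub = sub.copy()
    sub[0], sub[-1] = a, b
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(sub, axis=0), axis=1) > 1e-10 * scale]
    )
    sub = sub[keep]
    if len(sub) < 2:
        raise CurveError("degenerate (zero-length) intersection curve")
    return SurfaceCurve(points=sub)


def _routes(pts, closed, sa, sb):
    """Sub-polylines of a chain connecting arc positions sa and sb: one for
    an open chain, the two complementary arcs for a closed loop."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]

    def extract(s0, s1):
        i0 = int(np.searchsorted(s, s0, side="right") - 1)
        i1 = int(np.searchsorted(s, s1, side="left"))
        p0 = _interp_on(pts, s, s0)
        p1 = _interp_on(pts, s, s1)
        return np.vstack([[p0], pts[i0 + 1 : i1], [p1]])

    lo, hi = min(sa, sb), max(sa, sb)
    if lo == hi:
        return []
    direct = extract(lo, hi)
    if not closed:
        return [direct]
    if hi < total:
        around = np.vstack([extract(hi, total), extract(0.0, lo)[1:]])
    else:
        around = extract(0.0, lo)
    return [direct, around] if len(around) >= 2 else [direct]


def _bridge_chains_along_boundary(S, chains, scale, normal=None, plane_pt=None):
    """Join open section chains whose ends lie on the surface boundary.

    Section curves end where the cutting plane crosses a boundary edge, so
    gap ends sit on the boundary loop in alternating order; adjacent ends of
    different gaps are connected by the boundary sub-polyline (the shorter
    of the two alternating matchings), keeping the curve on the surface.
    Boundary paths that wander far off the cutting plane, or are much longer
    than the gap, are replaced by the straight gap chord.  Returns merged
    chains, or None when the configuration does not fit.
    """
    open_chains = [pts for pts, closed in chains if not closed]
    if not open_chains:
        return None
    loops = S.boundary_loops()
    if len(loops) != 1:
        return None
    loop_pts = S.vertices[loops[0] + loops[0][:1]]
    seg = np.linalg.norm(np.diff(loop_pts, axis=0), axis=1)
    s_loop = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_loop[-1]

    ends = []  # (arc position on loop, chain index, end index 0|1)
    for k, pts in enumerate(open_chains):
        for e, p in ((0, pts[0]), (1, pts[-1])):
            s, d, proj = _locate_on_polyline(loop_pts, p)
            if d > 1e-3 * scale:
                return None  # chain end not on the boundary
            ends.append((s, k, e))
    ends.sort()
    n = len(ends)
    if n % 2:
        return None

    def arc(s0, s1):
        """Boundary sub-polyline from s0 forward (cyclic) to s1."""
        span = (s1 - s0) % total
        # interior loop vertices strictly between s0 and s0+span
        inner = []
        for sv, pv in zip(s_loop[:-1], loop_pts[:-1]):
            rel = (sv - s0) % total
            if 1e-12 < rel < span - 1e-12:
                inner.append((rel, pv))
        inner.sort(key=lambda t: t[0])
        pts = [_interp_on(loop_pts, s_loop, s0)]
        pts.extend(p for _, p in inner)
        pts.append(_interp_on(loop_pts, s_loop, s1))
        pts = np.array(pts)
        chord = np.linalg.norm(pts[-1] - pts[0])
        path_len = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        if normal is not None and len(pts) > 2:
            off_plane = float(np.abs((pts - plane_pt) @ normal).max())
            if off_plane > 0.03 * scale or path_len > 2 * chord + 0.03 * scale:
                return np.array([pts[0], pts[-1]])  # straight gap chord
        return pts

    # two alternating matchings of adjacent ends; prefer the shorter bridges
    def matching(offset):
        pairs, length = [], 0.0
        for j in range(0, n, 2):
            e0 = ends[(j + offset) % n]
            e1 = ends[(j + 1 + offset) % n]
            d = (e1[0] - e0[0]) % total
            pairs.append((e0, e1))
            length += d
        return pairs, length

    m0, l0 = matching(0)
    m1, l1 = matching(1)
    pairs = m0 if l0 <= l1 else m1

    # assemble merged polylines: walk chains and bridges alternately
    bridge_of = {}
    for (s0, k0, e0), (s1, k1, e1) in pairs:
        br = arc(s0, s1)
        bridge_of[(k0, e0)] = ((k1, e1), br)
        bridge_of[(k1, e1)] = ((k0, e0), br[::-1])

    merged = []
    used_chain = set()
    for k0 in range(len(open_chains)):
        if k0 in used_chain:
            continue
        used_chain.add(k0)
        pts = open_chains[k0]
        start_key, tail_key = (k0, 0), (k0, 1)
        closed = False
        while tail_key in bridge_of:
            (k1, e1), br = bridge_of[tail_key]
            if k1 == start_key[0] and e1 == start_key[1]:
                pts = np.vstack([pts, br[1:]])
                closed = True
                break
            if k1 in used_chain:
                break
            used_chain.add(k1)
            nxt = open_chains[k1] if e1 == 0 else open_chains[k1][::-1]
            pts = np.vstack([pts, br[1:], nxt[1:]])
            tail_key = (k1, 1 - e1)
        merged.append((pts, closed))
    return merged


def _slab_march_curve(S, a, b, c, normal, scale):
    """Approximate section curve by angular marching through a vertex slab.

    Vertices within a thin slab around the cutting plane are projected onto
    it and parameterised by angle about the projected nasion-ear origin; the
    outermost point per angular bin forms the curve from a to b, taking the
    direction that passes the anchor c.  Used only when exact mesh
    sectioning fails; the result approximates the scalp curve to within the
    slab half-width.
    """
    edges = S.vertices[S.faces[:, 0]] - S.vertices[S.faces[:, 1]]
    h = 1.5 * float(np.median(np.linalg.norm(edges, axis=1)))
    origin = np.zeros(3)
    c0 = origin - np.dot(origin - a, normal) * normal
    ra = a - c0
    if np.linalg.norm(ra) < 1e-9:
        return None
    u = ra / np.linalg.norm(ra)
    w = np.cross(normal, u)

    def angle_of(p):
        rel = p - c0
        return float(np.arctan2(rel @ w, rel @ u))

    th_b, th_c = angle_of(b), angle_of(c)
    if abs(th_b) < 1e-9:
        return None
    # direction: does going +theta from 0 to th_b pass th_c?
    fwd_b = th_b % (2 * np.pi)
    fwd_c = th_c % (2 * np.pi)
    direction = 1.0 if fwd_c <= fwd_b + 1e-12 else -1.0
    span = fwd_b if direction > 0 else 2 * np.pi - fwd_b

    for attempt in range(3):
        d = (S.vertices - a) @ normal
        sel = np.abs(d) <= h * (2**attempt)
        if sel.sum() < 20:
            continue
        pts = S.vertices[sel]
        rel = (pts - d[sel, None] * normal) - c0
        th = np.arctan2(rel @ w, rel @ u) * direction % (2 * np.pi)
        r = np.linalg.norm(rel, axis=1)
        inside = th <= span + 1e-9
        if inside.sum() < 5:
            continue
        th, r = th[inside], r[inside]
        nbin = max(16, min(128, int(span / 0.02)))
        edges_th = np.linspace(0.0, span, nbin + 1)
        idx = np.clip(np.digitize(th, edges_th) - 1, 0, nbin - 1)
        rad = np.full(nbin, np.nan)
        for i, rr in zip(idx, r):
            if np.isnan(rad[i]) or rr > rad[i]:
                rad[i] = rr
        centers = 0.5 * (edges_th[:-1] + edges_th[1:])
        ok = ~np.isnan(rad)
        if ok.sum() < max(4, nbin // 4):
            continue
        rad = np.interp(centers, centers[ok], rad[ok])
        ang = centers * direction
        curve_pts = c0 + rad[:, None] * (
            np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * w
        )
        return np.vstack([[a], curve_pts, [b]])
    return None


def _drop_folds(sub: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Remove fold retraces from a section polyline.

    Points are parameterised by their angle about the projection of the
    nasion-ear origin onto the cutting plane; only points advancing the
    running angular maximum are kept (endpoints always survive).  Healthy
    star-shaped curves pass through unchanged.
    """
    if len(sub) < 4:
        return sub
    origin = np.zeros(3)
    c0 = origin - np.dot(origin - sub[0], normal) * normal
    rel = sub - c0
    r = np.linalg.norm(rel, axis=1)
    if r.min() < 1e-9:
        return sub  # curve passes through the centre; angles undefined
    u = rel[0] / r[0]
    w = np.cross(normal, u)
    th = np.unwrap(np.arctan2(rel @ w, rel @ u))
    if abs(th[-1] - th[0]) < 1e-12:
        return sub
    if th[-1] < th[0]:
        th = -th
    if np.all(np.diff(th) >= -1e-12):
        return sub
    keep = [0]
    hi = th[0]
    for i in range(1, len(sub) - 1):
        if th[i] > hi + 1e-12 and th[i] <= th[-1] + 1e-12:
            keep.append(i)
            hi = th[i]
    keep.append(len(sub) - 1)
    return sub[keep]


def _interp_on(pts, s, val):
    i = int(np.searchsorted(s, val, side="right") - 1)
    i = min(max(i, 0), len(pts) - 2)
    if s[i + 1] == s[i]:
        return pts[i]
    t = (val - s[i]) / (s[i + 1] - s[i])
    return pts[i] + t * (pts[i + 1] - pts[i])


# ---------------------------------------------------------------------------
# Cz and the 21 landmarks
# ---------------------------------------------------------------------------

def _snap(S, p):
    q, _ = closest_surface_point(S, p)
    return q


def _canonicalise(S: TriangleSurface, refs: ReferenceSet):
    """Express surface and refs in the nasion-ear frame built from the refs
    (all curve machinery assumes that frame); returns the frame too so
    results can be mapped back to the input coordinates."""
    frame = build_nasion_ear_frame(refs.nz, refs.al, refs.ar)
    if np.allclose(frame.origin, 0, atol=1e-9) and np.allclose(
        frame.rotation, np.eye(3), atol=1e-12
    ):
        return S, refs, None
    S_f = TriangleSurface(frame.to_frame(S.vertices), S.faces, validate=False)
    refs_f = refs.transform(frame.to_frame)
    return S_f, refs_f, frame


def locate_cz(
    S: TriangleSurface,
    refs: ReferenceSet,
    tol: float = 0.01,
    max_iter: int = 50,
) -> np.ndarray:
    """Vertex landmark Cz: fixed point of alternating 50 % measurements.

    Each iteration takes the midpoint of the Nz->Iz curve through the current
    estimate, then the midpoint of the AL->AR curve through that point;
    stops when the update moves less than ``tol`` mm.
    """
    S, refs, frame = _canonicalise(S, refs)
    cz = _locate_cz_canonical(S, refs, tol, max_iter)
    return frame.to_world(cz) if frame is not None else cz


def _locate_cz_canonical(S, refs, tol=0.01, max_iter=50):
    nz, iz = _snap(S, refs.nz), _snap(S, refs.iz)
    al, ar = _snap(S, refs.al), _snap(S, refs.ar)
    cz = S.vertices[int(np.argmax(S.vertices[:, 2]))]
    disp = np.inf
    for _ in range(max_iter):
        c1 = plane_surface_curve(S, nz, iz, cz)
        cz1 = point_at_fraction(c1, 0.5)
        c2 = plane_surface_curve(S, al, ar, cz1)
        cz2 = point_at_fraction(c2, 0.5)
        disp = float(np.linalg.norm(cz2 - cz))
        cz = cz2
        if disp < tol:
            return cz
    raise ConvergenceError(
        f"Cz iteration did not converge in {max_iter} iterations "
        f"(last displacement {disp:.4f} mm)"
    )


class LandmarkSet(dict):
    """Mapping landmark name -> (3,) position; insertion order preserved."""

    def as_array(self, names=LANDMARK_NAMES) -> np.ndarray:
        return np.array([self[n] for n in names])

    @classmethod
    def from_arrays(cls, names, points) -> "LandmarkSet":
        return cls(zip(names, np.asarray(points, dtype=float)))

    def transform(self, fn) -> "LandmarkSet":
        return LandmarkSet({k: np.asarray(fn(v), dtype=float) for k, v in self.items()})


def measure_1020(S: TriangleSurface, refs: ReferenceSet, tol: float = 0.01) -> LandmarkSet:
    """Measure all 21 10/20 landmarks on a surface (any rigid pose; the
    refs define the measurement frame)."""
    S, refs, frame = _canonicalise(S, refs)
    lm = _measure_1020_canonical(S, refs, tol)
    return lm.transform(frame.to_world) if frame is not None else lm


def _measure_1020_canonical(S, refs, tol=0.01):
    cz = _locate_cz_canonical(S, refs, tol=tol)
    nz, iz = _snap(S, refs.nz), _snap(S, refs.iz)
    al, ar = _snap(S, refs.al), _snap(S, refs.ar)

    lm = LandmarkSet()
    sag = plane_surface_curve(S, nz, iz, cz)
    for name, f in zip(("Fpz", "Fz", "Cz", "Pz", "Oz"), (0.1, 0.3, 0.5, 0.7, 0.9)):
        lm[name] = point_at_fraction(sag, f)
    cor = plane_surface_curve(S, al, ar, lm["Cz"])
    for name, f in zip(("T3", "C3", "C4", "T4"), (0.1, 0.3, 0.7, 0.9)):
        lm[name] = point_at_fraction(cor, f)

    circ_l = plane_surface_curve(S, lm["Fpz"], lm["Oz"], lm["T3"])
    for name, f in zip(("Fp1", "F7", "T5", "O1"), (0.1, 0.3, 0.7, 0.9)):
        lm[name] = point_at_fraction(circ_l, f)
    circ_r = plane_surface_curve(S, lm["Fpz"], lm["Oz"], lm["T4"])
    for name, f in zip(("Fp2", "F8", "T6", "O2"), (0.1, 0.3, 0.7, 0.9)):
        lm[name] = point_at_fraction(circ_r, f)

    # transverse curves: F3/F4 midway on the F7-Fz / Fz-F8 sub-arcs,
    # P3/P4 midway on T5-Pz / Pz-T6
    lm["F3"], lm["F4"] = _half_arc_pair(S, lm["F7"], lm["Fz"], lm["F8"])
    lm["P3"], lm["P4"] = _half_arc_pair(S, lm["T5"], lm["Pz"], lm["T6"])

    return LandmarkSet({n: lm[n] for n in LANDMARK_NAMES})


def _half_arc_pair(S, left, mid, right):
    """Midpoints of the left->mid and mid->right sub-arcs of the transverse
    curve left->right anchored through mid."""
    curve = plane_surface_curve(S, left, right, mid)
    s_mid, _, _ = _locate_on_polyline(curve.points, mid)
    f_mid = s_mid / curve.length
    return (
        point_at_fraction(curve, 0.5 * f_mid),
        point_at_fraction(curve, 0.5 * (f_mid + 1.0)),
    )


# ---------------------------------------------------------------------------
# 5 %-resolution candidate grid
# ---------------------------------------------------------------------------

@dataclass
class CandidateGrid:
    """Named scalp positions at 5 % proportional spacing, partitioned into
    10 region subsets of roughly equal coverage."""

    names: list[str]
    points: np.ndarray
    regions: list[str]
    refs: ReferenceSet

    @property
    def subsets(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, r in enumerate(self.regions):
            out.setdefault(r, []).append(i)
        return {k: np.array(v) for k, v in out.items()}

    def __len__(self):
        return len(self.names)


REGIONS = (
    "midline-frontal", "midline-posterior",
    "frontal-left", "frontal-right",
    "central-left", "central-right",
    "temporal-left", "temporal-right",
    "parieto-occipital-left", "parieto-occipital-right",
)


def _region_of(p: np.ndarray) -> str:
    """Region subset of a scalp position (nasion-ear frame).

    The ten subsets tile the upper head in patches of roughly equal
    coverage: a midline band split front/back, and per side a high central
    patch, a low temporal band, and frontal / parieto-occipital sectors.
    """
    u = p / np.linalg.norm(p)
    if abs(u[0]) < 0.25:
        return "midline-frontal" if u[1] >= 0 else "midline-posterior"
    side = "left" if u[0] < 0 else "right"
    if u[2] >= 0.72:
        return f"central-{side}"
    alpha = np.degrees(np.arctan2(u[1], abs(u[0])))
    if alpha >= 40:
        return f"frontal-{side}"
    if alpha <= -40:
        return f"parieto-occipital-{side}"
    return f"temporal-{side}"


def measure_105_grid(
    S: TriangleSurface,
    refs: ReferenceSet,
    tol: float = 0.01,
    min_separation: float = 0.5,
) -> CandidateGrid:
    """Candidate sampling grid at 5 % resolution.

    Sagittal, coronal and the two half-circumference curves are sampled
    every 5 %; transverse curves between matching left/right circumference
    levels (20-80 %, through the sagittal point at the same level) every
    10 %.  Near-duplicate positions (< ``min_separation`` mm) are merged.
    """
    S, refs, frame = _canonicalise(S, refs)
    lm = _measure_1020_canonical(S, refs, tol=tol)
    cz = lm["Cz"]
    nz, iz = _snap(S, refs.nz), _snap(S, refs.iz)
    al, ar = _snap(S, refs.al), _snap(S, refs.ar)

    entries: list[tuple[str, np.ndarray]] = []

    sag = plane_surface_curve(S, nz, iz, cz)
    for k in range(1, 20):
        f = 0.05 * k
        entries.append((f"SAG{int(f * 100):02d}", point_at_fraction(sag, f)))

    cor = plane_surface_curve(S, al, ar, cz)
    for k in range(1, 20):
        f = 0.05 * k
        if abs(f - 0.5) < 1e-9:
            continue  # Cz duplicates the sagittal midpoint
        entries.append((f"COR{int(f * 100):02d}", point_at_fraction(cor, f)))

    circ_l = plane_surface_curve(S, lm["Fpz"], lm["Oz"], lm["T3"])
    circ_r = plane_surface_curve(S, lm["Fpz"], lm["Oz"], lm["T4"])
    for curve, side in ((circ_l, "L"), (circ_r, "R")):
        for k in range(1, 20):
            f = 0.05 * k
            entries.append((f"CIRC{side}{int(f * 100):02d}", point_at_fraction(curve, f)))

    # transverse curves between matching circumference levels
    for k_level in range(3, 18):
        level = 0.05 * k_level
        pl = point_at_fraction(circ_l, level)
        pr = point_at_fraction(circ_r, level)
        ps = point_at_fraction(sag, level)
        try:
            tc = plane_surface_curve(S, pl, pr, ps)
        except CurveError:
            continue
        for k in range(1, 10):
            f = 0.1 * k
            if abs(f - 0.5) < 1e-9:
                continue  # midpoint duplicates the sagittal point
            entries.append(
                (f"TRV{int(round(level * 100)):02d}F{int(f * 100):02d}",
                 point_at_fraction(tc, f))
            )

    names, points, regions = [], [], []
    for name, p in entries:
        if points and np.min(np.linalg.norm(np.array(points) - p, axis=1)) < min_separation:
            continue
        names.append(name)
        points.append(p)
        regions.append(_region_of(p))

    points = np.array(points)
    if frame is not None:
        points = frame.to_world(points)
        refs = refs.transform(frame.to_world)
    grid = CandidateGrid(names=names, points=points, regions=regions, refs=refs)
    missing = set(REGIONS) - set(grid.subsets)
    if missing:
        raise CurveError(f"candidate grid left regions empty: {sorted(missing)}")
    return grid
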