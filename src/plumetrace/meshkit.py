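"""Triangle meshes of feather vane swatches: I/O, validation, cropping, ray queries.

Conventions
-----------
All geometry is in micrometres.  Wavefront OBJ carries no unit information, so
micrometres are asserted by convention (and logged on read).  The feather vane
lies in the xy-plane with +z pointing to the obverse (exposed) surface, +x
toward the distal tip and -x toward the proximal base.

Ray queries run against a bounding-volume hierarchy built once per mesh
(:func:`build_accel`); :func:`intersect_exhaustive` is the brute-force
per-triangle scan used as an oracle for the accelerated path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

log = logging.getLogger("plumetrace")

#: offset (um) along the outgoing ray used to avoid self-intersection.
#: Must sit far above float rounding at swatch scale (~1e-13 um) yet far
#: below any real surface separation, or grazing corner hits can tunnel
#: through watertight geometry and get trapped inside a solid.
EPS_SELF_INTERSECT = 1e-6

_LEAF_SIZE = 4


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Triangle surface mesh in micrometre coordinates.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    tags : free-form metadata (species label, generator seed, ...)
    """

    vertices: np.ndarray
    faces: np.ndarray
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates must be finite")
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face references an out-of-range vertex")
        self._face_normals: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    @property
    def face_normals(self) -> np.ndarray:
        """Unit geometric normals from winding (right-hand rule)."""
        if self._face_normals is None:
            tri = self.triangles
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            norm = np.linalg.norm(n, axis=1)
            norm[norm == 0] = 1.0
            self._face_normals = n / norm[:, None]
        return self._face_normals

    @property
    def face_areas(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array: [min corner, max corner] in um."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            dict(self.tags))

    def concat(self, other: "TriangleMesh") -> "TriangleMesh":
        """Disjoint union of two meshes (vertex indices re-based)."""
        verts = np.vstack([self.vertices, other.vertices])
        faces = np.vstack([self.faces, other.faces + len(self.vertices)])
        tags = dict(self.tags)
        tags.update(other.tags)
        return TriangleMesh(verts, faces, tags)


@dataclass
class MeshReport:
    """Topology census of a mesh; never mutates the mesh it describes."""

    n_vertices: int
    n_faces: int
    boundary_edge_count: int
    non_manifold_edge_count: int
    is_watertight: bool
    bbox: np.ndarray  # (2, 3) min/max corners, um

    def to_json(self) -> str:
        return json.dumps({
            "n_vertices": self.n_vertices,
            "n_faces": self.n_faces,
            "boundary_edge_count": self.boundary_edge_count,
            "non_manifold_edge_count": self.non_manifold_edge_count,
            "is_watertight": self.is_watertight,
            "bbox": self.bbox.tolist(),
        }, indent=2)


@dataclass
class Hit:
    """Nearest ray-surface intersection.

    ``normal`` is the unit geometric normal flipped, if necessary, so that it
    opposes the incoming ray direction; ``cos_incidence`` is
    |direction . geometric normal| in [0, 1].
    """

    t: float
    point: np.ndarray
    normal: np.ndarray
    face_index: int
    cos_incidence: float


# ---------------------------------------------------------------------------
# OBJ I/O
# ---------------------------------------------------------------------------

class ObjParseError(ValueError):
    pass


def read_obj(path) -> TriangleMesh:
    """Read a Wavefront OBJ file into a :class:`TriangleMesh`.

    Supports ``v`` and ``f`` records (1-based indices, ``f v/vt/vn`` forms
    accepted, the extra indices ignored).  Faces with more than three vertices
    are fan-triangulated.  ``vn`` records are ignored: geometric normals are
    recomputed from winding, which is what the physics uses.  Negative
    (relative) indices are unsupported and raise.  Coordinates are taken as
    micrometres by convention.
    """
    path = Path(path)
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            key = parts[0]
            if key == "v":
                if len(parts) < 4:
                    raise ObjParseError(
                        f"{path}:{lineno}: vertex record needs 3 coordinates")
                try:
                    vertices.append([float(p) for p in parts[1:4]])
                except ValueError as exc:
                    raise ObjParseError(
                        f"{path}:{lineno}: bad vertex coordinate") from exc
            elif key == "f":
                idx = []
                for p in parts[1:]:
                    tok = p.split("/")[0]
                    try:
                        i = int(tok)
                    except ValueError as exc:
                        raise ObjParseError(
                            f"{path}:{lineno}: bad face index {tok!r}") from exc
                    if i < 0:
                        raise ObjParseError(
                            f"{path}:{lineno}: negative OBJ indices are "
                            "unsupported")
                    if i == 0:
                        raise ObjParseError(
                            f"{path}:{lineno}: OBJ indices are 1-based")
                    idx.append(i - 1)
                if len(idx) < 3:
                    raise ObjParseError(
                        f"{path}:{lineno}: face needs at least 3 vertices")
                # fan triangulation, vertex order preserved
                for k in range(1, len(idx) - 1):
                    faces.append([idx[0], idx[k], idx[k + 1]])
            # all other record types (vn, vt, o, g, s, mtllib, ...) ignored
    if not vertices or not faces:
        raise ObjParseError(f"{path}: empty mesh (no v/f records)")
    mesh = TriangleMesh(np.array(vertices), np.array(faces),
                        tags={"source": str(path)})
    log.info("read %s: %d vertices, %d triangles (units taken as um)",
             path, mesh.n_vertices, mesh.n_faces)
    return mesh


def write_obj(mesh: TriangleMesh, path) -> None:
    """Write mesh as OBJ ('v'/'f' records, 1-based).  Deterministic bytes."""
    path = Path(path)
    lines = ["# plumetrace OBJ export (coordinates in micrometres)"]
    for key in sorted(mesh.tags):
        lines.append(f"# tag {key}={mesh.tags[key]}")
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.8f} {v[1]:.8f} {v[2]:.8f}")
    for f in mesh.faces:
        lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_mesh(mesh: TriangleMesh) -> MeshReport:
    """Edge census: boundary edges are used by exactly one face, non-manifold
    edges by more than two.  Watertight iff neither occurs."""
    if mesh.n_faces == 0:
        raise ValueError("cannot validate an empty mesh")
    edges = np.vstack([mesh.faces[:, [0, 1]],
                       mesh.faces[:, [1, 2]],
                       mesh.faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = int((counts == 1).sum())
    nonmanifold = int((counts > 2).sum())
    return MeshReport(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        boundary_edge_count=boundary,
        non_manifold_edge_count=nonmanifold,
        is_watertight=(boundary == 0 and nonmanifold == 0),
        bbox=mesh.bounds,
    )


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def _clip_polygon(poly: np.ndarray, axis: int, value: float,
                  keep_below: bool) -> np.ndarray:
    """Sutherland-Hodgman clip of a 3D polygon against an axis-aligned plane."""
    out: list[np.ndarray] = []
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        da = (value - a[axis]) if keep_below else (a[axis] - value)
        db = (value - b[axis]) if keep_below else (b[axis] - value)
        # da/db >= 0 means inside (points exactly on the plane are kept)
        if da >= 0:
            out.append(a)
        if (da < 0) != (db < 0):
            t = da / (da - db)
            out.append(a + t * (b - a))
    return np.array(out) if out else np.empty((0, 3))


def crop_swatch(mesh: TriangleMesh, center_xy=(0.0, 0.0),
                side_um: float = 500.0) -> TriangleMesh:
    """Crop to the axis-aligned square prism ``side_um`` wide around
    ``center_xy``: triangles wholly outside are removed, straddling triangles
    are clipped at the boundary planes and re-triangulated."""
    if side_um <= 0:
        raise ValueError("side_um must be positive")
    cx, cy = float(center_xy[0]), float(center_xy[1])
    h = side_um / 2.0
    lo = np.array([cx - h, cy - h])
    hi = np.array([cx + h, cy + h])

    b = mesh.bounds
    if (b[0, :2] >= lo - 1e-12).all() and (b[1, :2] <= hi + 1e-12).all():
        return mesh.copy()  # entirely inside: unchanged

    tri = mesh.triangles
    txy = tri[..., :2]
    fully_in = ((txy >= lo).all(axis=(1, 2)) & (txy <= hi).all(axis=(1, 2)))
    fully_out = ((txy[..., 0] <= lo[0]).all(axis=1)
                 | (txy[..., 0] >= hi[0]).all(axis=1)
                 | (txy[..., 1] <= lo[1]).all(axis=1)
                 | (txy[..., 1] >= hi[1]).all(axis=1))

    new_tris: list[np.ndarray] = [tri[fully_in]]
    for poly in tri[~fully_in & ~fully_out]:
        p = poly
        p = _clip_polygon(p, 0, lo[0], keep_below=False)
        if len(p) >= 3:
            p = _clip_polygon(p, 0, hi[0], keep_below=True)
        if len(p) >= 3:
            p = _clip_polygon(p, 1, lo[1], keep_below=False)
        if len(p) >= 3:
            p = _clip_polygon(p, 1, hi[1], keep_below=True)
        if len(p) >= 3:
            fan = np.stack([np.repeat(p[0][None, :], len(p) - 2, axis=0),
                            p[1:-1], p[2:]], axis=1)
            new_tris.append(fan)
    soup = np.concatenate(new_tris, axis=0) if new_tris else np.empty((0, 3, 3))
    if len(soup) == 0:
        raise ValueError("swatch contains no geometry")
    verts = soup.reshape(-1, 3)
    faces = np.arange(len(verts)).reshape(-1, 3)
    tags = dict(mesh.tags)
    tags["cropped"] = f"square side {side_um} um at ({cx}, {cy})"
    return TriangleMesh(verts, faces, tags)


# ---------------------------------------------------------------------------
# ray intersection: numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _ray_tri(ox, oy, oz, dx, dy, dz, ax, ay, az, bx, by, bz, cx, cy, cz, tmin):
    """Moller-Trumbore.  Returns t (or -1 on miss)."""
    e1x, e1y, e1z = bx - ax, by - ay, bz - az
    e2x, e2y, e2z = cx - ax, cy - ay, cz - az
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if -1e-12 < det < 1e-12:
        return -1.0
    inv = 1.0 / det
    tx, ty, tz = ox - ax, oy - ay, oz - az
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return -1.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return -1.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t <= tmin:
        return -1.0
    return t


@njit(cache=False)
def _bvh_nearest(tri, nmin, nmax, left, right, start, count, order,
                 ox, oy, oz, dx, dy, dz, tmin):
    """Nearest hit via BVH traversal.  Returns (t, face_index); face -1 = miss.

    Ties in t are broken toward the lower face index so that the accelerated
    result is identical to the exhaustive scan.
    """
    big = 1e300
    invx = 1.0 / dx if abs(dx) > 1e-300 else (big if dx >= 0 else -big)
    invy = 1.0 / dy if abs(dy) > 1e-300 else (big if dy >= 0 else -big)
    invz = 1.0 / dz if abs(dz) > 1e-300 else (big if dz >= 0 else -big)
    best_t = np.inf
    best_f = -1
    stack = np.empty(128, np.int64)
    sp = 0
    stack[0] = 0
    sp = 1
    while sp > 0:
        sp -= 1
        node = stack[sp]
        t1 = (nmin[node, 0] - ox) * invx
        t2 = (nmax[node, 0] - ox) * invx
        tn = min(t1, t2)
        tf = max(t1, t2)
        t1 = (nmin[node, 1] - oy) * invy
        t2 = (nmax[node, 1] - oy) * invy
        tn = max(tn, min(t1, t2))
        tf = min(tf, max(t1, t2))
        t1 = (nmin[node, 2] - oz) * invz
        t2 = (nmax[node, 2] - oz) * invz
        tn = max(tn, min(t1, t2))
        tf = min(tf, max(t1, t2))
        if tn > tf or tf < tmin or tn > best_t:
            continue
        if left[node] < 0:  # leaf
            for k in range(start[node], start[node] + count[node]):
                fi = order[k]
                t = _ray_tri(ox, oy, oz, dx, dy, dz,
                             tri[fi, 0, 0], tri[fi, 0, 1], tri[fi, 0, 2],
                             tri[fi, 1, 0], tri[fi, 1, 1], tri[fi, 1, 2],
                             tri[fi, 2, 0], tri[fi, 2, 1], tri[fi, 2, 2],
                             tmin)
                if t > 0.0 and (t < best_t or (t == best_t and fi < best_f)):
                    best_t = t
                    best_f = fi
        else:
            stack[sp] = left[node]
            stack[sp + 1] = right[node]
            sp += 2
    return best_t, best_f


@njit(cache=False)
def _exhaustive_nearest(tri, ox, oy, oz, dx, dy, dz, tmin):
    """Brute-force all-triangle minimum-t scan (oracle for the BVH)."""
    best_t = np.inf
    best_f = -1
    for fi in range(tri.shape[0]):
        t = _ray_tri(ox, oy, oz, dx, dy, dz,
                     tri[fi, 0, 0], tri[fi, 0, 1], tri[fi, 0, 2],
                     tri[fi, 1, 0], tri[fi, 1, 1], tri[fi, 1, 2],
                     tri[fi, 2, 0], tri[fi, 2, 1], tri[fi, 2, 2], tmin)
        if t > 0.0 and t < best_t:
            best_t = t
            best_f = fi
    return best_t, best_f


# ---------------------------------------------------------------------------
# BVH build
# ---------------------------------------------------------------------------

class MeshAccel:
    """Median-split BVH over a mesh's triangles, built once per mesh."""

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise ValueError("cannot build an acceleration structure over an "
                             "empty mesh")
        self.mesh = mesh
        tri = np.ascontiguousarray(mesh.triangles)
        self.tri = tri
        tmin = tri.min(axis=1)
        tmax = tri.max(axis=1)
        cent = tri.mean(axis=1)

        nodes_min: list[np.ndarray] = []
        nodes_max: list[np.ndarray] = []
        node_left: list[int] = []
        node_right: list[int] = []
        node_start: list[int] = []
        node_count: list[int] = []
        order = np.arange(len(tri))

        def new_node() -> int:
            nodes_min.append(np.zeros(3))
            nodes_max.append(np.zeros(3))
            node_left.append(-1)
            node_right.append(-1)
            node_start.append(0)
            node_count.append(0)
            return len(node_left) - 1

        stack = [(new_node(), 0, len(tri))]
        while stack:
            idx, lo, hi = stack.pop()
            sel = order[lo:hi]
            nodes_min[idx] = tmin[sel].min(axis=0)
            nodes_max[idx] = tmax[sel].max(axis=0)
            n = hi - lo
            c = cent[sel]
            ext = c.max(axis=0) - c.min(axis=0)
            if n <= _LEAF_SIZE or ext.max() <= 0:
                node_start[idx] = lo
                node_count[idx] = n
                continue
            axis = int(np.argmax(ext))
            perm = np.argsort(c[:, axis], kind="stable")
            order[lo:hi] = sel[perm]
            mid = lo + n // 2
            li = new_node()
            ri = new_node()
            node_left[idx] = li
            node_right[idx] = ri
            stack.append((li, lo, mid))
            stack.append((ri, mid, hi))

        self.nmin = np.ascontiguousarray(nodes_min)
        self.nmax = np.ascontiguousarray(nodes_max)
        self.left = np.array(node_left, dtype=np.int64)
        self.right = np.array(node_right, dtype=np.int64)
        self.start = np.array(node_start, dtype=np.int64)
        self.count = np.array(node_count, dtype=np.int64)
        self.order = np.ascontiguousarray(order, dtype=np.int64)


def build_accel(mesh: TriangleMesh) -> MeshAccel:
    return MeshAccel(mesh)


def _make_hit(mesh: TriangleMesh, origin, direction, t: float,
              face: int) -> Hit:
    point = origin + t * direction
    n = mesh.face_normals[face]
    cosi = float(abs(np.dot(direction, n)))
    if np.dot(n, direction) > 0:
        n = -n
    return Hit(t=float(t), point=point, normal=n.copy(), face_index=int(face),
               cos_incidence=min(cosi, 1.0))


def intersect(accel: MeshAccel, origin, direction,
              tmin: float = EPS_SELF_INTERSECT) -> Hit | None:
    """Nearest intersection with t > ``tmin``; the returned normal opposes the
    ray.  Returns None on a miss."""
    origin = np.asarray(origin, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    t, face = _bvh_nearest(accel.tri, accel.nmin, accel.nmax, accel.left,
                           accel.right, accel.start, accel.count, accel.order,
                           origin[0], origin[1], origin[2],
                           direction[0], direction[1], direction[2], tmin)
    if face < 0:
        return None
    return _make_hit(accel.mesh, origin, direction, t, face)


def intersect_exhaustive(mesh: TriangleMesh, origin, direction,
                         tmin: float = EPS_SELF_INTERSECT) -> Hit | None:
    """Exhaustive per-triangle nearest intersection (BVH oracle)."""
    origin = np.asarray(origin, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    tri = np.ascontiguousarray(mesh.triangles)
    t, face = _exhaustive_nearest(tri, origin[0], origin[1], origin[2],
                                  direction[0], direction[1], direction[2],
                                  tmin)
    if face < 0:
        return None
    return _make_hit(mesh, origin, direction, t, face)
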