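"""Parametric feather-microstructure meshes and analytic oracle shapes.

Two families of test geometry stand in for nano-CT surface models of real
feather vanes:

* *normal* barbule arrays — smooth, nearly horizontal, partially overlapping
  laths on parallel rami, the open-pennaceous morphology of ordinary black
  feathers;
* *super black* barbule arrays — densely packed, curved laths leaning
  ``tilt_deg`` away from the feather normal toward the distal tip, separated
  by deep, narrow cavities, with microscale marginal spikes.

Plus two analytic shapes with closed-form scattering behaviour (a flat slab
and a V-groove corner reflector) used as oracles for the ray tracer.

All generators are pure functions of (params, seed): the same inputs produce
byte-identical OBJ exports.  Every generated mesh is a union of closed solids
with outward-consistent winding, so the edge census reports it watertight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .meshkit import TriangleMesh, build_accel, intersect

__all__ = [
    "BarbuleParams",
    "generate_flat_plate",
    "generate_corner_reflector",
    "generate_normal_barbule_array",
    "generate_superblack_barbule_array",
    "measure_cavity_morphometry",
    "recover_array_tilt",
    "max_lath_inclination",
    "projected_coverage",
    "area_ratio",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class BarbuleParams:
    """Geometry of a synthetic barbule-array swatch (lengths in um).

    ``cavity_depth`` and ``cavity_width`` are (low, high) envelopes for the
    cavity population of the super-black array; ``tilt_deg`` is how far the
    lath planes lean away from the feather normal (+z) toward the distal tip
    (+x), recovered downstream from the mean lath surface normal.
    ``curvature`` is the sagitta-to-chord ratio of the circular-arc lath
    profile.
    """

    swatch_side: float = 500.0
    tilt_deg: float = 30.0
    cavity_depth: tuple[float, float] = (200.0, 400.0)
    cavity_width: tuple[float, float] = (5.0, 30.0)
    spike_scale: float = 4.0
    barbule_thickness: float = 3.0
    n_rami: int = 6
    curvature: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swatch_side <= 0 or self.barbule_thickness <= 0 \
                or self.spike_scale <= 0:
            raise ValueError("all lengths must be positive")
        if not (0 <= self.tilt_deg < 90):
            raise ValueError("tilt_deg must be in [0, 90)")
        lo, hi = self.cavity_depth
        wlo, whi = self.cavity_width
        if lo <= 0 or hi < lo or wlo <= 0 or whi < wlo:
            raise ValueError("cavity ranges must be positive and ordered")
        if self.spike_scale >= wlo + 0.75 * (whi - wlo):
            raise ValueError("spike_scale must be smaller than cavity_width")
        if self.n_rami < 1:
            raise ValueError("n_rami must be at least 1")
        if not (0 <= self.curvature < 0.5):
            raise ValueError("curvature (sagitta/chord) must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# solid-construction helpers (outward winding by construction)
# ---------------------------------------------------------------------------

_BOX_FACES = np.array([
    [0, 2, 1], [0, 3, 2],   # z- (bottom)
    [4, 5, 6], [4, 6, 7],   # z+ (top)
    [0, 1, 5], [0, 5, 4],   # y-
    [3, 7, 6], [3, 6, 2],   # y+
    [0, 4, 7], [0, 7, 3],   # x-
    [1, 2, 6], [1, 6, 5],   # x+
], dtype=np.int64)


def _box(center, size, rot: np.ndarray | None = None) -> tuple[np.ndarray,
                                                               np.ndarray]:
    """Closed axis-box (optionally rotated about its center), outward winding."""
    cx, cy, cz = center
    hx, hy, hz = size[0] / 2, size[1] / 2, size[2] / 2
    corners = np.array([
        [-hx, -hy, -hz], [hx, -hy, -hz], [hx, hy, -hz], [-hx, hy, -hz],
        [-hx, -hy, hz], [hx, -hy, hz], [hx, hy, hz], [-hx, hy, hz],
    ])
    if rot is not None:
        corners = corners @ rot.T
    return corners + np.array([cx, cy, cz]), _BOX_FACES.copy()


def _shoelace_xz(poly: np.ndarray) -> float:
    x, z = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(z, -1) - np.roll(x, -1) * z))


def _extrude_polygon_xz(poly: np.ndarray, y0: float, y1: float,
                        cap_tris: list[tuple[int, int, int]]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Extrude a simple polygon in the (x, z)-plane along y into a closed solid.

    ``poly`` must be counter-clockwise in (x, z); ``cap_tris`` is a
    triangulation of the polygon (indices in polygon order, each triangle
    counter-clockwise in (x, z)).
    """
    assert _shoelace_xz(poly) > 0, "cross-section polygon must be CCW in (x,z)"
    k = len(poly)
    verts = np.empty((2 * k, 3))
    verts[:k, 0] = poly[:, 0]
    verts[:k, 1] = y0
    verts[:k, 2] = poly[:, 1]
    verts[k:, 0] = poly[:, 0]
    verts[k:, 1] = y1
    verts[k:, 2] = poly[:, 1]
    faces: list[list[int]] = []
    for i, j, l in cap_tris:
        faces.append([i, j, l])              # y0 cap, outward -y
        faces.append([i + k, l + k, j + k])  # y1 cap, outward +y
    for i in range(k):
        j = (i + 1) % k
        # side quad (i@y0, i@y1, j@y1, j@y0), outward by CCW convention
        faces.append([i, i + k, j + k])
        faces.append([i, j + k, j])
    return verts, np.array(faces, dtype=np.int64)


def _tetra(base: np.ndarray, apex: np.ndarray) -> tuple[np.ndarray,
                                                        np.ndarray]:
    """Closed tetrahedron with outward winding."""
    p0, p1, p2 = base
    n = np.cross(p1 - p0, p2 - p0)
    if np.dot(n, apex - p0) > 0:  # base wound so its normal faces away
        p1, p2 = p2, p1
    verts = np.array([p0, p1, p2, apex])
    faces = np.array([[0, 1, 2], [0, 3, 1], [1, 3, 2], [2, 3, 0]],
                     dtype=np.int64)
    return verts, faces


class _SoupBuilder:
    """Accumulates closed solids into one mesh."""

    def __init__(self) -> None:
        self._verts: list[np.ndarray] = []
        self._faces: list[np.ndarray] = []
        self._n = 0

    def add(self, verts: np.ndarray, faces: np.ndarray) -> None:
        self._verts.append(verts)
        self._faces.append(faces + self._n)
        self._n += len(verts)

    def mesh(self, tags: dict) -> TriangleMesh:
        return TriangleMesh(np.vstack(self._verts), np.vstack(self._faces),
                            tags)


# ---------------------------------------------------------------------------
# analytic oracle shapes
# ---------------------------------------------------------------------------

def generate_flat_plate(side_um: float, thickness_um: float) -> TriangleMesh:
    """Closed rectangular slab centered at the origin, top face at z = 0."""
    if side_um <= 0 or thickness_um <= 0:
        raise ValueError("side and thickness must be positive")
    verts, faces = _box((0.0, 0.0, -thickness_um / 2),
                        (side_um, side_um, thickness_um))
    return TriangleMesh(verts, faces, tags={
        "kind": "flat_plate", "side_um": side_um,
        "thickness_um": thickness_um})


def generate_corner_reflector(side_um: float,
                              groove_half_angle_deg: float) -> TriangleMesh:
    """Solid V-groove: two planar walls meeting along the y-axis in the vane
    plane, inclined ``groove_half_angle_deg`` from vertical.  A 45-degree
    half-angle retroreflects rays entering the groove after exactly two
    bounces."""
    if not (0 < groove_half_angle_deg < 90):
        raise ValueError("groove_half_angle_deg must be in (0, 90)")
    ha = math.radians(groove_half_angle_deg)
    w = side_um / 2.0
    h = w / math.tan(ha)   # wall top height so walls span the swatch in x
    t = 10.0               # base slab thickness
    # cross-section pentagon, apex at origin; CW as listed, so reverse for CCW
    pent = np.array([
        [0.0, 0.0],        # apex
        [w, h],            # top right
        [w, -t],           # bottom right
        [-w, -t],          # bottom left
        [-w, h],           # top left
    ])[::-1]
    # fan anchor = bottom-right corner (sees all vertices of the pentagon);
    # after reversal bottom-right is index 2
    caps = [(2, 3, 4), (2, 4, 0), (2, 0, 1)]
    verts, faces = _extrude_polygon_xz(pent, -w, w, caps)
    return TriangleMesh(verts, faces, tags={
        "kind": "corner_reflector", "side_um": side_um,
        "groove_half_angle_deg": groove_half_angle_deg})


# ---------------------------------------------------------------------------
# barbule arrays
# ---------------------------------------------------------------------------

def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def generate_normal_barbule_array(params: BarbuleParams,
                                  seed: int | None = None) -> TriangleMesh:
    """Open-pennaceous stand-in: parallel rami along x bearing smooth planar
    laths lying within 5 degrees of the vane plane, partially overlapping, and
    covering most of the swatch."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    side = params.swatch_side
    half = side / 2.0
    pitch_y = side / params.n_rami
    lath_w = 16.0
    lath_pitch = 18.0
    lath_t = min(params.barbule_thickness, 3.0)
    if lath_w >= lath_pitch:
        raise ValueError("lath width must be below the lath pitch "
                         "(self-intersecting laths)")
    if pitch_y <= 12.0:
        raise ValueError("ramus pitch too small for the ramus cross-section "
                         "(self-intersecting rami)")

    b = _SoupBuilder()
    n_x = int((side - lath_w - 2.0) // lath_pitch) + 1
    x0 = -half + lath_w / 2 + 1.0
    for k in range(params.n_rami):
        y_r = -half + k * pitch_y + 5.0
        b.add(*_box((0.0, y_r, -4.0), (side, 10.0, 8.0)))  # ramus
        lath_len = min(0.95 * pitch_y, half - y_r - 6.0)
        for j in range(n_x):
            xc = x0 + j * lath_pitch
            incline = rng.uniform(0.0, 5.0) * rng.choice([-1.0, 1.0])
            b.add(*_box((xc, y_r + 5.0 + lath_len / 2, -3.0),
                        (lath_w, lath_len, lath_t), rot=_rot_x(incline)))
    return b.mesh({"kind": "normal_barbule_array",
                   "seed": params.seed if seed is None else seed,
                   "swatch_side_um": side})


def _arc_profile(length: float, elev_deg: float, curvature: float,
                 n_seg: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Circular-arc lath profile in the (x, z)-plane.

    Returns station points P (n_seg+1, 2) starting at the origin and unit
    left-normals N (pointing up-proximal for a lath rising toward +x).
    The tangent elevation sweeps symmetrically about ``elev_deg`` with a half
    spread set by the sagitta-to-chord ratio ``curvature``.
    """
    alpha = 2.0 * math.atan(2.0 * curvature)  # half central angle, radians
    e0 = math.radians(elev_deg)
    u = np.linspace(0.0, 1.0, n_seg + 1)
    theta = e0 + alpha * (2.0 * u - 1.0)
    mid = 0.5 * (theta[:-1] + theta[1:])
    ds = length / n_seg
    steps = np.stack([np.cos(mid), np.sin(mid)], axis=1) * ds
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    normals = np.stack([-np.sin(theta), np.cos(theta)], axis=1)
    return pts, normals


def _lath_solid(pts: np.ndarray, normals: np.ndarray, halfwidths: np.ndarray,
                y0: float, y1: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed prismatic lath: arc strip cross-section extruded along y."""
    top = pts + halfwidths[:, None] * normals
    bot = pts - halfwidths[:, None] * normals
    m = len(pts) - 1
    # polygon CCW in (x,z): bottom curve base->tip, then top curve tip->base
    poly = np.vstack([bot, top[::-1]])
    caps = []
    for i in range(m):
        # ladder triangulation of the strip between stations i and i+1
        caps.append((i, i + 1, 2 * m - i))
        caps.append((i, 2 * m - i, 2 * m + 1 - i))
    return _extrude_polygon_xz(poly, y0, y1, caps)


def generate_superblack_barbule_array(params: BarbuleParams,
                                      seed: int | None = None
                                      ) -> TriangleMesh:
    """Super-black stand-in: densely packed rows of curved barbule laminae
    leaning ``tilt_deg`` from the feather normal toward +x (distal).

    Each row is a rank of discrete finger-like laminae (width ~14 um,
    separated by ~6-um inter-barbule gaps aligned across rows, as barbules
    seated on parallel rami are); the laminae taper to knife-edge margins
    bearing tetrahedral spikes of size ``spike_scale``.  The cavity floor is
    the field of curving barbule bases, modelled as a sawtooth of shallow
    distally-rising ramps over the basal plate.  Rows are spaced so the
    inter-row cavities match the ``cavity_depth``/``cavity_width`` envelopes.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    side = params.swatch_side
    half = side / 2.0
    elev = 90.0 - params.tilt_deg           # lath long-axis elevation
    if elev <= 5.0:
        raise ValueError("tilt_deg too close to 90 (laths would lie flat)")
    t = params.barbule_thickness
    d_lo, d_hi = params.cavity_depth
    w_lo, w_hi = params.cavity_width
    length_mid = 0.5 * (d_lo + d_hi)
    # per-gap opening widths drawn from the middle half of the stated envelope
    # so the measured medians land inside it despite curvature effects
    w_span = w_hi - w_lo
    sin_e = math.sin(math.radians(elev))

    b = _SoupBuilder()
    b.add(*_box((0.0, 0.0, -5.0), (side, side, 10.0)))  # basal plate

    # sawtooth floor of curving barbule bases: shallow ramps rising distally
    # at 10 degrees (sunk 1 um into the plate; pitch decoupled from rows)
    ramp_pitch = 23.0
    ramp_h = ramp_pitch * math.tan(math.radians(10.0)) - 1.0
    xr = -half
    while xr < half - ramp_pitch:
        tri_sec = np.array([[xr, -1.0], [xr + ramp_pitch, -1.0],
                            [xr + ramp_pitch, ramp_h]])
        b.add(*_extrude_polygon_xz(tri_sec, -half, half, [(0, 1, 2)]))
        xr += ramp_pitch

    # finger columns: inter-barbule gaps aligned across rows (barbules seated
    # on parallel rami) form open corridors for escaping floor reflections
    finger_w, finger_gap = 14.0, 6.0
    col_pitch = finger_w + finger_gap
    n_cols = int((side - 1.0) // col_pitch)
    col_y0 = -half + 0.5

    n_seg = 8
    x = -half + 5.0
    # row bases span the whole swatch so no bare floor faces the sky inside
    # it; distal tips overhang the swatch edge like real vane margins
    while x <= half - 5.0:
        length = length_mid + rng.uniform(-20.0, 20.0)
        pts, normals = _arc_profile(length, elev, params.curvature, n_seg)
        halfw = np.full(n_seg + 1, t / 2.0)
        taper = np.linspace(0.0, 1.0, n_seg + 1)
        k0 = 0.6
        # laminae taper to a knife-edge margin: a blunt distally-facing end
        # cap would leak single-bounce light skyward, which the real
        # knife-edged barbule margins do not have
        mask = taper > k0
        halfw[mask] = (t / 2.0) * (1.0 - (taper[mask] - k0) / (1 - k0))

        # spike frame anchored at 90 % of the lamina length
        ia = int(0.9 * n_seg)
        na = normals[ia]
        n3 = np.array([na[0], 0.0, na[1]])
        ta = pts[ia + 1] - pts[ia]
        ta = ta / np.linalg.norm(ta)
        t3 = np.array([ta[0], 0.0, ta[1]])
        s = params.spike_scale
        ey = np.array([0.0, 1.0, 0.0])
        h_anchor = float(halfw[ia])
        # spikes lean back along the margin (apex tilted proximally along the
        # wall) so their facets scatter into the cavity, not skyward
        apex_dir = n3 - t3
        apex_dir = apex_dir / np.linalg.norm(apex_dir)

        for j in range(n_cols):
            yl = col_y0 + j * col_pitch
            verts, faces = _lath_solid(pts, normals, halfw, yl,
                                       yl + finger_w)
            # bury the lamina base 3 um inside the basal plate: volumetric
            # overlap is harmless to the tracer, exact tangency is not
            b.add(verts + np.array([x, 0.0, -3.0]), faces)
            # one marginal spike per finger, protruding into the cavity
            yq = yl + finger_w / 2.0 + rng.uniform(-2.0, 2.0)
            c_surf = np.array([pts[ia][0] + x, yq, pts[ia][1] - 3.0]) \
                + h_anchor * n3
            cb = c_surf - 0.3 * n3  # base sunk inside the lamina
            base = np.array([cb + 1.5 * ey,
                             cb - 1.5 * ey + 0.8 * t3,
                             cb - 1.5 * ey - 0.8 * t3])
            b.add(*_tetra(base, c_surf + s * apex_dir))

        gap = w_lo + 0.25 * w_span + rng.uniform(0.0, 0.5 * w_span)
        x += (t + gap) / sin_e
    return b.mesh({"kind": "superblack_barbule_array",
                   "seed": params.seed if seed is None else seed,
                   "tilt_deg": params.tilt_deg, "swatch_side_um": side})


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

def recover_array_tilt(mesh: TriangleMesh) -> float:
    """Lean of the lath planes away from the feather normal, in degrees,
    recovered from the area-weighted mean of up-facing lath surface normals
    (near-horizontal and vertical faces excluded)."""
    n = mesh.face_normals
    a = mesh.face_areas
    sel = (n[:, 2] > 0.05) & (n[:, 2] < 0.98)
    if not sel.any():
        raise ValueError("no inclined up-facing faces found")
    m = (n[sel] * a[sel, None]).sum(axis=0)
    m /= np.linalg.norm(m)
    return 90.0 - math.degrees(math.acos(float(np.clip(m[2], -1, 1))))


def max_lath_inclination(mesh: TriangleMesh) -> float:
    """Maximum angle (degrees) between up-facing face normals and +z,
    over faces within 45 degrees of horizontal (lath top surfaces)."""
    n = mesh.face_normals
    sel = n[:, 2] > math.cos(math.radians(45.0))
    if not sel.any():
        raise ValueError("no up-facing faces found")
    return float(np.degrees(np.arccos(np.clip(n[sel, 2], -1, 1))).max())


def projected_coverage(mesh: TriangleMesh, swatch_side: float,
                       grid_step: float = 5.0) -> float:
    """Fraction of the swatch square covered by the xy-projection of the mesh
    (point-in-triangle census on a regular grid; no ray tracing involved)."""
    half = swatch_side / 2.0
    g = np.arange(-half + grid_step / 2, half, grid_step)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    tri = mesh.triangles[:, :, :2]
    covered = np.zeros(len(pts), dtype=bool)
    for lo in range(0, len(tri), 256):
        sub = tri[lo:lo + 256]
        a, bb, c = sub[:, 0], sub[:, 1], sub[:, 2]
        d1 = _edge_sign(pts, a, bb)
        d2 = _edge_sign(pts, bb, c)
        d3 = _edge_sign(pts, c, a)
        neg = (d1 < 0) | (d2 < 0) | (d3 < 0)
        pos = (d1 > 0) | (d2 > 0) | (d3 > 0)
        covered |= (~(neg & pos)).any(axis=1)
        if covered.all():
            break
    return float(covered.mean())


def _edge_sign(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # (n_pts, n_tri) signed areas of (pt, a, b)
    return ((pts[:, None, 0] - b[None, :, 0]) * (a[None, :, 1] - b[None, :, 1])
            - (a[None, :, 0] - b[None, :, 0]) * (pts[:, None, 1] - b[None, :, 1]))


def area_ratio(mesh: TriangleMesh, swatch_side: float) -> float:
    """Total surface area over projected swatch area: the surface-complexity
    figure that separates super-black from normal morphology."""
    return mesh.area / float(swatch_side) ** 2


def measure_cavity_morphometry(mesh: TriangleMesh, tilt_deg: float = 30.0,
                               grid_step: float = 1.0, n_rows: int = 5,
                               margin: float = 40.0,
                               deep_threshold: float = 100.0) -> dict:
    """Ray-cast morphometry of a super-black array.

    Probe rays are cast anti-parallel to the mean lath axis (into the
    cavities) on a ``grid_step``-um transect grid.  Contiguous runs of rays
    that travel more than ``deep_threshold`` um past the tip envelope are
    cavities; each run yields a depth (median path length past the local tip
    reference) and an opening width (run extent converted to the
    perpendicular-to-lath gap).
    """
    elev = math.radians(90.0 - tilt_deg)
    axis = np.array([math.cos(elev), 0.0, math.sin(elev)])
    accel = build_accel(mesh)
    b = mesh.bounds
    zmax = b[1, 2]
    xs = np.arange(b[0, 0] + margin, b[1, 0] - margin, grid_step)
    ys = np.linspace(b[0, 1] + margin, b[1, 1] - margin, n_rows)
    back = 50.0
    depths: list[float] = []
    widths: list[float] = []
    for y in ys:
        ts = np.full(len(xs), np.nan)
        for i, x in enumerate(xs):
            origin = np.array([x, y, zmax + 1.0]) + back * axis
            hit = intersect(accel, origin, -axis)
            if hit is not None:
                ts[i] = hit.t
        valid = np.isfinite(ts)
        if not valid.any():
            continue
        t0 = np.nanmin(ts)
        deep = valid & (ts - t0 > deep_threshold)
        # contiguous deep runs bounded by shallow (tip) hits on both sides
        i = 0
        n = len(xs)
        while i < n:
            if not deep[i]:
                i += 1
                continue
            j = i
            while j < n and deep[j]:
                j += 1
            if i > 0 and j < n and valid[i - 1] and valid[j]:
                local_ref = min(ts[i - 1], ts[j])
                depths.append(float(np.median(ts[i:j]) - local_ref))
                widths.append((j - i) * grid_step * math.sin(elev))
            i = j
    if not depths:
        raise ValueError("no cavities detected by the probe transects")
    return {
        "median_cavity_depth_um": float(np.median(depths)),
        "median_cavity_width_um": float(np.median(widths)),
        "n_cavities": len(depths),
        "recovered_tilt_deg": recover_array_tilt(mesh),
    }
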