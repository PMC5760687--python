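"""Specular Monte-Carlo ray tracing with Fresnel power splitting.

The model: light interacts with the bare feather surface only.  At every
ray-surface intersection the ray splits into exactly one specularly reflected
component, carrying the unpolarized Fresnel fraction R(theta_i) of its power,
and one transmitted component that is absorbed entirely inside the keratin
(no BRDF, no dispersion, no polarization tracking).  A ray therefore bounces
specularly, its power decaying as the product of Fresnel coefficients, until
it leaves the scene and terminates on a bounding hemisphere where its
spherical coordinates are recorded.

Two illumination rigs mirror the physical spectrophotometry setups:

* ``omni`` — rays from random positions on the source hemisphere aimed at
  uniform random points in a 330-um square on the vane (diffuse sky light);
* ``directional`` — a 330-um square source face at 660 um height, grid-seeded
  and circularly culled to exactly floor(pi * n / 4) rays, each emitted within
  a 28-degree (full angle) cone, with the whole rig tilted +45/0/-45 degrees
  about the y-axis (positive tilt places the source over the proximal end).

Wavelengths are sampled uniformly in 300-700 nm and carried as bookkeeping;
the refractive index (air 1.0 / keratin 1.56) is non-dispersive, so per-ray
outcomes do not depend on them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .meshkit import (EPS_SELF_INTERSECT, Hit, MeshAccel, TriangleMesh,
                      _bvh_nearest, build_accel, intersect)

log = logging.getLogger("plumetrace")

N_AIR = 1.0
N_KERATIN = 1.56

FATE_NO_INTERACTION = 0
FATE_TRANSMITTED = 1
FATE_REFLECTED = 2
FATE_LABELS = np.array(["no_interaction", "transmitted", "reflected"])


@dataclass
class OpticalConstants:
    """Refractive indices outside (air) and inside (keratin) the surface."""

    n_outside: float = N_AIR
    n_feather: float = N_KERATIN

    def __post_init__(self) -> None:
        if self.n_outside < 1 or self.n_feather < 1:
            raise ValueError("refractive indices must be >= 1")


# ---------------------------------------------------------------------------
# Fresnel + specular law
# ---------------------------------------------------------------------------

def fresnel_unpolarized(n1: float, n2: float, cos_theta_i):
    """Unpolarized Fresnel power reflectance (Rs + Rp) / 2.

    ``cos_theta_i`` is the cosine of the incidence angle, scalar or array, in
    [0, 1].  Beyond the critical angle (only reachable for n1 > n2) the
    reflectance is 1 (total internal reflection).
    """
    cos_i = np.asarray(cos_theta_i, dtype=np.float64)
    if np.any(cos_i < -1e-12) or np.any(cos_i > 1 + 1e-12):
        raise ValueError("cos_theta_i must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    if n1 == n2:  # no interface: nothing reflects at any angle
        return 0.0 if cos_i.ndim == 0 else np.zeros_like(cos_i)
    cos_i = np.clip(cos_i, 0.0, 1.0)
    sin_i2 = 1.0 - cos_i ** 2
    sin_t2 = (n1 / n2) ** 2 * sin_i2
    tir = (n1 > n2) & (sin_t2 >= 1.0)
    cos_t = np.sqrt(np.clip(1.0 - sin_t2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
        rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    r = 0.5 * (rs + rp)
    r = np.where(tir, 1.0, r)
    # grazing limit: R -> 1 as cos_i -> 0 (the formula is exact there already)
    out = np.clip(r, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@njit(cache=False)
def _fresnel_scalar(n1, n2, cos_i):
    if n1 == n2:
        return 0.0
    if cos_i < 0.0:
        cos_i = 0.0
    elif cos_i > 1.0:
        cos_i = 1.0
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    a1 = n1 * cos_i
    a2 = n2 * cos_t
    b1 = n1 * cos_t
    b2 = n2 * cos_i
    rs = ((a1 - a2) / (a1 + a2)) ** 2
    rp = ((b1 - b2) / (b1 + b2)) ** 2
    r = 0.5 * (rs + rp)
    if r > 1.0:
        r = 1.0
    return r


def specular_reflect(direction: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Law of reflection: d - 2 (d . n) n.  ``normal`` must oppose ``d``."""
    direction = np.asarray(direction, dtype=np.float64)
    normal = np.asarray(normal, dtype=np.float64)
    out = direction - 2.0 * np.dot(direction, normal) * normal
    return out / np.linalg.norm(out)


# ---------------------------------------------------------------------------
# rays and sources
# ---------------------------------------------------------------------------

@dataclass
class Ray:
    """A single light ray (um coordinates, arbitrary power units)."""

    origin: np.ndarray
    direction: np.ndarray
    power: float = 1.0
    wavelength: float = 550.0
    bounces: int = 0


@dataclass
class RayBundle:
    """Structure-of-arrays batch of rays from one source."""

    origins: np.ndarray      # (n, 3)
    directions: np.ndarray   # (n, 3) unit
    powers: np.ndarray       # (n,)
    wavelengths: np.ndarray  # (n,) nm

    def __len__(self) -> int:
        return len(self.origins)

    def __getitem__(self, i: int) -> Ray:
        return Ray(self.origins[i].copy(), self.directions[i].copy(),
                   float(self.powers[i]), float(self.wavelengths[i]))


@dataclass
class SourceConfig:
    """Illumination rig definition (defaults mirror the physical setup)."""

    kind: str = "directional"              # "omni" or "directional"
    n_rays: int = 1_000_000
    tilt_deg: float = 0.0                  # +45 proximal / 0 / -45 distal
    cone_full_angle_deg: float = 28.0
    spot_diameter_um: float = 330.0
    source_width_um: float = 330.0         # square source face side
    source_height_um: float = 660.0        # 6 mm scaled at 11 %
    constraint_square_side_um: float = 330.0
    hemisphere_radius_um: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("omni", "directional"):
            raise ValueError("kind must be 'omni' or 'directional'")
        if self.n_rays <= 0:
            raise ValueError("n_rays must be positive")
        if not (0 < self.cone_full_angle_deg < 180):
            raise ValueError("cone_full_angle_deg must be in (0, 180)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "kind", "n_rays", "tilt_deg", "cone_full_angle_deg",
            "spot_diameter_um", "source_width_um", "source_height_um",
            "constraint_square_side_um", "hemisphere_radius_um", "seed")}


def make_omni_source(config: SourceConfig,
                     seed: int | None = None) -> RayBundle:
    """Rays from uniform random positions on the upper source hemisphere,
    aimed at uniform random points in the constraint square at z = 0."""
    if config.kind != "omni":
        raise ValueError("config.kind must be 'omni'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_rays
    r = config.hemisphere_radius_um
    z = rng.uniform(0.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    s = np.sqrt(1.0 - z ** 2)
    origins = np.column_stack([r * s * np.cos(phi), r * s * np.sin(phi),
                               r * z])
    half = config.constraint_square_side_um / 2.0
    targets = np.column_stack([rng.uniform(-half, half, n),
                               rng.uniform(-half, half, n),
                               np.zeros(n)])
    d = targets - origins
    d /= np.linalg.norm(d, axis=1)[:, None]
    wl = rng.uniform(300.0, 700.0, n)
    return RayBundle(origins, d, np.ones(n), wl)


def make_directional_source(config: SourceConfig,
                            seed: int | None = None) -> RayBundle:
    """Grid-seeded square source culled by a circular aperture to exactly
    floor(pi * n_rays / 4) rays, each emitted within the source cone, with the
    whole rig tilted ``tilt_deg`` about the y-axis."""
    if config.kind != "directional":
        raise ValueError("config.kind must be 'directional'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_rays
    g = int(round(math.sqrt(n)))
    if g * g != n:
        log.info("n_rays=%d is not a perfect square; using a %dx%d grid", n,
                 g, g)
    side = config.source_width_um
    c = (np.arange(g) + 0.5) / g - 0.5
    gx, gy = np.meshgrid(c * side, c * side, indexing="ij")
    gx = gx.ravel()
    gy = gy.ravel()
    keep = int(math.floor(math.pi * n / 4.0))
    keep = min(keep, g * g)
    dist2 = gx ** 2 + gy ** 2
    order = np.argsort(dist2, kind="stable")  # ties broken by grid index
    sel = order[:keep]
    sel.sort()  # deterministic emission order by grid index
    gx, gy = gx[sel], gy[sel]

    half_angle = math.radians(config.cone_full_angle_deg / 2.0)
    cos_t = rng.uniform(math.cos(half_angle), 1.0, keep)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    phi = rng.uniform(0.0, 2 * np.pi, keep)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), -cos_t])
    origins = np.column_stack([gx, gy,
                               np.full(keep, config.source_height_um)])

    tau = math.radians(config.tilt_deg)
    # R_y(-tau): maps the rig axis +z to (-sin tau, 0, cos tau); positive tilt
    # puts the source over the proximal (-x) end
    rot = np.array([[math.cos(tau), 0.0, -math.sin(tau)],
                    [0.0, 1.0, 0.0],
                    [math.sin(tau), 0.0, math.cos(tau)]])
    origins = origins @ rot.T
    dirs = dirs @ rot.T
    wl = rng.uniform(300.0, 700.0, keep)
    return RayBundle(origins, dirs, np.ones(keep), wl)


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

@dataclass
class RayRecord:
    """One ray's outcome."""

    fate: str
    n_scatter: int
    terminal_direction: np.ndarray
    terminal_point_spherical: tuple[float, float]  # (theta from +z, phi), rad
    terminal_power: float
    absorbed_power: float
    initial_power: float
    truncated: bool = False


@dataclass
class SimulationResult:
    """Per-ray outcome set for one (mesh, source) run.

    Columnar arrays: ``fate`` (coded 0/1/2, see FATE_LABELS), ``n_scatter``,
    ``theta``/``phi`` (terminal spherical coordinates, radians),
    ``terminal_power``, ``absorbed_power``, ``initial_power``.
    """

    fate: np.ndarray
    n_scatter: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    terminal_power: np.ndarray
    absorbed_power: np.ndarray
    initial_power: np.ndarray
    wavelengths: np.ndarray
    source: SourceConfig
    mesh_tag: str = ""
    truncated_count: int = 0

    def __len__(self) -> int:
        return len(self.fate)

    @property
    def emitted_power(self) -> float:
        return float(self.initial_power.sum())

    @property
    def totals(self) -> dict:
        refl = self.fate == FATE_REFLECTED
        trans = self.fate != FATE_REFLECTED  # includes no-interaction
        return {
            "emitted": self.emitted_power,
            "reflected_total": float(self.terminal_power[refl].sum()),
            "transmitted_total": float(self.terminal_power[trans].sum()),
            "absorbed_total": float(self.absorbed_power.sum()),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fate": FATE_LABELS[self.fate],
            "n_scatter": self.n_scatter,
            "theta_deg": np.degrees(self.theta),
            "phi_deg": np.degrees(self.phi),
            "terminal_power": self.terminal_power,
            "absorbed_power": self.absorbed_power,
        })

    def save(self, outdir, name: str = "rays") -> None:
        """Persist as columnar CSV plus a JSON run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / f"{name}.csv", index=False,
                                   float_format="%.12g")
        manifest = {
            "source": self.source.to_dict(),
            "mesh_tag": self.mesh_tag,
            "n_rays": len(self),
            "truncated_count": self.truncated_count,
            "totals": self.totals,
        }
        (outdir / f"{name}.manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))


@dataclass
class EnergyBalance:
    emitted: float
    reflected_total: float
    transmitted_total: float
    absorbed_total: float
    relative_residual: float


@njit(cache=False)
def _trace_kernel(tri, nmin, nmax, left, right, start, count, order,
                  origins, dirs, powers, n1, n2, max_bounces, eps,
                  absorb_interior):
    n = origins.shape[0]
    n_scatter = np.zeros(n, np.int64)
    term_power = np.empty(n, np.float64)
    out_o = np.empty((n, 3), np.float64)
    out_d = np.empty((n, 3), np.float64)
    truncated = np.zeros(n, np.uint8)
    interior = np.zeros(n, np.uint8)
    for i in range(n):
        ox, oy, oz = origins[i, 0], origins[i, 1], origins[i, 2]
        dx, dy, dz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        p = powers[i]
        b = 0
        while True:
            t, fi = _bvh_nearest(tri, nmin, nmax, left, right, start, count,
                                 order, ox, oy, oz, dx, dy, dz, eps)
            if fi < 0:
                break
            if b >= max_bounces:
                truncated[i] = 1
                break
            hx = ox + t * dx
            hy = oy + t * dy
            hz = oz + t * dz
            ax, ay, az = tri[fi, 0, 0], tri[fi, 0, 1], tri[fi, 0, 2]
            e1x, e1y, e1z = tri[fi, 1, 0] - ax, tri[fi, 1, 1] - ay, \
                tri[fi, 1, 2] - az
            e2x, e2y, e2z = tri[fi, 2, 0] - ax, tri[fi, 2, 1] - ay, \
                tri[fi, 2, 2] - az
            nx = e1y * e2z - e1z * e2y
            ny = e1z * e2x - e1x * e2z
            nz = e1x * e2y - e1y * e2x
            nn = math.sqrt(nx * nx + ny * ny + nz * nz)
            if nn == 0.0:
                break
            nx /= nn
            ny /= nn
            nz /= nn
            ddn = dx * nx + dy * ny + dz * nz
            if ddn > 0.0:
                # striking the face from behind: for consistently outward-
                # wound watertight solids this means the ray is inside the
                # keratin, where transmitted light is absorbed entirely
                if absorb_interior:
                    interior[i] = 1
                    p = 0.0
                    break
                # two-sided surface: flip the normal against the ray
                nx = -nx
                ny = -ny
                nz = -nz
                ddn = -ddn
            b += 1
            cos_i = -ddn
            p *= _fresnel_scalar(n1, n2, cos_i)
            dx = dx - 2.0 * ddn * nx
            dy = dy - 2.0 * ddn * ny
            dz = dz - 2.0 * ddn * nz
            dn = math.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= dn
            dy /= dn
            dz /= dn
            ox = hx + eps * dx
            oy = hy + eps * dy
            oz = hz + eps * dz
        n_scatter[i] = b
        term_power[i] = p
        out_o[i, 0], out_o[i, 1], out_o[i, 2] = ox, oy, oz
        out_d[i, 0], out_d[i, 1], out_d[i, 2] = dx, dy, dz
    return n_scatter, term_power, out_o, out_d, truncated, interior


def _terminal_spherical(origins: np.ndarray, dirs: np.ndarray,
                        radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Spherical coordinates of the termination point on the sphere of
    ``radius`` centered on the swatch."""
    od = np.einsum("ij,ij->i", origins, dirs)
    oo = np.einsum("ij,ij->i", origins, origins)
    disc = np.clip(od ** 2 - (oo - radius ** 2), 0.0, None)
    t = -od + np.sqrt(disc)  # larger root
    pts = origins + t[:, None] * dirs
    theta = np.arccos(np.clip(pts[:, 2] / radius, -1.0, 1.0))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    return theta, phi


def trace_ray(accel: MeshAccel, ray: Ray,
              constants: OpticalConstants = OpticalConstants(),
              max_bounces: int = 10000,
              hemisphere_radius: float = 5000.0) -> RayRecord:
    """Trace a single ray (reference path over :func:`meshkit.intersect`)."""
    o = np.asarray(ray.origin, dtype=np.float64).copy()
    d = np.asarray(ray.direction, dtype=np.float64).copy()
    p = float(ray.power)
    b = 0
    truncated = False
    while True:
        hit = intersect(accel, o, d)
        if hit is None:
            break
        if b >= max_bounces:
            truncated = True
            break
        b += 1
        p *= fresnel_unpolarized(constants.n_outside, constants.n_feather,
                                 hit.cos_incidence)
        d = specular_reflect(d, hit.normal)
        o = hit.point + EPS_SELF_INTERSECT * d
    theta, phi = _terminal_spherical(o[None, :], d[None, :],
                                     hemisphere_radius)
    if b == 0:
        fate = "no_interaction"
    elif d[2] > 0:
        fate = "reflected"
    else:
        fate = "transmitted"
    return RayRecord(fate=fate, n_scatter=b, terminal_direction=d,
                     terminal_point_spherical=(float(theta[0]),
                                               float(phi[0])),
                     terminal_power=p,
                     absorbed_power=ray.power - p,
                     initial_power=ray.power, truncated=truncated)


def run_simulation(mesh: TriangleMesh | MeshAccel, rays: RayBundle,
                   constants: OpticalConstants = OpticalConstants(),
                   config: SourceConfig | None = None,
                   max_bounces: int = 10000,
                   absorb_interior: bool = True) -> SimulationResult:
    """Trace a bundle of rays against a mesh.

    Deterministic given (mesh, rays, config).  Emits a warning if any ray was
    force-terminated at ``max_bounces`` (must not happen in shipped runs).

    ``absorb_interior``: with watertight, outward-wound geometry a ray can
    only strike a backface if numerical tunnelling carried it inside a solid;
    such a ray is terminated with all remaining power absorbed (the model
    absorbs all transmitted light) and classified ``transmitted``.  Disable
    for genuinely two-sided open shells.
    """
    accel = mesh if isinstance(mesh, MeshAccel) else build_accel(mesh)
    config = config or SourceConfig()
    origins = np.ascontiguousarray(rays.origins, dtype=np.float64)
    dirs = np.ascontiguousarray(rays.directions, dtype=np.float64)
    powers = np.ascontiguousarray(rays.powers, dtype=np.float64)
    n_scatter, term_power, out_o, out_d, truncated, interior = _trace_kernel(
        accel.tri, accel.nmin, accel.nmax, accel.left, accel.right,
        accel.start, accel.count, accel.order, origins, dirs, powers,
        constants.n_outside, constants.n_feather, max_bounces,
        EPS_SELF_INTERSECT, absorb_interior)
    n_trunc = int(truncated.sum())
    if n_trunc:
        log.warning("%d rays force-terminated at max_bounces=%d", n_trunc,
                    max_bounces)
    n_interior = int(interior.sum())
    if n_interior:
        log.info("%d rays entered a solid through numerical tunnelling and "
                 "were absorbed", n_interior)
    fate = np.where(n_scatter == 0, FATE_NO_INTERACTION,
                    np.where(out_d[:, 2] > 0, FATE_REFLECTED,
                             FATE_TRANSMITTED)).astype(np.int8)
    fate[interior.astype(bool)] = FATE_TRANSMITTED
    theta, phi = _terminal_spherical(out_o, out_d,
                                     config.hemisphere_radius_um)
    mesh_obj = accel.mesh
    tag = str(mesh_obj.tags.get("kind", mesh_obj.tags.get("source", "")))
    return SimulationResult(
        fate=fate, n_scatter=n_scatter, theta=theta, phi=phi,
        terminal_power=term_power,
        absorbed_power=powers - term_power,
        initial_power=powers, wavelengths=rays.wavelengths.copy(),
        source=config, mesh_tag=tag, truncated_count=n_trunc)


def energy_audit(result: SimulationResult) -> EnergyBalance:
    """Power-conservation check: emitted = reflected + transmitted + absorbed
    up to floating-point rounding."""
    t = result.totals
    emitted = t["emitted"]
    resid = abs(emitted - (t["reflected_total"] + t["transmitted_total"]
                           + t["absorbed_total"]))
    return EnergyBalance(
        emitted=emitted,
        reflected_total=t["reflected_total"],
        transmitted_total=t["transmitted_total"],
        absorbed_total=t["absorbed_total"],
        relative_residual=resid / emitted if emitted > 0 else 0.0,
    )


def mesh_hash(mesh: TriangleMesh) -> str:
    """Stable content hash of the mesh geometry (for run manifests)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(mesh.faces).tobytes())
    return h.hexdigest()[:16]
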