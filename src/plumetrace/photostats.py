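"""Directional-reflectance statistics over ray-tracing results.

Reduces a :class:`~plumetrace.raytrace.SimulationResult` to the headline
quantities of the structural-absorption analysis:

* percent directional reflectance within the detector acceptance cone
  (27-degree full angle by default, mirroring the full-angle convention of
  the source cone), with its companion absorbance;
* percent multiple scattering — the percentage of a selected set of rays
  (detector-cone set by default) that scattered two or more times;
* reflected power per 90-degree azimuthal viewing quadrant and the darkest
  quadrant;
* a kernel-regression hemisphere map of locally averaged reflectance
  (radiant intensity per unit solid angle, normalized by emitted power),
  evaluated on a deterministic 400-point Fibonacci lattice;
* ordinary least squares with slope standard error and t-test, for the
  reflectance-versus-multiple-scattering regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .raytrace import FATE_REFLECTED, SimulationResult

QUADRANTS = ("distal", "left_lateral", "proximal", "right_lateral")


@dataclass
class DirectionalReflectance:
    percent: float
    absorbance_percent: float
    detector_cone_full_angle_deg: float
    n_rays_in_cone: int


@dataclass
class QuadrantReport:
    power_by_quadrant: dict
    darkest: str
    tie: bool
    halves: dict  # proximal/distal two-halves aggregation


@dataclass
class HemisphereMap:
    eval_directions: np.ndarray  # (n, 3) unit vectors on the hemisphere
    values: np.ndarray           # power per sr per emitted power
    bandwidth: float             # radians

    def to_dataframe(self) -> pd.DataFrame:
        theta = np.degrees(np.arccos(np.clip(self.eval_directions[:, 2],
                                             -1, 1)))
        phi = np.degrees(np.arctan2(self.eval_directions[:, 1],
                                    self.eval_directions[:, 0]))
        return pd.DataFrame({"theta_deg": theta, "phi_deg": phi,
                             "value": self.values})


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    se_slope: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------

def _reflected_in_cone(result: SimulationResult,
                       cone_full_angle_deg: float) -> np.ndarray:
    half = math.radians(cone_full_angle_deg / 2.0)
    return (result.fate == FATE_REFLECTED) & (result.theta <= half)


def directional_reflectance(result: SimulationResult,
                            cone_full_angle_deg: float = 27.0
                            ) -> DirectionalReflectance:
    """%R: reflected power terminating within the detector cone about +z,
    as a percentage of emitted power."""
    emitted = result.emitted_power
    if emitted <= 0:
        raise ValueError("zero emitted power")
    mask = _reflected_in_cone(result, cone_full_angle_deg)
    pct = 100.0 * float(result.terminal_power[mask].sum()) / emitted
    return DirectionalReflectance(
        percent=pct, absorbance_percent=100.0 - pct,
        detector_cone_full_angle_deg=cone_full_angle_deg,
        n_rays_in_cone=int(mask.sum()))


def multiple_scatter_fraction(result: SimulationResult,
                              selection: str = "in_cone",
                              cone_full_angle_deg: float = 27.0) -> float:
    """Percent of the selected rays that scattered at least twice.

    ``selection``: ``"in_cone"`` (reflected rays terminating in the detector
    cone, the set used for the headline statistic) or ``"all_reflected"``.
    Counts rays, not power.
    """
    if selection == "in_cone":
        mask = _reflected_in_cone(result, cone_full_angle_deg)
    elif selection == "all_reflected":
        mask = result.fate == FATE_REFLECTED
    else:
        raise ValueError("selection must be 'in_cone' or 'all_reflected'")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no reflected rays in the selected set")
    return 100.0 * float((result.n_scatter[mask] >= 2).sum()) / n


def quadrant_summary(result: SimulationResult) -> QuadrantReport:
    """Reflected terminal power by 90-degree azimuthal viewing quadrant.

    distal: phi in [-45, 45); left_lateral: [45, 135); proximal:
    [135, 180] u [-180, -135); right_lateral: [-135, -45).  The darkest
    quadrant attains the minimum (ties flagged, lexicographic winner).
    """
    refl = result.fate == FATE_REFLECTED
    if not refl.any():
        raise ValueError("no reflected rays")
    phi = np.degrees(result.phi[refl])
    p = result.terminal_power[refl]
    power = {}
    power["distal"] = float(p[(phi >= -45) & (phi < 45)].sum())
    power["left_lateral"] = float(p[(phi >= 45) & (phi < 135)].sum())
    power["proximal"] = float(p[(phi >= 135) | (phi < -135)].sum())
    power["right_lateral"] = float(p[(phi >= -135) & (phi < -45)].sum())
    mn = min(power.values())
    winners = [q for q in sorted(power) if power[q] == mn]
    # two-halves split along the horizontal (y) axis of the projection
    x = np.cos(result.phi[refl])
    halves = {"proximal_half": float(p[x < 0].sum()),
              "distal_half": float(p[x >= 0].sum())}
    return QuadrantReport(power_by_quadrant=power, darkest=winners[0],
                          tie=len(winners) > 1, halves=halves)


# ---------------------------------------------------------------------------
# hemisphere map
# ---------------------------------------------------------------------------

def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, near-uniform lattice of n unit vectors on the upper
    hemisphere (golden-angle spiral)."""
    k = np.arange(n)
    z = (k + 0.5) / n
    phi = 2.0 * np.pi * k * (1.0 - 1.0 / ((1 + math.sqrt(5)) / 2))
    s = np.sqrt(1.0 - z ** 2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _kernel_values(result: SimulationResult, u: np.ndarray,
                   bandwidth: float, quad_n: int = 16384) -> np.ndarray:
    """Nadaraya-Watson kernel estimate of reflected power per unit solid
    angle (normalized by emitted power) at unit directions ``u``."""
    refl = result.fate == FATE_REFLECTED
    theta = result.theta[refl]
    phi = result.phi[refl]
    s = np.sin(theta)
    d = np.column_stack([s * np.cos(phi), s * np.sin(phi), np.cos(theta)])
    p = result.terminal_power[refl]

    def kern(cosang: np.ndarray) -> np.ndarray:
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        return np.exp(-0.5 * (ang / bandwidth) ** 2)

    num = np.zeros(len(u))
    for lo in range(0, len(d), 65536):
        sub = d[lo:lo + 65536]
        num += kern(u @ sub.T) @ p[lo:lo + 65536]
    # kernel solid-angle mass per evaluation direction (deterministic
    # quadrature on a dense hemisphere lattice)
    q = fibonacci_hemisphere(quad_n)
    w = 2.0 * np.pi / quad_n
    mass = kern(u @ q.T).sum(axis=1) * w
    return num / (result.emitted_power * mass)


def viewing_contrast(result: SimulationResult, polar_deg: float = 45.0,
                     bandwidth: float = 0.2) -> dict:
    """Locally averaged reflectance for a viewer at ``polar_deg`` on the
    distal (+x) versus the proximal (-x) side — the darkest-viewing-direction
    comparison.  Returns the two kernel-map values and which side is darker.
    """
    t = math.radians(polar_deg)
    u = np.array([[math.sin(t), 0.0, math.cos(t)],     # viewed from distal
                  [-math.sin(t), 0.0, math.cos(t)]])   # viewed from proximal
    vals = _kernel_values(result, u, bandwidth)
    return {"distal_view": float(vals[0]), "proximal_view": float(vals[1]),
            "darker": "distal" if vals[0] <= vals[1] else "proximal"}


def hemisphere_map(result: SimulationResult, n_eval: int = 400,
                   bandwidth: float = 0.2,
                   _quad_n: int = 16384) -> HemisphereMap:
    """Nadaraya-Watson kernel regression of reflected power over viewing
    directions, with a Gaussian kernel on angular distance.

    value(u) = sum_i K(angle(u, d_i) / h) p_i / (P_emitted * m(u)) where
    m(u) is the kernel's solid-angle mass over the hemisphere, so the map
    integrates to (reflected power / emitted power) and the wide-bandwidth
    limit is reflected_total / (2 pi emitted).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if (result.fate == FATE_REFLECTED).sum() < 10:
        raise ValueError("need at least 10 reflected rays")
    u = fibonacci_hemisphere(n_eval)
    values = _kernel_values(result, u, bandwidth, _quad_n)
    return HemisphereMap(eval_directions=u, values=values,
                         bandwidth=bandwidth)


def plot_hemisphere_map(hmap: HemisphereMap, path,
                        title: str = "") -> None:
    """Orthographic projection of the hemisphere map with log-scale colors
    and concentric rings at 22.5, 45, 67.5 and 90 degrees polar angle."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    u = hmap.eval_directions
    v = np.clip(hmap.values, None, None)
    floor = max(v[v > 0].min() if (v > 0).any() else 1e-12, 1e-12)
    v = np.clip(v, floor, None)
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(u[:, 0], u[:, 1], c=v, s=36,
                    norm=LogNorm(vmin=floor, vmax=v.max()), cmap="inferno")
    for ring_deg in (22.5, 45.0, 67.5, 90.0):
        r = math.sin(math.radians(ring_deg))
        circ = plt.Circle((0, 0), r, fill=False, color="gray", lw=0.6)
        ax.add_patch(circ)
    ax.axhline(0.0, color="gray", lw=0.6)  # proximal/distal separator
    ax.set_aspect("equal")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("distal  ->  +x")
    ax.set_ylabel("+y")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="reflected power / (sr x emitted)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def ols_fit(x_values, y_values) -> RegressionResult:
    """Ordinary least squares y = intercept + slope * x with the slope's
    standard error and two-sided t-test (n - 2 degrees of freedom)."""
    x = np.asarray(x_values, dtype=np.float64)
    y = np.asarray(y_values, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("ols_fit requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    if np.ptp(y) == 0:
        # degenerate flat response: slope 0 with no explained variance
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                r_squared=0.0, se_slope=0.0, p_value=1.0,
                                n=len(x))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared), se_slope=float(model.bse[1]),
        p_value=float(model.pvalues[1]), n=len(x))
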