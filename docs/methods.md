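# Methods

## Optical model

A feather swatch is a triangle surface mesh in micrometres, vane in the
xy-plane, +z toward the exposed (obverse) side, +x toward the distal tip.
Light is a set of rays with equal radiant power. At each ray–surface
intersection the ray splits once: a specularly reflected component carrying
the unpolarized Fresnel fraction `R(θi) = (Rs + Rp)/2` of the power
(n_outside = 1.0, n_feather = 1.56, non-dispersive), and a transmitted
component that is absorbed entirely inside the keratin. There is no BRDF,
no roughness, no polarization tracking, no dispersion and no re-emergence of
transmitted light; wavelengths (uniform 300–700 nm) are carried only as
bookkeeping and provably never change a ray's path or power. Consequently a
ray's terminal power is `p0 · Π R(θk)` and its absorbed power is the exact
complement, so the global energy audit closes to machine precision
(residual < 1e−9 is enforced; observed ~1e−16).

A ray terminates when it no longer intersects the mesh; it is projected onto
a sphere of radius `hemisphere_radius_um` (default 5000 µm) centred on the
swatch and its termination point's spherical coordinates (θ from +z, φ from
+x) are recorded. Fate classification: `no_interaction` (zero hits),
`reflected` (≥1 hit, terminal direction z > 0), `transmitted` (otherwise;
the measure-zero z = 0 tie is deterministic and counts as transmitted).

## Illumination rigs

*Directional* (a scale model of a normal-incidence reflectance probe): one
million rays are seeded on a cell-centred √n×√n grid spanning a 330-µm
square source face 660 µm above the swatch (a 6-mm working distance scaled
at 11 %). A circular aperture culls the grid to exactly `⌊π·n/4⌋` rays —
785 398 for n = 10⁶ — implemented as keeping the `⌊π·n/4⌋` grid points
nearest the source centre with ties broken by grid index, so the emitted
count is exact and grid-convention independent. Each ray's direction is
drawn uniformly in solid angle within a cone of **full** angle 28° about the
source axis (the printed angular ranges are read as full angles; both are
config fields). The whole rig rotates about the y-axis by +45° (source over
the proximal −x end), 0°, or −45° (source over the distal end). The
absolute fibre-bundle width is not independently known; the source face
defaults to the 330-µm spot and is exposed in `SourceConfig`.

*Omni* (diffuse sky): ray origins uniform on the upper source hemisphere,
directions toward uniform random points in a 330-µm square on the vane.

## Statistics

* **Directional reflectance (%R)** — 100 × (terminal power of reflected rays
  whose termination polar angle lies within the detector cone, full angle
  27° by default) / emitted power; absorbance = 100 − %R is reported
  alongside. Membership uses the termination point on the sphere, so for
  oracle comparisons against pure exit-angle integrals the far field
  (`hemisphere_radius_um = 1e6`) removes the source-size parallax.
* **Percent multiple scattering** — the percentage *of rays* (not power) in
  a selected set that scattered ≥ 2 times; the default set is the
  detector-cone set of the 0° rig, `all_reflected` is available.
* **Viewing quadrants** — reflected terminal power split by azimuth into
  distal [−45°, 45°), left-lateral [45°, 135°), proximal [135°, 225°),
  right-lateral [225°, 315°); the darkest attains the minimum (exact ties
  flagged, lexicographic winner). Because purely specular scenes starve the
  lateral sectors, the report also carries the two-halves aggregation
  (proximal vs distal of the projection's horizontal split), which is the
  robust form of the darkest-viewing-quadrant comparison, plus
  `viewing_contrast`, the kernel-map value at the ±45° viewing directions.
* **Hemisphere map** — Nadaraya–Watson regression of reflected power over
  viewing directions with a Gaussian kernel on angular distance (default
  bandwidth 0.2 rad, config), evaluated on a deterministic 400-point
  Fibonacci lattice; values are power per steradian per emitted power, each
  divided by the kernel's solid-angle mass at that direction (computed on a
  dense deterministic lattice), so the wide-bandwidth limit is
  `reflected_total / (2π · emitted)`. Plots are orthographic projections
  with log-scale colour and rings at 22.5°, 45°, 67.5°, 90°.
* **Regression** — ordinary least squares (statsmodels) of reflectance on
  percent multiple scattering with slope standard error and the two-sided
  t-test on n − 2 degrees of freedom.

## Synthetic geometry

The generators are pure functions of (params, seed); identical inputs give
byte-identical OBJ exports. All shapes are unions of closed, outward-wound
solids, so the edge census reports them watertight; solids may interpenetrate
(harmless to a surface tracer) but are never in exact tangential contact,
which would invite numerical tunnelling.

*Flat plate* and *V-groove corner reflector* are analytic oracles: a convex
plate forces exactly one bounce; a 45° groove retroreflects interior rays
after exactly two bounces with terminal power R(45°)².

*Normal array*: six rami along x bearing smooth planar laths (16 µm wide,
2–3 µm thick, 18-µm pitch) that lie within 5° of the vane plane and overlap
the next ramus like an open pennaceous vane; projected coverage ≥ 0.8 of the
swatch.

*Super-black array*: rows of curved laminae leaning `tilt_deg = 30°` from
the feather normal toward the distal tip. "Tilt" is anchored to what can be
measured on a mesh: the area-weighted mean of the up-facing lath surface
normals sits `tilt_deg` above the vane plane, pointing proximally. Each row
is a rank of discrete finger-like laminae (14 µm wide) separated by 6-µm
inter-barbule gaps aligned across rows, as barbules seated on parallel rami
are; the aligned gaps form open corridors. Laminae follow a circular-arc
profile (sagitta/chord `curvature`, default 0.02 — visibly bowed yet slim
enough that the ~15-µm slots stay clear to the floor) and taper to
knife-edge margins: a blunt distally-facing end cap is a meshing artifact
that would leak single-bounce light skyward, which real knife-edged barbule
margins do not do. Margins bear one tetrahedral spike per finger
(`spike_scale` 4 µm < 5 µm), leaning back along the wall so spike facets
scatter into the cavity. The cavity floor is the field of curving barbule
bases, modelled as a sawtooth of shallow (10°) distally-rising ramps over
the basal plate. Row pitch is set from per-gap widths drawn from the middle
half of the `cavity_width` envelope; lamina lengths are the `cavity_depth`
midpoint ± 20 µm.

Two of these elements carry the directional physics. The deep slots produce
the multiple scattering and the extreme absorption; any light escaping a
deep slot leaves along the distally tilted slot axis. The fingered corridors
and ramped floor produce the *proximal* reflectance bias: light reaching the
floor reflects off the ramps and escapes up the corridors toward the
proximal hemisphere, which is why the distal viewing quadrant stays the
darkest under every illumination tilt — including −45°, where the beam
shines straight into the cavity mouths and total reflectance collapses.
A wall-only geometry (no corridors, flat floor) reproduces the absorption
but *not* the always-proximal bias; the paths were verified by tracing.

*Morphometry*: cavity depth and opening width are measured by casting probe
rays anti-parallel to the mean lath axis (i.e. into the cavities) on a 1-µm
transect grid. Contiguous runs of rays travelling > 100 µm past the tip
envelope are cavities; a run's depth is the median path length past the
local tip reference and its width is the run extent converted to the
perpendicular inter-lath gap. Vertical ray casting cannot measure these
slanted cavities (a vertical ray meets the next lath after ~pitch·tan(elev)
µm), so the probe direction follows the anatomy. Defaults yield medians of
~290 µm depth, ~14 µm width, and a recovered tilt of 30.3°.

## Spectra

Raw replicate spectra (1-nm grid, 300–700 nm, % of a white standard) are
reduced by clamping negatives to zero, averaging the replicates pointwise,
loess smoothing (statsmodels lowess, span 0.25 of the points, config), and
clamping once more since smoothing can undershoot. Clamp-before-average is
deliberate and order-sensitive on noisy near-zero data. %R is the
left-Riemann-sum area over [400, 700) nm divided by the bin count — the
bin-mean reflectance. Synthetic fixtures: super black is flat at 0.2 % with
N(0, 0.05 %) noise (negative excursions appear when the level approaches
the noise floor); normal black is 3.5 % with a +0.02 %/nm melanin-like rise
above 600 nm.

## Numerics

Ray–triangle tests are Möller–Trumbore inside a median-split BVH (leaf
size 4) compiled with numba; an exhaustive per-triangle scan with the same
epsilon conventions is kept as the oracle, and ties in hit distance break
toward the lower face index in both paths so they agree exactly.
Self-intersection is avoided by a 1e−6-µm offset along the outgoing ray —
far above float rounding at swatch scale, far below any real surface
separation. Should numerical tunnelling still carry a ray inside a solid,
the backface hit betrays it (outward-wound watertight geometry shows
exteriors only frontfaces) and the ray is terminated with its remaining
power absorbed, consistent with the model's total absorption inside
keratin; this guard is switchable off for genuinely open two-sided shells.
The bounce cap (default 10 000) exists only to guarantee termination:
grazing rays legitimately ping-pong >1000 times in µm-scale slots, and
shipped runs always finish with zero force-terminated rays.

## Problem sizes and determinism

The shipped tests and the acceptance script run 10⁵ rays per rig (the
emitted-count census uses the full 10⁶-ray grid, which needs no tracing)
and 5×10⁴ rays per point of the regression series. All randomness flows
from named integer seeds; the pipeline derives per-(mesh, rig) seeds from a
master seed by stable hashing, so adding a mesh never perturbs the other
streams, and reruns under the same manifest are byte-identical.

## Limitations

The synthetic arrays are stand-ins, not anatomical reconstructions: they
reproduce the published morphology envelopes (tilt, cavity depth and width,
sub-5-µm marginal spikes) and the qualitative optical contrasts, but not
any species' absolute reflectance values, which depend on the real meshes'
multi-scale roughness. Thin-film, diffraction and melanosome optics are out
of scope by construction, as are interactions between overlapping feathers;
rays exiting below the vane are counted and then set aside, as the analysis
concerns the reflected set only. Mesh repair is out of scope: defects are
detected (edge census) but never fixed.
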