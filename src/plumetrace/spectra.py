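"""Reflectance-spectrum reduction and synthetic spectra fixtures.

The reduction pipeline mirrors directional reflectance spectrophotometry of
very dark plumage, where the raw signal is noisy and can swing negative:
negative values are clamped to zero first, the replicate spectra are then
averaged pointwise, a loess curve is fitted, and the smoothed curve is
clamped once more (smoothing may undershoot zero).  The summary statistic %R
is the left-Riemann-sum area under the curve between 400 and 700 nm divided
by the number of wavelength bins, i.e. the bin-mean reflectance relative to
a 100 % white standard.

Synthetic fixtures emulate the two observed spectral shapes: melanin-sloped
normal black (reflectance rising above ~600 nm) and nearly flat super black.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["Spectrum", "reduce_spectra", "percent_reflectance",
           "synth_spectrum"]


@dataclass
class Spectrum:
    """Wavelength-indexed reflectance (% of white standard)."""

    wavelengths: np.ndarray   # nm, strictly increasing, within [300, 700]
    reflectance: np.ndarray   # %, same length
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance lengths differ")
        if len(self.wavelengths) and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"wavelength_nm": self.wavelengths,
                             "reflectance_percent": self.reflectance})


def reduce_spectra(raw_spectra, span: float = 0.25) -> Spectrum:
    """Clamp negatives to zero, average replicates pointwise, loess-smooth
    (``span`` = fraction of points in the local window), clamp again.

    The clamp-before-average order matters on noisy near-zero data: it is the
    signal-processing order used on the instrument output.
    """
    spectra = list(raw_spectra)
    if not spectra:
        raise ValueError("need at least one raw spectrum")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if len(s.wavelengths) != len(wl) or not np.allclose(s.wavelengths, wl):
            raise ValueError("replicate spectra are on mismatched "
                             "wavelength grids")
    stack = np.vstack([np.clip(s.reflectance, 0.0, None) for s in spectra])
    mean = stack.mean(axis=0)
    smooth = lowess(mean, wl, frac=span, it=0, return_sorted=False)
    smooth = np.clip(smooth, 0.0, None)
    return Spectrum(wl.copy(), smooth,
                    meta={"n_averaged": len(spectra), "loess_span": span})


def percent_reflectance(spectrum: Spectrum, lo_nm: float = 400.0,
                        hi_nm: float = 700.0) -> float:
    """%R: left-Riemann-sum area under the spectrum over [lo, hi) divided by
    the bin count — the mean per-bin reflectance relative to the white
    standard."""
    wl = spectrum.wavelengths
    if wl.min() > lo_nm or wl.max() < hi_nm:
        raise ValueError(f"spectrum does not cover [{lo_nm}, {hi_nm}] nm")
    mask = (wl >= lo_nm) & (wl < hi_nm)  # left-sum: exclude the hi endpoint
    if not mask.any():
        raise ValueError("no wavelength bins in the requested range")
    return float(spectrum.reflectance[mask].mean())


def synth_spectrum(kind: str, level: float | None = None,
                   seed: int = 0, n_replicates: int = 5,
                   noise_sd: float = 0.05) -> list[Spectrum]:
    """Generate raw replicate spectra on a 1-nm grid over 300-700 nm.

    ``superblack``: flat at ``level`` (default 0.2 %) plus Gaussian noise
    with negative excursions.  ``normalblack``: baseline ``level`` (default
    3.5 %) with a monotone melanin-like upward slope added above 600 nm
    (+0.02 %/nm), plus the same noise.
    """
    if kind not in ("superblack", "normalblack"):
        raise ValueError("kind must be 'superblack' or 'normalblack'")
    if level is None:
        level = 0.2 if kind == "superblack" else 3.5
    if level <= 0:
        raise ValueError("level must be positive")
    rng = np.random.default_rng(seed)
    wl = np.arange(300.0, 701.0)
    base = np.full_like(wl, level)
    if kind == "normalblack":
        base = base + 0.02 * np.clip(wl - 600.0, 0.0, None)
    out = []
    for i in range(n_replicates):
        noisy = base + rng.normal(0.0, noise_sd, len(wl))
        out.append(Spectrum(wl.copy(), noisy,
                            meta={"kind": kind, "replicate": i,
                                  "seed": seed}))
    return out
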