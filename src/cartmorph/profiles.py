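"""Cartilage cross-section geometry.

A section is represented by two ordered polylines in micrometer coordinates:
the articular surface and the tidemark (the boundary between uncalcified and
calcified cartilage).  The x axis runs along the section, y increases toward
the joint space, so the surface lies above the tidemark everywhere.

Synthetic sections are built from

* a smooth condylar base curve — a shallow parabolic arc whose apex
  curvature matches a condylar radius of ~15 mm, so surface normals are not
  vertical and perpendicular-measurement code is genuinely exercised;
* a zero-mean fibrillation roughness field — a sum of random-phase sinusoids
  rescaled so its realized RMS over the region of interest (ROI) equals the
  requested value exactly, which makes roughness recovery analytically
  checkable;
* optionally, erosion lesions carved as cosine-tapered depressions whose
  depth is expressed in thirds of the local cartilage thickness.

The tidemark is the parallel (normal-offset) curve of the base at the
animal's true thickness, so the perpendicular surface-to-tidemark separation
of an unlesioned section equals the true thickness by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .presets import GeometrySettings
from .scoring import Lesion, LesionDepth

__all__ = ["CartilageProfile", "ProfileValidationError", "build_profile", "roughness_field"]

ROI_WIDTH_TOL = 1.0  # um


class ProfileValidationError(ValueError):
    """Raised when a cartilage profile violates its geometric invariants."""


@dataclass
class CartilageProfile:
    """Two boundary polylines plus the measurement geometry.

    Coordinates are in micrometers.  ``scale`` records the um-per-pixel
    factor of the raster the boundaries came from (1.0 when coordinates are
    already physical).  ``roi`` is the 7 mm weight-bearing evaluation window;
    ``flanks`` are the two x-intervals of normal cartilage outside it, used
    to fit the idealized smooth surface.
    """

    surface: np.ndarray  # (N, 2)
    tidemark: np.ndarray  # (M, 2)
    roi: tuple[float, float]
    flanks: tuple[tuple[float, float], tuple[float, float]]
    scale: float = 1.0
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.surface = np.asarray(self.surface, dtype=float)
        self.tidemark = np.asarray(self.tidemark, dtype=float)

    def validate(self, roi_width: float = 7000.0) -> None:
        for name, poly in (("surface", self.surface), ("tidemark", self.tidemark)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
                raise ProfileValidationError(f"{name} must be an (N,2) polyline with N >= 2")
            if np.any(np.diff(poly[:, 0]) <= 0):
                raise ProfileValidationError(f"{name} x-coordinates must be strictly increasing")
        x0, x1 = self.roi
        if abs((x1 - x0) - roi_width) > ROI_WIDTH_TOL:
            raise ProfileValidationError(
                f"roi width {x1 - x0:.3f} um differs from {roi_width} um by more than {ROI_WIDTH_TOL} um"
            )
        lo = max(self.surface[0, 0], self.tidemark[0, 0])
        hi = min(self.surface[-1, 0], self.tidemark[-1, 0])
        if lo > x0 or hi < x1:
            raise ProfileValidationError("polylines do not span the roi")
        xs = np.linspace(lo, hi, 512)
        ys = np.interp(xs, self.surface[:, 0], self.surface[:, 1])
        yt = np.interp(xs, self.tidemark[:, 0], self.tidemark[:, 1])
        if np.any(ys - yt < -1e-6):
            raise ProfileValidationError("surface must lie above the tidemark at every shared x")

    def surface_roi(self) -> np.ndarray:
        """Digitized surface points whose x falls inside the ROI."""
        x = self.surface[:, 0]
        m = (x >= self.roi[0]) & (x <= self.roi[1])
        return self.surface[m]

    def flank_surface_points(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.surface[:, 0]
        out = []
        for lo, hi in self.flanks:
            m = (x >= lo) & (x <= hi)
            out.append(self.surface[m])
        return out[0], out[1]


def roughness_field(
    x: np.ndarray,
    target_rms: float,
    roi: tuple[float, float],
    rng: np.random.Generator,
    n_waves: tuple[int, int] = (3, 8),
    wavelength: tuple[float, float] = (250.0, 2000.0),
    edge_taper: float = 150.0,
) -> np.ndarray:
    """Random-phase sinusoidal fibrillation field with exact ROI RMS.

    The field is a sum of 3-8 sinusoids with wavelengths drawn
    log-uniformly, cosine-tapered to zero over ``edge_taper`` um at the ROI
    edges and zero outside the ROI, then rescaled so that the root mean
    square over the digitized ROI abscissae equals ``target_rms`` exactly.
    """
    x = np.asarray(x, dtype=float)
    if target_rms < 0:
        raise ValueError("target_rms must be >= 0")
    if target_rms == 0.0:
        return np.zeros_like(x)
    k = int(rng.integers(n_waves[0], n_waves[1] + 1))
    lam = np.exp(rng.uniform(np.log(wavelength[0]), np.log(wavelength[1]), size=k))
    phase = rng.uniform(0, 2 * np.pi, size=k)
    amp = rng.uniform(0.5, 1.0, size=k)
    f = np.zeros_like(x)
    for a, l, p in zip(amp, lam, phase):
        f += a * np.sin(2 * np.pi * x / l + p)

    x0, x1 = roi
    window = np.zeros_like(x)
    inside = (x >= x0) & (x <= x1)
    window[inside] = 1.0
    if edge_taper > 0:
        for edge, sgn in ((x0, 1.0), (x1, -1.0)):
            band = inside & (sgn * (x - edge) < edge_taper)
            window[band] = 0.5 * (1 - np.cos(np.pi * sgn * (x[band] - edge) / edge_taper))
    f = f * window

    realized = float(np.sqrt(np.mean(f[inside] ** 2)))
    if realized < 1e-12:  # pathological phase cancellation; retry deterministic
        return roughness_field(x, target_rms, roi, rng, n_waves, wavelength, edge_taper)
    return f * (target_rms / realized)


def _carve(x: np.ndarray, surface_y: np.ndarray, local_thickness: np.ndarray,
           lesions: Sequence[Lesion], roi: tuple[float, float],
           rng: np.random.Generator) -> np.ndarray:
    """Subtract cosine-tapered depressions for each erosion lesion.

    Depth is a fraction of the local cartilage thickness: one third, two
    thirds, or the full depth for the full-depth categories.  Fissures are
    carved as narrow notches; surface irregularities are left to the
    fibrillation field.
    """
    frac = {
        LesionDepth.EROSION_ONE_THIRD: 1 / 3,
        LesionDepth.EROSION_TWO_THIRDS: 2 / 3,
        LesionDepth.FULL_DEPTH: 1.0,
        LesionDepth.FULL_DEPTH_CALCIFIED: 1.0,
    }
    x0, x1 = roi
    y = surface_y.copy()
    for lesion in lesions:
        if lesion.depth is LesionDepth.SURFACE_IRREGULARITY:
            continue
        if lesion.depth is LesionDepth.FISSURE:
            width, depth_frac = 30.0, 0.4
        else:
            width = max(lesion.extent_fraction * (x1 - x0), 50.0)
            depth_frac = frac[lesion.depth]
        half = width / 2
        c = rng.uniform(x0 + half, x1 - half) if x1 - x0 > width else 0.5 * (x0 + x1)
        m = np.abs(x - c) <= half
        taper = 0.5 * (1 + np.cos(np.pi * (x[m] - c) / half))
        y[m] -= depth_frac * local_thickness[m] * taper
    return y


def build_profile(
    thickness_um: float,
    rms_um: float,
    geometry: GeometrySettings | None = None,
    rng: np.random.Generator | None = None,
    lesions: Sequence[Lesion] | None = None,
) -> CartilageProfile:
    """Construct one synthetic medial-femoral cross-section.

    The ROI is centred on the condylar apex at x in [-3500, 3500] um with
    flanks of normal (smooth) cartilage on either side.  The stored ``truth``
    records the injected thickness, RMS and lesion inventory for recovery
    testing.
    """
    geometry = geometry or GeometrySettings()
    rng = rng if rng is not None else np.random.default_rng()
    if thickness_um <= 0:
        raise ValueError("thickness_um must be > 0")

    half_roi = geometry.roi_length / 2
    lo = -half_roi - geometry.flank_length
    hi = half_roi + geometry.flank_length
    n = int(np.ceil((hi - lo) / geometry.point_spacing)) + 1
    x = np.linspace(lo, hi, n)
    roi = (-half_roi, half_roi)
    flanks = ((lo, -half_roi), (half_roi, hi))

    R = geometry.condyle_radius
    base = 1000.0 - x**2 / (2 * R)  # parabolic condylar arc, apex radius R
    dydx = -x / R
    s = np.sqrt(1 + dydx**2)

    field_ = roughness_field(
        x, rms_um, roi, rng,
        n_waves=geometry.n_roughness_waves,
        wavelength=geometry.roughness_wavelength,
        edge_taper=geometry.edge_taper,
    )
    surface_y = base + field_
    if lesions:
        surface_y = _carve(x, surface_y, np.full_like(x, thickness_um), lesions, roi, rng)

    # Tidemark = parallel curve of the base at distance thickness_um, so the
    # perpendicular separation equals the true thickness by construction.
    tid_x = x + thickness_um * dydx / s
    tid_y = base - thickness_um / s

    # Full-depth lesions may carve through the band; the surface can touch
    # but never cross the tidemark.
    if lesions:
        surface_y = np.maximum(surface_y, np.interp(x, tid_x, tid_y))

    profile = CartilageProfile(
        surface=np.column_stack([x, surface_y]),
        tidemark=np.column_stack([tid_x, tid_y]),
        roi=roi,
        flanks=flanks,
        scale=1.0,
        truth={
            "thickness_um": float(thickness_um),
            "rms_um": float(rms_um),
            "normalized_roughness": 1000.0 * rms_um / thickness_um,
            "lesions": [l.to_dict() for l in (lesions or [])],
        },
    )
    profile.validate(roi_width=geometry.roi_length)
    return profile
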