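"""Quantitative cartilage histomorphometry.

Given a digitized cross-section (articular surface and tidemark polylines in
micrometer coordinates) this module measures, over a 7 mm weight-bearing
region of interest (ROI):

* **thickness** — the mean of 20 measurements taken perpendicularly to the
  surface at equally spaced abscissae.  Perpendicular means along the local
  normal of the *idealized* smooth surface: rays are cast from the real
  surface along that normal to their nearest tidemark intersection.  The
  idealized surface is a low-order polynomial fitted only to the flanking
  normal cartilage outside the ROI, so fibrillation noise and lesions do not
  perturb the measurement directions.
* **area** — trapezoidal integration of the surface-to-tidemark vertical
  separation over the ROI (or a narrower evaluation window).
* **RMS surface roughness** — the root mean square deviation of the real
  digitized surface from the idealized surface over all N digitized ROI
  points, ``sqrt((1/N) * sum_i (Y_ideal_i - Y_real_i)**2)``.
* **normalized roughness** — RMS roughness divided by mean thickness.  The
  raw ratio is of order 0.02-0.05 for degenerated cartilage; it is reported
  multiplied by 1000 (a reporting convention, switchable via
  ``ratio_scale``).

A scale-calibration and boundary-extraction path is provided for grayscale
raster sections: the um/px factor is read off a rendered 1 mm ruler bar, and
the tissue band's upper/lower contours become the surface and tidemark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .profiles import CartilageProfile

__all__ = [
    "IdealizedSurface",
    "MorphometryResult",
    "CalibrationError",
    "SegmentationError",
    "GeometryError",
    "calibrate_scale",
    "extract_boundaries",
    "fit_idealized_surface",
    "mean_thickness",
    "cartilage_area",
    "rms_roughness",
    "normalized_roughness",
    "measure_profile",
]

logger = logging.getLogger(__name__)

#: Reporting convention for the dimensionless roughness/thickness ratio.
RATIO_REPORT_SCALE = 1000.0


class CalibrationError(ValueError):
    pass


class SegmentationError(ValueError):
    pass


class GeometryError(ValueError):
    pass


class FitError(ValueError):
    pass


@dataclass
class IdealizedSurface:
    """Low-order polynomial model of the ideal smooth articular surface,
    fitted from the flanking normal cartilage only."""

    model: Polynomial
    degree: int

    def __call__(self, x) -> np.ndarray:
        return self.model(np.asarray(x, dtype=float))

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients in the unscaled x domain, ascending order."""
        return self.model.convert().coef

    def slope(self, x) -> np.ndarray:
        return self.model.deriv()(np.asarray(x, dtype=float))

    def sampled(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.column_stack([x, self(x)])


@dataclass
class MorphometryResult:
    thickness_mean: float  # um
    thickness_points: np.ndarray  # the 20 perpendicular measurements, um
    area: float  # um^2
    rms_roughness: float  # um
    normalized_roughness: float  # dimensionless x1000
    n_digitized: int  # N of the RMS formula

    def to_dict(self) -> dict:
        return {
            "thickness_um": self.thickness_mean,
            "area_um2": self.area,
            "rms_um": self.rms_roughness,
            "normalized_roughness": self.normalized_roughness,
            "n_digitized": self.n_digitized,
        }


# ---------------------------------------------------------------------------
# Raster path
# ---------------------------------------------------------------------------

DARK_LEVEL = 20  # ruler bar intensity threshold
TISSUE_LEVEL = 120  # tissue band intensity threshold
MIN_BAR_PX = 10
MIN_COMPONENT_PX = 50


def _longest_run(mask_row: np.ndarray) -> int:
    if not mask_row.any():
        return 0
    padded = np.concatenate([[0], mask_row.astype(int), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def calibrate_scale(ruler_image: np.ndarray, known_length: float = 1000.0) -> float:
    """Read the um/px factor off the rendered ruler bar.

    The bar is located as the longest horizontal run of dark pixels;
    ``known_length`` is its physical length in um (1 mm by default).
    """
    img = np.asarray(ruler_image)
    dark = img < DARK_LEVEL
    runs = [_longest_run(row) for row in dark]
    bar_px = max(runs, default=0)
    if bar_px < MIN_BAR_PX:
        raise CalibrationError(
            f"no ruler bar found (longest dark horizontal run {bar_px} px < {MIN_BAR_PX})"
        )
    return known_length / bar_px


def extract_boundaries(
    image: np.ndarray,
    scale: float,
    roi: tuple[float, float] | None = None,
    roi_length: float = 7000.0,
) -> CartilageProfile:
    """Segment the tissue band and return its contours as a profile.

    The band must form exactly one connected component above the tissue
    intensity threshold.  Per image column, the topmost tissue pixel becomes
    the surface and the bottommost the tidemark; y increases upward
    (``y = -row * scale``), x is ``column * scale``.  When ``roi`` is not
    given, a centred window of ``roi_length`` is used and the remainder of
    the band becomes the flanks.
    """
    from skimage import measure

    img = np.asarray(image)
    tissue = img > TISSUE_LEVEL
    labels = measure.label(tissue, connectivity=2)
    sizes = np.bincount(labels.ravel())
    components = [i for i in range(1, sizes.size) if sizes[i] >= MIN_COMPONENT_PX]
    if len(components) != 1:
        raise SegmentationError(
            f"expected exactly one tissue band, found {len(components)} components"
        )
    band = labels == components[0]

    cols = np.flatnonzero(band.any(axis=0))
    surface_pts, tidemark_pts = [], []
    for c in cols:
        rows = np.flatnonzero(band[:, c])
        surface_pts.append((c * scale, -rows.min() * scale))
        tidemark_pts.append((c * scale, -rows.max() * scale))
    surface = np.asarray(surface_pts)
    tidemark = np.asarray(tidemark_pts)

    x_lo, x_hi = surface[0, 0], surface[-1, 0]
    if roi is None:
        mid = 0.5 * (x_lo + x_hi)
        roi = (mid - roi_length / 2, mid + roi_length / 2)
    if roi[0] < x_lo or roi[1] > x_hi:
        raise SegmentationError("tissue band does not span the requested roi")
    flanks = ((x_lo, roi[0]), (roi[1], x_hi))

    profile = CartilageProfile(
        surface=surface, tidemark=tidemark, roi=roi, flanks=flanks, scale=scale
    )
    profile.validate(roi_width=roi[1] - roi[0])
    return profile


# ---------------------------------------------------------------------------
# Geometric measurements
# ---------------------------------------------------------------------------


def fit_idealized_surface(profile: CartilageProfile, degree: int = 2) -> IdealizedSurface:
    """Least-squares polynomial fit to the flank surface points only.

    The flanks are normal cartilage outside the degenerated ROI, so the fit
    captures the condylar shape without chasing fibrillation or lesions.
    """
    left, right = profile.flank_surface_points()
    if len(left) < 10 or len(right) < 10:
        raise FitError(
            f"each flank needs >= 10 surface points (got {len(left)} and {len(right)}); "
            "provide flanks or fall back to degree 0 over the roi"
        )
    pts = np.vstack([left, right])
    model = Polynomial.fit(pts[:, 0], pts[:, 1], deg=degree)
    return IdealizedSurface(model=model, degree=degree)


def _ray_polyline_distance(origin: np.ndarray, direction: np.ndarray,
                           polyline: np.ndarray) -> float | None:
    """Distance along a ray to its nearest polyline intersection, or None."""
    a = polyline[:-1]
    seg = polyline[1:] - a
    ao = a - origin
    denom = direction[0] * seg[:, 1] - direction[1] * seg[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (ao[:, 0] * seg[:, 1] - ao[:, 1] * seg[:, 0]) / denom
        u = (ao[:, 1] * direction[0] - ao[:, 0] * direction[1]) / -denom
    ok = np.isfinite(d) & np.isfinite(u) & (d > 0) & (u >= 0) & (u <= 1)
    if not ok.any():
        return None
    return float(d[ok].min())


def mean_thickness(
    profile: CartilageProfile,
    idealized: IdealizedSurface | None = None,
    n_points: int = 20,
) -> tuple[float, np.ndarray]:
    """Mean of ``n_points`` perpendicular thickness measurements.

    At equally spaced abscissae across the ROI, a ray is cast from the real
    surface along the inward normal of the idealized surface to its nearest
    tidemark intersection.  Points where the ray misses the tidemark (edge
    geometry) fall back to the vertical surface-tidemark distance and are
    logged.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if idealized is None:
        idealized = fit_idealized_surface(profile)
    xs = np.linspace(profile.roi[0], profile.roi[1], n_points)
    y_real = np.interp(xs, profile.surface[:, 0], profile.surface[:, 1])
    slopes = idealized.slope(xs)
    values = np.empty(n_points)
    n_fallback = 0
    for i, (x, y, m) in enumerate(zip(xs, y_real, slopes)):
        norm = np.hypot(m, 1.0)
        direction = np.array([m / norm, -1.0 / norm])  # inward unit normal
        d = _ray_polyline_distance(np.array([x, y]), direction, profile.tidemark)
        if d is None:
            y_tid = np.interp(x, profile.tidemark[:, 0], profile.tidemark[:, 1])
            d = y - y_tid
            n_fallback += 1
        values[i] = d
    if n_fallback:
        logger.debug("mean_thickness: vertical-distance fallback at %d/%d points",
                     n_fallback, n_points)
    return float(values.mean()), values


def cartilage_area(
    profile: CartilageProfile,
    window: tuple[float, float] | None = None,
) -> float:
    """Cartilage area (um^2) between surface and tidemark.

    Trapezoidal integration of the vertical separation over ``window``
    (default: the full ROI), i.e. the area of the polygon bounded by the two
    contours and the window-edge verticals.
    """
    lo, hi = window if window is not None else profile.roi
    xs = profile.surface[:, 0]
    x_eval = np.union1d(xs[(xs >= lo) & (xs <= hi)], [lo, hi])
    y_s = np.interp(x_eval, profile.surface[:, 0], profile.surface[:, 1])
    y_t = np.interp(x_eval, profile.tidemark[:, 0], profile.tidemark[:, 1])
    sep = y_s - y_t
    if np.any(sep < -1e-6):
        raise GeometryError("surface crosses below the tidemark inside the evaluation window")
    return float(np.trapezoid(np.maximum(sep, 0.0), x_eval))


def rms_roughness(
    profile: CartilageProfile,
    idealized: IdealizedSurface | None = None,
) -> tuple[float, int]:
    """RMS deviation of the digitized real surface from the idealized one.

    Returns ``(rms_um, N)`` where N is the number of digitized surface
    points inside the ROI.
    """
    if idealized is None:
        idealized = fit_idealized_surface(profile)
    pts = profile.surface_roi()
    n = len(pts)
    if n == 0:
        raise GeometryError("no digitized surface points inside the roi")
    dev = idealized(pts[:, 0]) - pts[:, 1]
    return float(np.sqrt(np.mean(dev**2))), n


def normalized_roughness(rms: float, thickness_mean: float,
                         ratio_scale: float = RATIO_REPORT_SCALE) -> float:
    """Roughness normalized to thickness, reported x1000 by convention."""
    if thickness_mean <= 0:
        raise GeometryError("thickness_mean must be > 0")
    if rms < 0:
        raise GeometryError("rms must be >= 0")
    return ratio_scale * rms / thickness_mean


def measure_profile(
    profile: CartilageProfile,
    n_points: int = 20,
    degree: int = 2,
    area_window: tuple[float, float] | None = None,
) -> MorphometryResult:
    """Run the full measurement battery on one section."""
    idealized = fit_idealized_surface(profile, degree=degree)
    t_mean, t_points = mean_thickness(profile, idealized, n_points=n_points)
    area = cartilage_area(profile, window=area_window)
    rms, n = rms_roughness(profile, idealized)
    return MorphometryResult(
        thickness_mean=t_mean,
        thickness_points=t_points,
        area=area,
        rms_roughness=rms,
        normalized_roughness=normalized_roughness(rms, t_mean),
        n_digitized=n,
    )
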