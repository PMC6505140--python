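"""Colony-image quantification of pseudohyphal growth ("Eclipse").

A pinned, nitrogen-starved yeast colony shows a bright ring where the pin
deposited cells, a gray halo of pseudohyphal filaments spreading outward,
and a darker agar background.  The algorithm classifies each pixel into
{ring, filament, background} by color, takes the row/column extrema of the
ring pixels to define an axis-aligned ellipse, "eclipses" everything inside
that ellipse as the inner colony, and reports the filamentous index:

    index = 100 * (colony-class pixels outside the ellipse) / (eclipsed pixels)

The index is a percent-scale measure of how much growth escaped the inner
colony.  One set of color thresholds is used for a whole tray, never tuned
per colony, to avoid bias between colonies on the same plate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .render import BACKGROUND, FILAMENT, RING, well_name

logger = logging.getLogger(__name__)


class RingError(ValueError):
    """Raised when no usable ring can be located in a colony crop."""


class CalibrationError(ValueError):
    """Raised when automatic threshold calibration cannot find three modes."""


@dataclass
class ColorThresholds:
    """Luminance bands separating ring (white), filament (gray), background.

    A pixel is achromatic when its channel spread (max - min) is at most
    ``max_chroma``; achromatic pixels with mean intensity >= ``white_min``
    are ring, those in [``gray_min``, ``gray_max``) are filament, and
    everything else is background.
    """

    white_min: float = 200.0
    gray_min: float = 110.0
    gray_max: float = 200.0
    max_chroma: float = 30.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.gray_min < self.gray_max <= self.white_min <= 255:
            raise ValueError(
                "require 0 <= gray_min < gray_max <= white_min <= 255, got "
                f"{self.gray_min}, {self.gray_max}, {self.white_min}")
        if self.max_chroma < 0:
            raise ValueError("max_chroma must be >= 0")


@dataclass
class EllipseSpec:
    """Axis-aligned ellipse through the ring's row/column extrema."""

    center: tuple[float, float]          # (row, col), px
    semi_axis_row: float
    semi_axis_col: float

    def __post_init__(self) -> None:
        if self.semi_axis_row <= 0 or self.semi_axis_col <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass
class ColonyMeasurement:
    """Filamentous index and pixel accounting for one colony crop."""

    filamentous_index: float
    n_eclipsed: int
    n_outside_colony: int      # ring + filament pixels outside the ellipse
    n_filament_outside: int    # the stricter, filament-only numerator
    ellipse: EllipseSpec | None
    qc_status: str = "OK"      # OK | DROPPED | CROPPED
    qc_reason: str = ""
    well: str = ""


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    return image


def classify_pixels(image: np.ndarray, thresholds: ColorThresholds) -> np.ndarray:
    """Classify every pixel as RING, FILAMENT or BACKGROUND.

    Deterministic rule on mean channel intensity and channel spread; see
    :class:`ColorThresholds`.
    """
    image = _validate_rgb(image).astype(np.int16)
    mean = image.mean(axis=2)
    spread = image.max(axis=2) - image.min(axis=2)
    achromatic = spread <= thresholds.max_chroma
    out = np.full(mean.shape, BACKGROUND, dtype=np.uint8)
    out[achromatic & (mean >= thresholds.gray_min)
        & (mean < thresholds.gray_max)] = FILAMENT
    out[achromatic & (mean >= thresholds.white_min)] = RING
    return out


def calibrate_thresholds(plate_image: np.ndarray,
                         max_chroma: float = 30.0,
                         min_band_fraction: float = 1e-4) -> ColorThresholds:
    """Propose tray-wide thresholds from the plate luminance histogram.

    Multi-level (three-class) Otsu thresholding of the whole-tray luminance
    separates background / gray / white modes; the two cut points become
    (gray_min) and (gray_max = white_min).  A filament band holding fewer
    than ``min_band_fraction`` of pixels is flagged ``"empty filament band"``.
    Explicit user thresholds always take precedence over calibration.
    """
    from skimage.filters import threshold_multiotsu

    image = _validate_rgb(plate_image)
    lum = image.astype(np.float64).mean(axis=2)
    values, counts = np.unique(lum, return_counts=True)
    if values.size < 3:
        raise CalibrationError(
            "plate luminance histogram has fewer than three modes; "
            "supply thresholds explicitly")
    try:
        t1, t2 = threshold_multiotsu(lum, classes=3)
    except ValueError as exc:
        raise CalibrationError(f"three-mode thresholding failed: {exc}") from exc
    # Otsu cuts can land inside a histogram spike; refine by Lloyd iteration
    # on the luminance histogram and place cuts midway between class means.
    labels = np.digitize(values, [t1, t2])
    centers = np.array([
        np.average(values[labels == k], weights=counts[labels == k])
        if np.any(labels == k) else np.nan for k in range(3)])
    if np.any(np.isnan(centers)):  # a class came out empty: spread over range
        centers = np.quantile(np.repeat(values, counts), [0.05, 0.5, 0.95])
    for _ in range(30):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array([
            np.average(values[assign == k], weights=counts[assign == k])
            if np.any(assign == k) else centers[k] for k in range(3)])
        if np.allclose(new, centers):
            break
        centers = new
    centers = np.sort(centers)
    t1 = (centers[0] + centers[1]) / 2.0
    t2 = (centers[1] + centers[2]) / 2.0
    if not t1 < t2:
        raise CalibrationError("could not separate three luminance modes")
    thresholds = ColorThresholds(white_min=float(t2), gray_min=float(t1),
                                 gray_max=float(t2), max_chroma=max_chroma)
    band = (lum >= t1) & (lum < t2)
    if band.mean() < min_band_fraction:
        thresholds.flags.append("empty filament band")
        logger.warning("calibration: filament band holds %.2g%% of pixels",
                       100 * band.mean())
    return thresholds


def fit_ring_ellipse(classmap: np.ndarray,
                     valid: np.ndarray | None = None) -> EllipseSpec:
    """Axis-aligned ellipse through the extreme ring pixels.

    The minimal/maximal row and column indices of any RING pixel give the
    ellipse center ((rmin+rmax)/2, (cmin+cmax)/2) and semi-axes
    ((rmax-rmin)/2, (cmax-cmin)/2).
    """
    ring = classmap == RING
    if valid is not None:
        ring = ring & valid
    rows, cols = np.nonzero(ring)
    if rows.size == 0:
        raise RingError("no ring")
    rmin, rmax = int(rows.min()), int(rows.max())
    cmin, cmax = int(cols.min()), int(cols.max())
    if rmin == rmax or cmin == cmax:
        raise RingError("degenerate ring")
    return EllipseSpec(((rmin + rmax) / 2.0, (cmin + cmax) / 2.0),
                       (rmax - rmin) / 2.0, (cmax - cmin) / 2.0)


def eclipse_mask(ellipse: EllipseSpec, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels eclipsed by the ellipse.

    Pixel (r, c) is eclipsed iff
    ((r - cr)/sr)^2 + ((c - cc)/sc)^2 <= 1 at integer pixel centers;
    the boundary counts as eclipsed and the mask clips to ``shape``.
    """
    h, w = shape
    rr = (np.arange(h, dtype=float)[:, None] - ellipse.center[0]) / ellipse.semi_axis_row
    cc = (np.arange(w, dtype=float)[None, :] - ellipse.center[1]) / ellipse.semi_axis_col
    return rr ** 2 + cc ** 2 <= 1.0


def _border_ring_fraction(classmap: np.ndarray) -> float:
    border = np.concatenate([classmap[0, :], classmap[-1, :],
                             classmap[1:-1, 0], classmap[1:-1, -1]])
    return float((border == RING).mean()) if border.size else 0.0


def measure_colony(image: np.ndarray, thresholds: ColorThresholds,
                   exclude: np.ndarray | None = None,
                   denominator: str = "all",
                   well: str = "", strict: bool = True) -> ColonyMeasurement:
    """Measure the filamentous index of a single-colony crop.

    Composes pixel classification, ring-extrema ellipse fitting and the
    eclipse mask.  ``exclude`` is an optional boolean mask of pixels to
    remove entirely (manual crop of smudges/cracks); excluded pixels enter
    neither the numerator nor the denominator and the measurement is marked
    CROPPED.  ``denominator`` is ``"all"`` (every eclipsed pixel, default)
    or ``"nonbackground"`` (eclipsed ring+filament pixels only).  With
    ``strict=False`` ring failures become DROPPED measurements instead of
    exceptions, for batch processing.
    """
    if denominator not in ("all", "nonbackground"):
        raise ValueError(f"unknown denominator variant {denominator!r}")
    classmap = classify_pixels(image, thresholds)
    valid = np.ones(classmap.shape, dtype=bool)
    cropped = False
    if exclude is not None:
        if exclude.shape != classmap.shape:
            raise ValueError("exclude mask shape mismatch")
        valid &= ~exclude
        cropped = bool(exclude.any())
    try:
        ellipse = fit_ring_ellipse(classmap, valid)
    except RingError as exc:
        if strict:
            raise
        return ColonyMeasurement(np.nan, 0, 0, 0, None,
                                 qc_status="DROPPED", qc_reason=str(exc),
                                 well=well)
    inside = eclipse_mask(ellipse, classmap.shape) & valid
    colony = (classmap != BACKGROUND) & valid
    outside_colony = colony & ~inside
    if denominator == "all":
        n_eclipsed = int(inside.sum())
    else:
        n_eclipsed = int((inside & colony).sum())
    n_outside = int(outside_colony.sum())
    n_fil_outside = int((outside_colony & (classmap == FILAMENT)).sum())
    if n_eclipsed == 0:
        if strict:
            raise RingError("empty eclipse")
        return ColonyMeasurement(np.nan, 0, n_outside, n_fil_outside, ellipse,
                                 qc_status="DROPPED", qc_reason="empty eclipse",
                                 well=well)
    reason = ""
    if _border_ring_fraction(classmap) > 0.60:
        reason = "ring covers >60% of crop border (possible bleed-through)"
        logger.warning("%s: %s", well or "colony", reason)
    return ColonyMeasurement(
        100.0 * n_outside / n_eclipsed, n_eclipsed, n_outside, n_fil_outside,
        ellipse, qc_status="CROPPED" if cropped else "OK",
        qc_reason=reason, well=well)


@dataclass
class PlateLayout:
    """Pixel geometry of the pinned 8 x 12 grid on a tray image.

    ``exclusions`` maps well names (e.g. ``"A1"``) to lists of rectangles
    (r0, c0, r1, c1), half-open, in *plate* coordinates, whose pixels are
    removed from the well's measurement (manual crop QC).
    """

    origin: tuple[int, int] = (0, 0)
    cell_height: int = 100
    cell_width: int = 100
    n_rows: int = 8
    n_cols: int = 12
    exclusions: dict = field(default_factory=dict)

    def validate_against(self, shape: tuple[int, int]) -> None:
        h, w = shape
        r_end = self.origin[0] + self.n_rows * self.cell_height
        c_end = self.origin[1] + self.n_cols * self.cell_width
        if self.origin[0] < 0 or self.origin[1] < 0 or r_end > h or c_end > w:
            raise ValueError(
                f"layout grid ({r_end} x {c_end}) exceeds image ({h} x {w})")

    def cell_slices(self, grid_row: int, grid_col: int) -> tuple[slice, slice]:
        r0 = self.origin[0] + grid_row * self.cell_height
        c0 = self.origin[1] + grid_col * self.cell_width
        return slice(r0, r0 + self.cell_height), slice(c0, c0 + self.cell_width)


def process_plate(image: np.ndarray, layout: PlateLayout,
                  thresholds: ColorThresholds,
                  denominator: str = "all") -> list[ColonyMeasurement]:
    """Measure all 96 positions of a tray with one shared set of thresholds.

    Crops each grid cell, applies the layout's exclusion rectangles, and
    measures each colony; ring failures yield DROPPED entries and a QC log
    line rather than exceptions.
    """
    image = _validate_rgb(image)
    layout.validate_against(image.shape[:2])
    measurements: list[ColonyMeasurement] = []
    for gr in range(layout.n_rows):
        for gc in range(layout.n_cols):
            wname = well_name(gr, gc)
            rs, cs = layout.cell_slices(gr, gc)
            crop = image[rs, cs]
            exclude = None
            rects = layout.exclusions.get(wname, [])
            if rects:
                exclude = np.zeros(crop.shape[:2], dtype=bool)
                for (r0, c0, r1, c1) in rects:
                    lr0 = max(r0 - rs.start, 0)
                    lc0 = max(c0 - cs.start, 0)
                    lr1 = min(r1 - rs.start, crop.shape[0])
                    lc1 = min(c1 - cs.start, crop.shape[1])
                    if lr1 > lr0 and lc1 > lc0:
                        exclude[lr0:lr1, lc0:lc1] = True
            m = measure_colony(crop, thresholds, exclude=exclude,
                               denominator=denominator, well=wname,
                               strict=False)
            if m.qc_status != "OK":
                logger.info("QC %s: %s (%s)", wname, m.qc_status,
                            m.qc_reason or "exclusion applied")
            measurements.append(m)
    return measurements


def measurements_to_frame(measurements: list[ColonyMeasurement],
                          plate: str = "", strain: str = "",
                          treatment: str = "", assay: str = ""):
    """Tidy per-colony results table (one row per well)."""
    import pandas as pd

    return pd.DataFrame([{
        "plate": plate, "well": m.well, "strain": strain,
        "treatment": treatment, "assay": assay,
        "filamentous_index": m.filamentous_index,
        "n_eclipsed": m.n_eclipsed,
        "n_outside_colony": m.n_outside_colony,
        "n_filament_outside": m.n_filament_outside,
        "qc_status": m.qc_status, "qc_reason": m.qc_reason,
    } for m in measurements])
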