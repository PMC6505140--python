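"""Synthetic colony and plate renderer with exact ground truth.

Emulates flat-bed-scanner images of nitrogen-starved yeast colonies pinned
in a 96-position grid: each colony is a bright elliptical "ring" (the dense
inner colony's rim), surrounded by a gray halo of pseudohyphal filaments on
a darker agar background.  Every rendered pixel belongs to exactly one hard
color class, so the painted class map is unambiguous ground truth for the
downstream quantification, and the renderer records its own filamentous
index by direct pixel counting — independent of the measurement code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# pixel class labels shared with the quantification module
BACKGROUND, FILAMENT, RING = 0, 1, 2

#: default hard-class colors (ring, filament, background)
DEFAULT_COLORS = ((245, 245, 245), (150, 150, 150), (80, 90, 110))
ARTIFACT_COLOR = (250, 250, 250)  # near-white: corrupts ring extrema, as a smudge would


@dataclass
class ColonySpec:
    """Geometry and appearance of one synthetic colony.

    center
        (row, col) pixel coordinates of the colony center.
    ring_outer_radii
        (row semi-axis, col semi-axis) of the ring's outer boundary, px.
    ring_thickness
        Radial thickness of the bright ring, px.
    halo_extent
        How far the filamentous halo reaches beyond the ring, px.
    halo_coverage
        Fraction in [0, 1] of halo-annulus pixels painted filament-gray.
    ring_irregularity
        Amplitude in [0, 0.5] of smooth per-angle radial noise on the outer
        ring boundary, as a fraction of the radius.
    """

    center: tuple[float, float]
    ring_outer_radii: tuple[float, float]
    ring_thickness: float = 6.0
    halo_extent: float = 0.0
    halo_coverage: float = 0.0
    ring_irregularity: float = 0.0
    colors: tuple = DEFAULT_COLORS

    def __post_init__(self) -> None:
        if self.ring_thickness >= min(self.ring_outer_radii):
            raise ValueError("ring_thickness must be < min(ring_outer_radii)")
        if not 0.0 <= self.halo_coverage <= 1.0:
            raise ValueError("halo_coverage must lie in [0, 1]")
        if not 0.0 <= self.ring_irregularity <= 0.5:
            raise ValueError("ring_irregularity must lie in [0, 0.5]")
        for rgb in self.colors:
            if any(not 0 <= v <= 255 for v in rgb):
                raise ValueError("color channels must lie in [0, 255]")

    @property
    def max_extent(self) -> float:
        """Largest radius the colony can reach from its center, px."""
        return (max(self.ring_outer_radii) * (1.0 + self.ring_irregularity)
                + self.halo_extent)


@dataclass
class GroundTruth:
    """Exact painted-pixel accounting for one rendered colony."""

    position: str
    n_ring: int
    n_filament: int
    n_background: int
    ring_extents: tuple[int, int, int, int]  # rmin, rmax, cmin, cmax
    ellipse_center: tuple[float, float]
    ellipse_semi_axes: tuple[float, float]
    painted_index: float      # by direct counting against the extrema ellipse
    analytic_index: float     # closed-form ellipse-area ratio
    flags: list[str] = field(default_factory=list)


@dataclass
class PlateSpec:
    """96-position plate: grid geometry, per-position colonies, artifacts.

    ``colonies`` maps (row, col) grid positions (0-based) to a ColonySpec
    whose center is relative to the cell's top-left corner; missing
    positions are empty.  ``artifacts`` are axis-aligned rectangles
    (r0, c0, r1, c1), half-open, in plate pixel coordinates, painted last
    in a near-white smudge color.
    """

    cell_size: int = 100
    margin: int = 20
    n_rows: int = 8
    n_cols: int = 12
    colonies: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)
    background: tuple = DEFAULT_COLORS[2]

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols > 96:
            raise ValueError("at most 96 positions")
        h, w = self.image_shape
        for r0, c0, r1, c1 in self.artifacts:
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"artifact {(r0, c0, r1, c1)} outside image")
        for (gr, gc) in self.colonies:
            if not (0 <= gr < self.n_rows and 0 <= gc < self.n_cols):
                raise ValueError(f"grid position {(gr, gc)} out of range")

    @property
    def image_shape(self) -> tuple[int, int]:
        return (2 * self.margin + self.n_rows * self.cell_size,
                2 * self.margin + self.n_cols * self.cell_size)

    def cell_origin(self, grid_row: int, grid_col: int) -> tuple[int, int]:
        return (self.margin + grid_row * self.cell_size,
                self.margin + grid_col * self.cell_size)


def well_name(grid_row: int, grid_col: int) -> str:
    """A1-style well name for a 0-based grid position (A1 = top-left)."""
    return f"{chr(ord('A') + grid_row)}{grid_col + 1}"


def _smooth_periodic_noise(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth periodic perturbation in [-1, 1]: a few random harmonics."""
    harmonics = rng.integers(2, 6, size=3)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    amps = rng.uniform(0.3, 1.0, size=3)
    s = sum(a * np.sin(k * theta + ph)
            for a, k, ph in zip(amps, harmonics, phases))
    peak = np.max(np.abs(s))
    return s / peak if peak > 0 else np.zeros_like(s)


def _paint_colony(canvas: np.ndarray, classmap: np.ndarray, spec: ColonySpec,
                  rng: np.random.Generator) -> None:
    """Paint ring and halo pixels of one colony onto canvas + class map."""
    h, w = classmap.shape
    cr, cc = spec.center
    a, b = spec.ring_outer_radii  # row, col semi-axes
    reach = spec.max_extent
    r0, r1 = max(0, int(np.floor(cr - reach)) - 1), min(h, int(np.ceil(cr + reach)) + 2)
    c0, c1 = max(0, int(np.floor(cc - reach)) - 1), min(w, int(np.ceil(cc + reach)) + 2)
    rows = np.arange(r0, r1, dtype=float)[:, None] - cr
    cols = np.arange(c0, c1, dtype=float)[None, :] - cc
    rho = np.sqrt((rows / a) ** 2 + (cols / b) ** 2)
    theta = np.arctan2(rows / a, cols / b)  # angle in normalized coordinates

    if spec.ring_irregularity > 0:
        noise = _smooth_periodic_noise(theta.ravel(), rng).reshape(theta.shape)
        rho_outer = 1.0 + spec.ring_irregularity * noise
    else:
        rho_outer = np.ones_like(rho)
    rho_inner = rho_outer * (1.0 - spec.ring_thickness / min(a, b))
    rho_halo = rho_outer + spec.halo_extent / min(a, b)

    ring = (rho >= rho_inner) & (rho <= rho_outer)
    halo = (rho > rho_outer) & (rho <= rho_halo)
    if spec.halo_coverage >= 1.0:
        fil = halo
    elif spec.halo_coverage <= 0.0:
        fil = np.zeros_like(halo)
    else:
        fil = halo & (rng.random(halo.shape) < spec.halo_coverage)

    ring_rgb, fil_rgb, _ = spec.colors
    view = canvas[r0:r1, c0:c1]
    cview = classmap[r0:r1, c0:c1]
    view[fil] = fil_rgb
    cview[fil] = FILAMENT
    view[ring] = ring_rgb
    cview[ring] = RING


def _ground_truth_from_classmap(classmap: np.ndarray, spec: ColonySpec,
                                position: str = "") -> GroundTruth:
    """Exact index by direct counting against the painted-extrema ellipse."""
    ring_rows, ring_cols = np.nonzero(classmap == RING)
    flags: list[str] = []
    if ring_rows.size == 0:
        return GroundTruth(position, 0, int((classmap == FILAMENT).sum()),
                           int((classmap == BACKGROUND).sum()),
                           (-1, -1, -1, -1), (np.nan, np.nan),
                           (np.nan, np.nan), np.nan, np.nan, ["empty"])
    rmin, rmax = int(ring_rows.min()), int(ring_rows.max())
    cmin, cmax = int(ring_cols.min()), int(ring_cols.max())
    center = ((rmin + rmax) / 2.0, (cmin + cmax) / 2.0)
    semi = ((rmax - rmin) / 2.0, (cmax - cmin) / 2.0)
    if semi[0] == 0 or semi[1] == 0:
        flags.append("degenerate ring")
        painted_index = np.nan
    else:
        rr = (np.arange(classmap.shape[0], dtype=float)[:, None] - center[0]) / semi[0]
        cc = (np.arange(classmap.shape[1], dtype=float)[None, :] - center[1]) / semi[1]
        inside = rr ** 2 + cc ** 2 <= 1.0
        n_inside = int(inside.sum())
        n_outside = int(((classmap != BACKGROUND) & ~inside).sum())
        painted_index = 100.0 * n_outside / n_inside

    a, b = spec.ring_outer_radii
    if spec.halo_extent > 0:
        scale = 1.0 + spec.halo_extent / min(a, b)
        analytic = 100.0 * spec.halo_coverage * (scale * a * scale * b - a * b) / (a * b)
    else:
        analytic = 0.0
    return GroundTruth(
        position, int(ring_rows.size), int((classmap == FILAMENT).sum()),
        int((classmap == BACKGROUND).sum()), (rmin, rmax, cmin, cmax),
        center, semi, painted_index, analytic, flags)


def render_colony(spec: ColonySpec, image_size: tuple[int, int],
                  seed: int = 0) -> tuple[np.ndarray, GroundTruth, np.ndarray]:
    """Render one colony into a fresh image.

    Returns the H x W x 3 uint8 image, the GroundTruth record and the
    painted class map.  Rendering uses hard (non-anti-aliased) color
    classes and is bit-reproducible for a fixed (spec, seed).
    """
    h, w = image_size
    cr, cc = spec.center
    reach = spec.max_extent
    for name, lo, hi, c in (("row", 0, h, cr), ("col", 0, w, cc)):
        if c - reach < lo or c + reach > hi:
            raise ValueError(
                f"colony exceeds image bounds on the {name} axis: center "
                f"{c}, reach {reach:.1f}, image extent {hi}")
    rng = np.random.default_rng(seed)
    canvas = np.empty((h, w, 3), dtype=np.uint8)
    canvas[:] = spec.colors[2]
    classmap = np.full((h, w), BACKGROUND, dtype=np.uint8)
    _paint_colony(canvas, classmap, spec, rng)
    truth = _ground_truth_from_classmap(classmap, spec)
    return canvas, truth, classmap


def render_plate(spec: PlateSpec, seed: int = 0
                 ) -> tuple[np.ndarray, list[GroundTruth], np.ndarray]:
    """Render a whole plate; artifacts painted last.

    Returns the plate image, one GroundTruth per grid position (row-major,
    named A1..H12) and the painted class map.  Positions overlapped by an
    artifact are flagged "artifact"; empty positions are flagged "empty".
    Per-position random streams are spawned deterministically from ``seed``.
    """
    h, w = spec.image_shape
    canvas = np.empty((h, w, 3), dtype=np.uint8)
    canvas[:] = spec.background
    classmap = np.full((h, w), BACKGROUND, dtype=np.uint8)

    children = np.random.SeedSequence(seed).spawn(spec.n_rows * spec.n_cols)
    truths: list[GroundTruth] = []
    for gr in range(spec.n_rows):
        for gc in range(spec.n_cols):
            pos = well_name(gr, gc)
            cspec = spec.colonies.get((gr, gc))
            orow, ocol = spec.cell_origin(gr, gc)
            if cspec is None:
                truths.append(GroundTruth(pos, 0, 0, spec.cell_size ** 2,
                                          (-1, -1, -1, -1), (np.nan, np.nan),
                                          (np.nan, np.nan), np.nan, np.nan,
                                          ["empty"]))
                continue
            cr, cc = cspec.center
            if (cr - cspec.max_extent < 0 or cr + cspec.max_extent > spec.cell_size
                    or cc - cspec.max_extent < 0
                    or cc + cspec.max_extent > spec.cell_size):
                raise ValueError(
                    f"colony at {pos} overlaps neighbouring cells "
                    f"(reach {cspec.max_extent:.1f} px, cell {spec.cell_size} px)")
            # paint into a cell-local buffer so ground truth is per-colony
            local = np.empty((spec.cell_size, spec.cell_size, 3), dtype=np.uint8)
            local[:] = spec.background
            local_map = np.full((spec.cell_size, spec.cell_size),
                                BACKGROUND, dtype=np.uint8)
            rng = np.random.default_rng(children[gr * spec.n_cols + gc])
            _paint_colony(local, local_map, cspec, rng)
            truth = _ground_truth_from_classmap(local_map, cspec, position=pos)
            canvas[orow:orow + spec.cell_size, ocol:ocol + spec.cell_size] = local
            classmap[orow:orow + spec.cell_size,
                     ocol:ocol + spec.cell_size] = local_map
            truths.append(truth)

    for (r0, c0, r1, c1) in spec.artifacts:
        canvas[r0:r1, c0:c1] = ARTIFACT_COLOR
        classmap[r0:r1, c0:c1] = RING  # near-white scores as ring-class
        for gr in range(spec.n_rows):
            for gc in range(spec.n_cols):
                orow, ocol = spec.cell_origin(gr, gc)
                if (r0 < orow + spec.cell_size and r1 > orow
                        and c0 < ocol + spec.cell_size and c1 > ocol):
                    t = truths[gr * spec.n_cols + gc]
                    if "artifact" not in t.flags:
                        t.flags.append("artifact")
    return canvas, truths, classmap


def write_ground_truth_csv(truths: list[GroundTruth], path,
                           header_lines: list[str] | None = None) -> None:
    import pandas as pd

    rows = [{
        "position": t.position,
        "analytic_index": t.analytic_index,
        "painted_index": t.painted_index,
        "ring_extents": "|".join(map(str, t.ring_extents)),
        "n_ring": t.n_ring, "n_filament": t.n_filament,
        "flags": ";".join(t.flags),
    } for t in truths]
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def save_png(image: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(image, mode="RGB").save(path, format="PNG")


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as an H x W x 3 uint8 array."""
    from PIL import Image

    img = np.asarray(Image.open(path).convert("RGB"))
    return img
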