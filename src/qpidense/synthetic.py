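"""Forward simulation of quantitative-phase scenes with known ground truth.

The simulator stands in for the microscope: it renders optical-path-difference
(OPD) images of prolate-ellipsoid yeast cells referenced to culture medium
(plate mode) or of a packed microfluidic chamber referenced to PDMS (chamber
mode), plus GFP z-stacks, so every analysis stage downstream has an exact
oracle. OPD is in nm, lengths in μm, pressure in MPa.

Geometry model: a cell is a prolate ellipsoid with in-plane semi-axes (a, b),
a ≥ b, and vertical semi-axis c = b (minor axis vertical). The OPD contributed
at a pixel is (RI_cell − RI_reference) times the vertical chord through the
ellipsoid at that pixel centre — an exact closed form, no wave optics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import OpticalConstants

__all__ = [
    "SyntheticCell",
    "SyntheticChamberTruth",
    "PlateScene",
    "ChamberScene",
    "render_plate_scene",
    "render_chamber_scene",
    "generate_pressure_series",
    "generate_gfp_stack",
    "sample_plate_population",
]

_NM_PER_UM = 1000.0


def _require_seed(noise_sd: float, seed) -> np.random.Generator | None:
    """Stochastic renders must be explicitly seeded; noiseless ones need no RNG."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd == 0:
        return None
    if seed is None:
        raise ValueError("noise_sd > 0 requires an explicit seed")
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SyntheticCell:
    """A prolate-ellipsoid cell: position (μm), semi-axes a ≥ b = c (μm),
    intracellular refractive index and in-plane orientation (rad)."""

    center_xy: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b); vertical semi-axis equals b
    ri: float
    orientation: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        if a < b:
            raise ValueError(f"major semi-axis a must be >= b, got {self.semi_axes}")

    @property
    def height_um(self) -> float:
        """Vertical extent 2b — what plate-mode analysis estimates as d_cell."""
        return 2.0 * self.semi_axes[1]


@dataclass(frozen=True)
class SyntheticChamberTruth:
    """Ground truth for a pressurised-chamber experiment.

    The cellular refractive index follows ri(P) = ri_at_zero + ri_slope·P and
    the chamber height d(P) = chamber_height0 + height_slope·P. The nominal
    intracellular osmotic pressure pi_c0_true is the (sign-flipped) pressure at
    which the extrapolated RI reaches that of water, so the three RI fields
    must satisfy pi_c0_true = (ri_at_zero − n_water)/ri_slope.
    """

    pi_c0_true: float  # MPa
    ri_slope: float  # RI per MPa
    ri_at_zero: float
    chamber_height0: float  # μm
    height_slope: float  # μm per MPa
    packing_fraction: float = 1.0
    noise_sd: float = 0.0  # nm, additive i.i.d. Gaussian on OPD pixels
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ri_slope <= 0:
            raise ValueError(f"ri_slope must be > 0, got {self.ri_slope}")
        if not (0.0 <= self.packing_fraction <= 1.0):
            raise ValueError(f"packing_fraction must be in [0, 1], got {self.packing_fraction}")
        if self.chamber_height0 <= 0:
            raise ValueError(f"chamber_height0 must be > 0, got {self.chamber_height0}")

    @classmethod
    def from_anchor(
        cls,
        pi_c0_true: float,
        ri_at_zero: float,
        n_water: float,
        chamber_height0: float,
        height_slope: float,
        **kwargs,
    ) -> "SyntheticChamberTruth":
        """Build a self-consistent truth from the anchor (pi_c0, RI at P=0)."""
        slope = (ri_at_zero - n_water) / pi_c0_true
        return cls(
            pi_c0_true=pi_c0_true,
            ri_slope=slope,
            ri_at_zero=ri_at_zero,
            chamber_height0=chamber_height0,
            height_slope=height_slope,
            **kwargs,
        )

    def check_consistent(self, n_water: float, tol: float = 1e-9) -> None:
        implied = (self.ri_at_zero - n_water) / self.ri_slope
        if abs(implied - self.pi_c0_true) > tol * max(1.0, abs(self.pi_c0_true)):
            raise ValueError(
                f"inconsistent truth: (ri_at_zero - n_water)/ri_slope = {implied:.6g} "
                f"but pi_c0_true = {self.pi_c0_true:.6g}"
            )

    def ri_at(self, gip: float) -> float:
        return self.ri_at_zero + self.ri_slope * gip

    def height_at(self, gip: float) -> float:
        return self.chamber_height0 + self.height_slope * gip


@dataclass
class PlateScene:
    """Rendered medium-referenced OPD image plus its per-cell ground truth."""

    image: np.ndarray  # OPD, nm, float32
    pixel_size_um: float
    truth: pd.DataFrame  # cell_id, x_um, y_um, a_um, b_um, ri_true, peak_opd_nm, ...


@dataclass
class ChamberScene:
    """Rendered PDMS-referenced OPD image, the chamber-interior mask, and truth."""

    image: np.ndarray  # OPD, nm, float32
    interior_mask: np.ndarray  # bool, True inside the chamber
    pixel_size_um: float
    truth: dict


def _pixel_grid(image_shape: tuple[int, int], pixel_size_um: float):
    ny, nx = image_shape
    x = (np.arange(nx) + 0.5) * pixel_size_um
    y = (np.arange(ny) + 0.5) * pixel_size_um
    return x, y


def _cell_chord_um(cell: SyntheticCell, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
    """Vertical chord length (μm) through the ellipsoid at each pixel centre.

    chord(x, y) = 2c·sqrt(1 − (x'/a)² − (y'/b)²) with c = b and (x', y') the
    in-plane coordinates rotated into the cell frame.
    """
    a, b = cell.semi_axes
    cx, cy = cell.center_xy
    dx = x_um[None, :] - cx
    dy = y_um[:, None] - cy
    ct, st = math.cos(cell.orientation), math.sin(cell.orientation)
    xr = dx * ct + dy * st
    yr = -dx * st + dy * ct
    s = 1.0 - (xr / a) ** 2 - (yr / b) ** 2
    return 2.0 * b * np.sqrt(np.clip(s, 0.0, None))


def render_plate_scene(
    cells: list[SyntheticCell],
    constants: OpticalConstants,
    pixel_size_um: float,
    image_shape: tuple[int, int],
    noise_sd: float = 0.0,
    seed: int | None = None,
    on_overlap: str = "error",
    background_poly: tuple[float, ...] | None = None,
) -> PlateScene:
    """Render a medium-referenced OPD image of cells lying on a plate.

    Each pixel receives OPD = (ri − n_media)·chord in nm; the background is
    zero up to noise and the optional smooth bias. ``on_overlap`` is "error"
    (reject scenes with overlapping cells) or "sum" (chords add).

    ``background_poly`` — optional quadratic bias surface, coefficients
    (c0, cx, cy, cxx, cxy, cyy) in nm over coordinates normalised to [0, 1];
    emulates the slowly varying OPD gradients of real phase images.
    """
    ny, nx = image_shape
    if ny <= 0 or nx <= 0:
        raise ValueError(f"image shape must be positive, got {image_shape}")
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    if on_overlap not in ("error", "sum"):
        raise ValueError(f"on_overlap must be 'error' or 'sum', got {on_overlap!r}")
    rng = _require_seed(noise_sd, seed)

    x_um, y_um = _pixel_grid(image_shape, pixel_size_um)
    fov_x, fov_y = nx * pixel_size_um, ny * pixel_size_um
    image = np.zeros(image_shape, dtype=np.float64)
    occupied = np.zeros(image_shape, dtype=bool)

    records = []
    for cid, cell in enumerate(cells):
        a = cell.semi_axes[0]
        cx, cy = cell.center_xy
        if not (a <= cx <= fov_x - a and a <= cy <= fov_y - a):
            raise ValueError(f"cell {cid} at ({cx:.2f}, {cy:.2f}) μm does not lie within the field")
        # render only within the cell's bounding box for speed
        j0 = max(0, int((cx - a) / pixel_size_um) - 1)
        j1 = min(nx, int((cx + a) / pixel_size_um) + 2)
        i0 = max(0, int((cy - a) / pixel_size_um) - 1)
        i1 = min(ny, int((cy + a) / pixel_size_um) + 2)
        chord = _cell_chord_um(cell, x_um[j0:j1], y_um[i0:i1])
        support = chord > 0
        if on_overlap == "error" and np.any(occupied[i0:i1, j0:j1] & support):
            raise ValueError(f"cell {cid} overlaps a previously placed cell")
        occupied[i0:i1, j0:j1] |= support
        image[i0:i1, j0:j1] += (cell.ri - constants.n_media) * chord * _NM_PER_UM
        records.append(
            {
                "cell_id": cid,
                "x_um": cx,
                "y_um": cy,
                "a_um": cell.semi_axes[0],
                "b_um": cell.semi_axes[1],
                "height_um": cell.height_um,
                "ri_true": cell.ri,
                "orientation_rad": cell.orientation,
                "peak_opd_nm": (cell.ri - constants.n_media) * cell.height_um * _NM_PER_UM,
            }
        )

    if background_poly is not None:
        c0, cx1, cy1, cxx, cxy, cyy = background_poly
        xn = (np.arange(nx) + 0.5) / nx
        yn = (np.arange(ny) + 0.5) / ny
        X, Y = np.meshgrid(xn, yn)
        image += c0 + cx1 * X + cy1 * Y + cxx * X**2 + cxy * X * Y + cyy * Y**2
    if rng is not None:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)

    truth = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["cell_id", "x_um", "y_um", "a_um", "b_um", "height_um",
                 "ri_true", "orientation_rad", "peak_opd_nm"]
    )
    return PlateScene(image=image.astype(np.float32), pixel_size_um=pixel_size_um, truth=truth)


def _chamber_interior_mask(image_shape: tuple[int, int], border_px: int) -> np.ndarray:
    ny, nx = image_shape
    mask = np.zeros(image_shape, dtype=bool)
    mask[border_px : ny - border_px, border_px : nx - border_px] = True
    if not mask.any():
        raise ValueError("chamber border leaves no interior pixels")
    return mask


def render_chamber_scene(
    truth: SyntheticChamberTruth,
    gip: float,
    constants: OpticalConstants,
    pixel_size_um: float,
    image_shape: tuple[int, int] = (64, 64),
    border_px: int = 8,
    packing_fraction: float | None = None,
) -> ChamberScene:
    """Render a PDMS-referenced OPD image of a pressurised chamber.

    The chamber interior is a uniform effective medium of refractive index
    φ·ri(P) + (1 − φ)·n_media (φ = packing fraction); its OPD against the PDMS
    surround is (n_interior − n_pdms)·d_chamber(P), negative whenever the
    interior is optically rarer than PDMS. The PDMS frame renders as zero.
    """
    if gip < 0:
        raise ValueError(f"growth-induced pressure must be >= 0, got {gip}")
    truth.check_consistent(constants.n_water)
    rng = _require_seed(truth.noise_sd, truth.seed)

    phi = truth.packing_fraction if packing_fraction is None else packing_fraction
    if not (0.0 <= phi <= 1.0):
        raise ValueError(f"packing fraction must be in [0, 1], got {phi}")
    ri_cell = truth.ri_at(gip)
    n_interior = phi * ri_cell + (1.0 - phi) * constants.n_media
    d_um = truth.height_at(gip)
    opd_nm = (n_interior - constants.n_pdms) * d_um * _NM_PER_UM

    mask = _chamber_interior_mask(image_shape, border_px)
    image = np.zeros(image_shape, dtype=np.float64)
    image[mask] = opd_nm
    if rng is not None:
        image = image + rng.normal(0.0, truth.noise_sd, size=image.shape)

    record = {
        "gip_mpa": gip,
        "ri_true": ri_cell,
        "n_interior_true": n_interior,
        "d_chamber_um": d_um,
        "mean_opd_nm_true": opd_nm,
        "packing_fraction": phi,
        "underestimated": phi < 1.0,
    }
    return ChamberScene(
        image=image.astype(np.float32),
        interior_mask=mask,
        pixel_size_um=pixel_size_um,
        truth=record,
    )


def generate_pressure_series(
    truth: SyntheticChamberTruth,
    gip_values: list[float] | np.ndarray,
    constants: OpticalConstants,
    pixel_size_um: float = 0.1,
    image_shape: tuple[int, int] = (64, 64),
    border_px: int = 8,
    packing_fraction_gip0: float | None = None,
) -> tuple[list[ChamberScene], pd.DataFrame]:
    """Render one chamber scene per pressure and collect the ground-truth table.

    At P = 0 the chamber may be only partially filled (cells have not yet grown
    to confluence); ``packing_fraction_gip0`` overrides the packing fraction
    for those scenes to reproduce the documented RI underestimation. Per-scene
    seeds are derived from ``truth.seed`` so the whole series is reproducible.
    """
    gip_values = np.asarray(gip_values, dtype=float)
    if gip_values.size == 0:
        raise ValueError("gip_values must be non-empty")

    if truth.noise_sd > 0 and truth.seed is None:
        raise ValueError("noise_sd > 0 requires an explicit seed")
    child_seeds: list[int | None]
    if truth.seed is not None:
        ss = np.random.SeedSequence(truth.seed)
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(gip_values.size)]
    else:
        child_seeds = [None] * gip_values.size

    scenes: list[ChamberScene] = []
    rows = []
    for gip, s in zip(gip_values, child_seeds):
        scene_truth = SyntheticChamberTruth(
            pi_c0_true=truth.pi_c0_true,
            ri_slope=truth.ri_slope,
            ri_at_zero=truth.ri_at_zero,
            chamber_height0=truth.chamber_height0,
            height_slope=truth.height_slope,
            packing_fraction=truth.packing_fraction,
            noise_sd=truth.noise_sd,
            seed=s,
        )
        phi = None
        if gip == 0 and packing_fraction_gip0 is not None:
            phi = packing_fraction_gip0
        scene = render_chamber_scene(
            scene_truth, float(gip), constants, pixel_size_um, image_shape,
            border_px=border_px, packing_fraction=phi,
        )
        scenes.append(scene)
        rows.append(scene.truth)
    table = pd.DataFrame.from_records(rows)
    return scenes, table


def generate_gfp_stack(
    cells: list[SyntheticCell],
    per_cell_brightness: list[float] | np.ndarray,
    autofluorescence_level: float,
    background_level: float,
    z_step_um: float = 0.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
    pixel_size_um: float = 0.1,
    image_shape: tuple[int, int] = (128, 128),
) -> tuple[np.ndarray, np.ndarray]:
    """Render a labeled GFP z-stack and a matched blank (unlabeled) stack.

    Each cell's total brightness is spread uniformly over the voxels of its
    in-plane footprint across the slices spanning its height, so the
    background- and autofluorescence-corrected sum recovers the brightness
    exactly in the noiseless case. Both stacks share the uniform background
    and autofluorescence rates (per pixel per slice).
    """
    if z_step_um <= 0:
        raise ValueError(f"z_step_um must be > 0, got {z_step_um}")
    brightness = np.asarray(per_cell_brightness, dtype=float)
    if brightness.size != len(cells):
        raise ValueError("one brightness per cell required")
    if np.any(brightness < 0):
        raise ValueError("per-cell brightness must be non-negative")
    rng = _require_seed(noise_sd, seed)

    max_height = max((c.height_um for c in cells), default=z_step_um)
    n_z = max(1, int(math.ceil(max_height / z_step_um)))
    ny, nx = image_shape
    x_um, y_um = _pixel_grid(image_shape, pixel_size_um)

    signal = np.zeros((n_z, ny, nx), dtype=np.float64)
    for cell, b_total in zip(cells, brightness):
        chord = _cell_chord_um(cell, x_um, y_um)
        footprint = chord > 0
        n_px = int(footprint.sum())
        if n_px == 0:
            raise ValueError("cell footprint smaller than one pixel; refine pixel_size_um")
        n_slices = max(1, min(n_z, int(round(cell.height_um / z_step_um))))
        per_voxel = b_total / (n_px * n_slices)
        signal[:n_slices][:, footprint] += per_voxel

    base = background_level + autofluorescence_level
    labeled = signal + base
    blank = np.full_like(signal, base)
    if rng is not None:
        labeled = labeled + rng.normal(0.0, noise_sd, size=labeled.shape)
        blank = blank + rng.normal(0.0, noise_sd, size=blank.shape)
    return labeled, blank


def sample_plate_population(
    n_cells: int,
    ri_mean: float,
    ri_sd: float,
    height_mean_um: float,
    height_sd_um: float,
    field_um: tuple[float, float],
    seed: int,
    constants: OpticalConstants | None = None,
    aspect_range: tuple[float, float] = (1.05, 1.6),
    clearance_um: float = 0.4,
    max_tries: int = 100_000,
) -> list[SyntheticCell]:
    """Draw a non-overlapping asynchronous population of plate cells.

    RI and height (2b) are Gaussian around the population means; the in-plane
    aspect ratio a/b is uniform over ``aspect_range`` and orientation uniform.
    Placement is rejection sampling keeping centre separations above the sum
    of major semi-axes plus ``clearance_um``.
    """
    rng = np.random.default_rng(seed)
    n_water = constants.n_water if constants is not None else 1.332
    fx, fy = field_um
    cells: list[SyntheticCell] = []
    centers: list[tuple[float, float, float]] = []  # x, y, exclusion radius
    tries = 0
    while len(cells) < n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place all cells without overlap; enlarge the field")
        height = rng.normal(height_mean_um, height_sd_um)
        if height < 1.0:
            continue  # reject non-physical tiny cells
        b = height / 2.0
        a = b * rng.uniform(*aspect_range)
        ri = max(rng.normal(ri_mean, ri_sd), n_water + 1e-4)
        cx = rng.uniform(a + clearance_um, fx - a - clearance_um)
        cy = rng.uniform(a + clearance_um, fy - a - clearance_um)
        if any((cx - px) ** 2 + (cy - py) ** 2 < (a + pr + clearance_um) ** 2
               for px, py, pr in centers):
            continue
        cells.append(
            SyntheticCell(center_xy=(cx, cy), semi_axes=(a, b), ri=ri,
                          orientation=rng.uniform(0, np.pi))
        )
        centers.append((cx, cy, a))
    return cells
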