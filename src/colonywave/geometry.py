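"""Colony masks and edge-distance machinery.

All simulations and quantifications in this package share a single geometric
vocabulary: a boolean lattice marking the cell-covered region of a
micropatterned colony, a physical calibration (micrometres per pixel), and a
per-pixel distance from the colony edge. Radial profiles everywhere in the
package are functions of *edge distance*, not of distance from the centroid,
so that non-circular shapes (triangles, pacman) are handled uniformly.

Conventions
-----------
* pixel centers, 0-based row-major indices; distances are center-to-center
* the default calibration maps a 700 um colony onto a 50-pixel diameter
  (14 um/pixel), so the canonical simulation circle of radius 25 pixels
  represents a 700 um colony
* the pacman wedge is 90 degrees, apex at the circle center, bisector along +x
* triangles are equilateral with one vertex pointing up (-y in image
  coordinates); ``nominal_diameter`` is the circumscribed-circle diameter
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

DEFAULT_PIXEL_SIZE = 14.0  # um / pixel: maps the radius-25 px circle to 700 um

SHAPES = ("circle", "triangle", "pacman", "custom")


@dataclass(frozen=True)
class ColonyMask:
    """Boolean lattice of the cell-covered region, with physical calibration.

    Invariants (checked by :func:`validate_mask`): exactly one connected
    foreground component with positive area, and a margin of at least one
    background pixel on every lattice border, so periodic boundary conditions
    in the simulators never wrap the colony onto itself.
    """

    grid: np.ndarray  # bool, H x W
    pixel_size: float  # um per pixel
    shape_label: str = "custom"
    nominal_diameter: float = 0.0  # um

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=bool))

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def centroid(self) -> tuple[float, float]:
        """Foreground centroid as (row, col) in pixels."""
        rr, cc = np.nonzero(self.grid)
        return float(rr.mean()), float(cc.mean())


@dataclass(frozen=True)
class EdgeDistanceField:
    """Distance from the colony edge (um), defined on foreground pixels."""

    values: np.ndarray  # float, um; 0 outside the mask
    max_distance: float  # um


class MaskError(ValueError):
    pass


def validate_mask(mask: ColonyMask) -> None:
    grid = mask.grid
    if grid.ndim != 2:
        raise MaskError("mask grid must be 2-D")
    if grid.sum() == 0:
        raise MaskError("empty mask: foreground area must be > 0")
    if (
        grid[0, :].any()
        or grid[-1, :].any()
        or grid[:, 0].any()
        or grid[:, -1].any()
    ):
        raise MaskError(
            "foreground touches the lattice border; periodic boundaries "
            "would wrap the colony onto itself (need >= 1 pixel margin)"
        )
    _, n_components = ndimage.label(grid)
    if n_components != 1:
        raise MaskError(
            f"mask must have exactly one connected component, got {n_components}"
        )


def make_mask(
    shape_label: str,
    nominal_diameter: float,
    lattice_size: int | tuple[int, int] = 190,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> ColonyMask:
    """Construct a colony mask centered on the lattice.

    Parameters
    ----------
    shape_label
        One of ``circle``, ``triangle``, ``pacman``.
    nominal_diameter
        Physical diameter in um. For the triangle this is the diameter of the
        circumscribed circle; for the pacman it is the diameter of the parent
        circle before removal of the 90-degree wedge.
    lattice_size
        Lattice side (square) or an (H, W) pair.
    pixel_size
        um per pixel.

    Raises
    ------
    MaskError
        If the shape does not fit the lattice with a 1-pixel margin, or the
        requested diameter is degenerate.
    """
    if shape_label not in ("circle", "triangle", "pacman"):
        raise MaskError(f"unknown shape label {shape_label!r}")
    if nominal_diameter <= 0:
        raise MaskError("nominal_diameter must be > 0 (empty masks forbidden)")
    if np.isscalar(lattice_size):
        H = W = int(lattice_size)
    else:
        H, W = map(int, lattice_size)
    radius_px = nominal_diameter / 2.0 / pixel_size
    needed = int(np.ceil(2 * radius_px)) + 3  # shape + margin
    if H < needed or W < needed:
        raise MaskError(
            f"{shape_label} of diameter {nominal_diameter} um "
            f"({2 * radius_px:.1f} px) does not fit a {H}x{W} lattice; "
            f"need at least {needed}x{needed}"
        )
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx

    if shape_label == "circle":
        grid = dy**2 + dx**2 <= radius_px**2
    elif shape_label == "pacman":
        grid = dy**2 + dx**2 <= radius_px**2
        # remove the 90-degree wedge with bisector along +x (image "east");
        # wedge spans angles in (-45, 45) degrees around the center
        ang = np.arctan2(dy, dx)
        grid &= ~(np.abs(ang) < np.pi / 4)
    else:  # equilateral triangle, one vertex up, circumradius = radius_px
        R = radius_px
        # vertex angles measured in image coords (y down): up is -90 deg
        angles = np.deg2rad([-90.0, 30.0, 150.0])
        vx = cx + R * np.cos(angles)
        vy = cy + R * np.sin(angles)
        grid = np.ones((H, W), dtype=bool)
        for i in range(3):
            x1, y1 = vx[i], vy[i]
            x2, y2 = vx[(i + 1) % 3], vy[(i + 1) % 3]
            # keep pixels on the centroid side of each edge
            cross = (x2 - x1) * (yy - y1) - (y2 - y1) * (xx - x1)
            side = (x2 - x1) * (cy - y1) - (y2 - y1) * (cx - x1)
            grid &= cross * np.sign(side) >= 0

    mask = ColonyMask(
        grid=grid,
        pixel_size=float(pixel_size),
        shape_label=shape_label,
        nominal_diameter=float(nominal_diameter),
    )
    validate_mask(mask)
    return mask


def edge_distance(mask: ColonyMask) -> EdgeDistanceField:
    """Euclidean distance (um) from each foreground pixel to the colony edge.

    Boundary pixels (foreground pixels 4-adjacent to background) are exactly 0:
    the raw center-to-center distance transform is shifted by one pixel and
    clipped at zero.
    """
    validate_mask(mask)
    dt = ndimage.distance_transform_edt(mask.grid)
    vals = np.clip(dt - 1.0, 0.0, None) * mask.pixel_size
    vals[~mask.grid] = 0.0
    return EdgeDistanceField(values=vals, max_distance=float(vals.max()))


def analytic_edge_distance(mask: ColonyMask) -> EdgeDistanceField:
    """Exact distance (um) to the ideal shape boundary for canonical shapes.

    The lattice distance transform carries an orientation-dependent bias of
    up to one pixel along boundaries not aligned with the lattice axes; for
    the canonical shapes (circle, triangle, pacman) the distance to the
    ideal geometric boundary is available in closed form and is used by the
    simulators and fate measurements. Custom masks fall back to
    :func:`edge_distance`.
    """
    if mask.shape_label not in ("circle", "triangle", "pacman"):
        return edge_distance(mask)
    H, W = mask.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    R = mask.nominal_diameter / 2.0 / mask.pixel_size
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx
    r = np.sqrt(dy**2 + dx**2)

    if mask.shape_label == "circle":
        vals = R - r
    elif mask.shape_label == "pacman":

        def seg_dist(ang: float) -> np.ndarray:
            ex, ey = np.cos(ang), np.sin(ang)
            t = np.clip(dx * ex + dy * ey, 0.0, R)
            return np.sqrt((dx - t * ex) ** 2 + (dy - t * ey) ** 2)

        vals = np.minimum(R - r, np.minimum(seg_dist(np.pi / 4), seg_dist(-np.pi / 4)))
    else:  # triangle: min distance to the three side lines
        angles = np.deg2rad([-90.0, 30.0, 150.0])
        vx = R * np.cos(angles)
        vy = R * np.sin(angles)
        vals = np.full((H, W), np.inf)
        for i in range(3):
            x1, y1 = vx[i], vy[i]
            x2, y2 = vx[(i + 1) % 3], vy[(i + 1) % 3]
            L = np.hypot(x2 - x1, y2 - y1)
            dist_line = np.abs((x2 - x1) * (dy - y1) - (y2 - y1) * (dx - x1)) / L
            vals = np.minimum(vals, dist_line)
    vals = np.clip(vals, 0.0, None) * mask.pixel_size
    vals[~mask.grid] = 0.0
    return EdgeDistanceField(values=vals, max_distance=float(vals.max()))


def bin_by_edge_distance(
    field: EdgeDistanceField,
    mask: ColonyMask,
    bin_width: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges (um) covering [0, max_distance] and per-pixel bin index.

    Returns ``(bin_edges, bin_index)`` where ``bin_index`` is -1 outside the
    mask. The last bin absorbs the maximum so every foreground pixel is
    assigned.
    """
    n_bins = max(1, int(np.ceil(field.max_distance / bin_width)))
    bin_edges = np.arange(n_bins + 1, dtype=float) * bin_width
    idx = np.minimum((field.values / bin_width).astype(int), n_bins - 1)
    idx = np.where(mask.grid, idx, -1)
    return bin_edges, idx


# ---------------------------------------------------------------------------
# I/O: single-channel TIFF (0/255) with a JSON sidecar for the calibration


def save_mask(mask: ColonyMask, path: str | Path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, (mask.grid.astype(np.uint8) * 255))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size": mask.pixel_size,
                "shape_label": mask.shape_label,
                "nominal_diameter": mask.nominal_diameter,
            }
        )
    )


def load_mask(path: str | Path) -> ColonyMask:
    import tifffile

    path = Path(path)
    grid = tifffile.imread(path) > 0
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    mask = ColonyMask(
        grid=grid,
        pixel_size=float(meta.get("pixel_size", DEFAULT_PIXEL_SIZE)),
        shape_label=meta.get("shape_label", "custom"),
        nominal_diameter=float(meta.get("nominal_diameter", 0.0)),
    )
    validate_mask(mask)
    return mask
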