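"""Particle outlining, measurement and filtering.

A *particle* is one connected component of foreground (stained) pixels in a
binarized image.  Each particle is measured with the descriptor set used
throughout the analysis: pixel area, outer-boundary perimeter, circularity
(``4*pi*area/perimeter**2``, capped at 1), maximum Feret (caliper) diameter,
convex-hull area and solidity (``area/hull_area``, capped at 1).

Perimeter estimation
--------------------
The perimeter is estimated from the Freeman chain code of the outer boundary
(pixel centres, 8-connected, holes filled for the trace only).  Two regimes:

* purely rectilinear boundaries (no diagonal chain steps): unit step lengths
  plus a signed miter corner term ``sum(min(tan(|turn|/2), 2))``, which
  reproduces the continuous perimeter of axis-aligned rectangles, strips and
  dominoes exactly;
* boundaries containing diagonal steps: corner-corrected chain-code weights
  ``P = we*Ne + wd*No + wc*Nc + c0`` with ``Ne``/``No`` the number of
  axis/diagonal steps and ``Nc`` the number of direction changes.  The
  coefficients were calibrated once on randomly placed digital disks
  (r in [9, 45]); the intercept absorbs the fixed total curvature of a closed
  boundary.  Worst-case error is ~1.2% on digital disks of radius >= 10 and
  < 1% on digital ellipses — a naive crack-boundary perimeter would
  overestimate a disk's perimeter by ~27% and depress its circularity to
  ~0.62, breaking the 0.8-circularity filter semantics.

Convex hull
-----------
The hull polygon is built from the pixel corner points, pulled in by a
quarter pixel for curved boundaries (calibrated against continuous disks,
hull area within ~1%) and kept at the full corners for rectilinear
boundaries (exact for axis-aligned rectangles).  The Feret diameter always
uses the full corner polygon, so a single pixel measures sqrt(2) and a
10x5 rectangle sqrt(125).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as skmeasure

from .imaging import BinaryMask

__all__ = [
    "Particle",
    "FilterSpec",
    "label_components",
    "measure_mask",
    "circularity",
    "solidity",
    "max_feret",
    "apply_filter",
    "particle_table",
    "PERIMETER_ESTIMATOR",
]

# Chain-code perimeter coefficients, calibrated on randomly placed digital
# disks of radius 9-45 (axis weight, diagonal weight, corner weight,
# closed-boundary curvature intercept).
_WE, _WD, _WC, _C0 = 1.037386, 1.370160, -0.128778, 2.831535
#: Identifier of the perimeter estimator, recorded in output metadata.
PERIMETER_ESTIMATOR = "chain-code(calibrated-disk weights; rectilinear exact)"

# hull shrink (pixels) for curved boundaries
_HULL_INSET = 0.25

# Moore neighbourhood in clockwise order starting North: (drow, dcol)
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass(frozen=True)
class Particle:
    """Measurements of one connected stained component."""

    id: int
    area_px: int
    perimeter_px: float
    circularity: float
    feret_max_px: float
    hull_area_px: float
    solidity: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclass(frozen=True)
class FilterSpec:
    """One cell of the screening grid.

    ``binarization`` is either the string ``"auto"`` or an integer fixed
    threshold; circularity and size (area, px) bounds are inclusive at both
    ends.
    """

    binarization: object = "auto"
    circularity_min: float = 0.0
    circularity_max: float = 1.0
    size_min_px: float = 10.0
    size_max_px: float = math.inf

    def __post_init__(self) -> None:
        if not 0.0 <= self.circularity_min <= self.circularity_max <= 1.0:
            raise ValueError("need 0 <= circularity_min <= circularity_max <= 1")
        if not 0 < self.size_min_px <= self.size_max_px:
            raise ValueError("need 0 < size_min_px <= size_max_px")
        if self.binarization != "auto":
            t = int(self.binarization)
            if not 0 <= t <= 255:
                raise ValueError("fixed binarization threshold must be in [0, 255]")
            object.__setattr__(self, "binarization", t)

    @property
    def label(self) -> str:
        hi = "inf" if math.isinf(self.size_max_px) else f"{self.size_max_px:g}"
        return (
            f"bin={self.binarization}|circ={self.circularity_min:g}-"
            f"{self.circularity_max:g}|size={self.size_min_px:g}-{hi}"
        )


def label_components(mask, connectivity: int = 8) -> np.ndarray:
    """Label maximal connected foreground regions (default 8-connectivity).

    Returns the labeled integer array; background is 0.
    """
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    return skmeasure.label(data, connectivity=1 if connectivity == 4 else 2)


def circularity(area: float, perimeter: float) -> float:
    """``min(1, 4*pi*area/perimeter**2)``; 1 for a circle, -> 0 when elongated."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def solidity(area: float, hull_area: float) -> float:
    """``min(1, area/hull_area)``; 1 for a convex (solid) object."""
    if area <= 0 or hull_area <= 0:
        raise ValueError("area and hull_area must be positive")
    return min(1.0, area / hull_area)


def max_feret(points: np.ndarray) -> float:
    """Maximum caliper diameter of a point set (boundary polygon vertices).

    Computed as the exhaustive pairwise maximum over convex-hull vertices,
    which equals the exhaustive maximum over all points.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) == 0:
        raise ValueError("empty point set")
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # degenerate (collinear) point sets
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _trace_outer(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbour trace of the outer boundary pixel centres.

    ``mask`` must contain a single 8-connected, hole-filled region.  Returns
    the closed boundary path as an (n, 2) array of (row, col); uses Jacob's
    stopping criterion (stop on re-entering the start pixel from the same
    direction).
    """
    rows, cols = np.nonzero(mask)
    r0, c0 = int(rows[0]), int(cols[0])  # topmost, then leftmost
    h, w = mask.shape
    path = [(r0, c0)]
    back = 6  # came from the West
    cur = (r0, c0)
    start_state = None
    while True:
        nxt = None
        for k in range(1, 9):
            d = (back + k) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                nxt = (nr, nc)
                entry = d
                break
        if nxt is None:  # isolated pixel
            return np.array(path)
        state = (nxt, entry)
        if start_state is None:
            start_state = state
        elif state == start_state:
            # the closure step may have re-appended the start pixel
            while len(path) > 1 and path[-1] == path[0]:
                path.pop()
            return np.array(path)
        path.append(nxt)
        cur = nxt
        back = (entry + 4) % 8
        if len(path) > 4 * mask.size:  # safety net; cannot trigger on valid input
            raise RuntimeError("boundary trace failed to close")


def _perimeter_from_path(path: np.ndarray) -> float:
    if len(path) == 1:
        # a single pixel is treated as the digitization of a dot of radius 1/2
        return math.pi
    p = path.astype(float)
    d = np.diff(np.vstack([p, p[:1]]), axis=0)
    step2 = (d**2).sum(1)
    n_diag = int((step2 > 1.5).sum())
    n_axis = len(d) - n_diag
    dirs = np.arctan2(d[:, 0], d[:, 1])
    turns = np.diff(np.concatenate([dirs, dirs[:1]]))
    turns = (turns + np.pi) % (2.0 * np.pi) - np.pi
    n_corner = int((np.abs(turns) > 1e-9).sum())
    if n_diag == 0:
        # rectilinear: exact crack-equivalent perimeter via signed miter offsets
        total = turns.sum()
        sgn = 1.0 if total >= 0 else -1.0
        miter = np.sum(np.sign(turns) * sgn * np.minimum(np.abs(np.tan(turns / 2.0)), 2.0))
        return float(n_axis + miter)
    return float(_WE * n_axis + _WD * n_diag + _WC * n_corner + _C0)


def _corner_points(boundary: np.ndarray, inset: float) -> np.ndarray:
    d = 0.5 - inset
    offs = ((-d, -d), (-d, d), (d, -d), (d, d))
    return np.vstack([boundary + off for off in offs]).astype(float)


def _measure_region(
    region_mask: np.ndarray,
    pid: int,
    offset: tuple[int, int],
    with_feret: bool = True,
) -> Particle:
    """Measure one cropped region mask (True inside the particle)."""
    area = int(region_mask.sum())
    if area >= 8:  # smaller regions cannot enclose a hole
        filled = ndimage.binary_fill_holes(region_mask)
    else:
        filled = region_mask
    path = _trace_outer(filled)
    perim = _perimeter_from_path(path)
    circ = circularity(area, perim)

    # boundary pixels suffice for hull / feret (they contain all extreme pixels)
    if len(path) == 1:
        hull_area = 1.0
        feret = math.sqrt(2.0)
    else:
        d = np.diff(np.vstack([path, path[:1]]), axis=0)
        rectilinear = not np.any((d**2).sum(1) > 1.5)
        bpts = path  # duplicates are harmless for hull construction
        inset = 0.0 if rectilinear else _HULL_INSET
        hull_pts = _corner_points(bpts, inset)
        try:
            hull_area = float(ConvexHull(hull_pts).volume)
        except QhullError:
            hull_area = float(area)
        feret = max_feret(_corner_points(bpts, 0.0)) if with_feret else math.nan
    sol = solidity(area, hull_area)

    rr, cc = np.nonzero(region_mask)
    r0, c0 = offset
    centroid = (float(rr.mean()) + r0, float(cc.mean()) + c0)
    bbox = (int(rr.min()) + r0, int(cc.min()) + c0, int(rr.max()) + r0 + 1, int(cc.max()) + c0 + 1)
    return Particle(
        id=pid,
        area_px=area,
        perimeter_px=perim,
        circularity=circ,
        feret_max_px=feret,
        hull_area_px=hull_area,
        solidity=sol,
        centroid=centroid,
        bbox=bbox,
    )


def measure_mask(
    mask,
    connectivity: int = 8,
    include_edge: bool = True,
    with_feret: bool = True,
) -> list[Particle]:
    """Label a binary mask and measure every particle.

    Parameters
    ----------
    mask : BinaryMask or bool ndarray
    connectivity : {4, 8}
        Foreground connectivity (8 by default, the particle-analyzer
        convention).
    include_edge : bool
        Whether particles touching the image border are measured (default
        True).
    with_feret : bool
        Set False to skip the Feret diameter (NaN) when only area/shape
        descriptors are needed (the screening hot path).

    Returns
    -------
    list of :class:`Particle`, ordered by label.
    """
    labels = label_components(mask, connectivity)
    particles: list[Particle] = []
    h, w = labels.shape
    for region in skmeasure.regionprops(labels):
        minr, minc, maxr, maxc = region.bbox
        if not include_edge and (minr == 0 or minc == 0 or maxr == h or maxc == w):
            continue
        crop = region.image  # bool array of the region within its bbox
        particles.append(_measure_region(crop, region.label, (minr, minc), with_feret))
    return particles


def apply_filter(particles: list[Particle], spec: FilterSpec) -> list[Particle]:
    """Retain particles whose circularity and area fall inside the filter.

    Both bounds of both ranges are inclusive; input order is preserved.
    Particles outside the filter range are ignored.
    """
    return [
        p
        for p in particles
        if spec.circularity_min <= p.circularity <= spec.circularity_max
        and spec.size_min_px <= p.area_px <= spec.size_max_px
    ]


def particle_table(
    particles: list[Particle],
    image_id: str = "",
    pixel_size_um: float = 1.4,
) -> pd.DataFrame:
    """Tabulate per-particle measurements, with Feret also in micrometres."""
    rows = [
        dict(
            image_id=image_id,
            particle_id=p.id,
            area_px=p.area_px,
            perimeter_px=p.perimeter_px,
            circularity=p.circularity,
            feret_px=p.feret_max_px,
            feret_um=p.feret_max_px * pixel_size_um,
            hull_area_px=p.hull_area_px,
            solidity=p.solidity,
            centroid_row=p.centroid[0],
            centroid_col=p.centroid[1],
        )
        for p in particles
    ]
    cols = [
        "image_id", "particle_id", "area_px", "perimeter_px", "circularity",
        "feret_px", "feret_um", "hull_area_px", "solidity",
        "centroid_row", "centroid_col",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["perimeter_estimator"] = PERIMETER_ESTIMATOR
    return df
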