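"""Synthetic fixtures, tumor-like images and patient cohorts.

Three generators, all deterministic under a seed:

* :func:`generate_fixture_mask` renders non-overlapping geometric shapes
  (disks, rectangles, ellipses, a plus-pentomino, single pixels) together
  with their closed-form continuous measurements, so the particle
  measurements can be checked against analytic geometry.
* :func:`generate_tumor_image` emulates a pan-cytokeratin-stained tumor
  section at 1.4 um/pixel: a light background (strictly above the fixed
  binarization thresholds), dark irregular epithelial clusters built as
  unions of disks along a random walk, and scattered dark single cells
  rendered as hard (un-anti-aliased) disks whose pixel areas fall in the
  20-60 px single-cell band (~7-11 um equivalent diameter).
* :func:`generate_cohort` draws a patient cohort (default 102 patients,
  20 distant-metastasis events, 5 images each) in which metastasis risk is
  driven by the density of scattered single cells: the per-patient latent
  log mean count is Gaussian with a standardized event/non-event separation
  ``d``, so the generating AUC of the latent count is ``Phi(d/sqrt(2))``
  (monotone transforms of a Gaussian latent preserve AUC).  Event times are
  exponential with log-rate linear in the latent density; censoring mimics
  the study's follow-up window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtri

from .imaging import DEFAULT_PIXEL_SIZE_UM, GrayImage

__all__ = [
    "ShapeSpec",
    "MorphologySpec",
    "CohortSimSpec",
    "SimulatedCohort",
    "generate_fixture_mask",
    "render_shapes_image",
    "generate_tumor_image",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# geometric fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeSpec:
    """One geometric shape to rasterize, with analytic ground truth.

    ``kind`` is one of ``disk``, ``rectangle``, ``ellipse``,
    ``plus_pentomino``, ``single_pixel``.  ``position`` is the centre
    (row, col) for disks/ellipses/plus/pixel and the top-left pixel for
    rectangles.  Sizes are in pixels: ``radius`` for disks, ``width`` and
    ``height`` for rectangles, ``axes`` (semi-axis row, semi-axis col) for
    ellipses.  ``intensity`` is used only when rendering a grayscale image.
    """

    kind: str
    position: tuple[float, float]
    radius: float | None = None
    width: int | None = None
    height: int | None = None
    axes: tuple[float, float] | None = None
    intensity: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"disk", "rectangle", "ellipse", "plus_pentomino", "single_pixel"}:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if not 0 <= self.intensity <= 255:
            raise ValueError("intensity must be in [0, 255]")
        if self.kind == "disk" and not (self.radius and self.radius > 0):
            raise ValueError("disk requires a positive radius")
        if self.kind == "rectangle" and not (self.width and self.height):
            raise ValueError("rectangle requires width and height")
        if self.kind == "ellipse" and not (
            self.axes and self.axes[0] > 0 and self.axes[1] > 0
        ):
            raise ValueError("ellipse requires positive semi-axes")

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize onto a boolean canvas of the given image shape."""
        rows, cols = shape
        out = np.zeros(shape, dtype=bool)
        r, c = self.position
        if self.kind == "single_pixel":
            out[int(round(r)), int(round(c))] = True
        elif self.kind == "plus_pentomino":
            ri, ci = int(round(r)), int(round(c))
            out[ri, ci - 1 : ci + 2] = True
            out[ri - 1 : ri + 2, ci] = True
        elif self.kind == "rectangle":
            r0, c0 = int(round(r)), int(round(c))
            out[r0 : r0 + self.height, c0 : c0 + self.width] = True
        elif self.kind == "disk":
            yy, xx = np.mgrid[:rows, :cols]
            out = (yy - r) ** 2 + (xx - c) ** 2 <= self.radius**2
        else:  # ellipse
            ar, ac = self.axes
            yy, xx = np.mgrid[:rows, :cols]
            out = ((yy - r) / ar) ** 2 + ((xx - c) / ac) ** 2 <= 1.0
        return out

    def expected(self) -> dict[str, float]:
        """Closed-form measurements of the continuous shape."""
        if self.kind == "single_pixel":
            return dict(area=1.0, perimeter=4.0, feret=math.sqrt(2.0), hull_area=1.0)
        if self.kind == "plus_pentomino":
            # 3x3 cross of unit squares; corner-polygon hull is the octagon of area 7
            return dict(area=5.0, perimeter=12.0, feret=math.sqrt(10.0), hull_area=7.0)
        if self.kind == "rectangle":
            w, h = float(self.width), float(self.height)
            return dict(
                area=w * h,
                perimeter=2.0 * (w + h),
                feret=math.hypot(w, h),
                hull_area=w * h,
            )
        if self.kind == "disk":
            rr = float(self.radius)
            return dict(
                area=math.pi * rr**2,
                perimeter=2.0 * math.pi * rr,
                feret=2.0 * rr,
                hull_area=math.pi * rr**2,
            )
        a, b = float(self.axes[0]), float(self.axes[1])
        # Ramanujan's perimeter approximation for the ellipse
        per = math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))
        return dict(
            area=math.pi * a * b,
            perimeter=per,
            feret=2.0 * max(a, b),
            hull_area=math.pi * a * b,
        )


def generate_fixture_mask(
    shapes: list[ShapeSpec], shape: tuple[int, int]
) -> tuple[np.ndarray, list[dict[str, float]]]:
    """Rasterize non-overlapping shapes and return their analytic oracle values.

    Shapes must be pairwise disjoint even under 8-connectivity (touching
    shapes would merge into one particle and defeat per-shape oracles) and
    must fit fully inside the image bounds.
    """
    canvas = np.zeros(shape, dtype=bool)
    blocked = np.zeros(shape, dtype=bool)  # canvas dilated by 1 px
    expected = []
    for i, s in enumerate(shapes):
        m = s.render(shape)
        if not m.any():
            raise ValueError(f"shape {i} rasterizes to nothing")
        rr, cc = np.nonzero(m)
        if rr.min() == 0 or cc.min() == 0 or rr.max() == shape[0] - 1 or cc.max() == shape[1] - 1:
            raise ValueError(f"shape {i} does not fit fully inside the image bounds")
        if (m & blocked).any():
            raise ValueError(f"shape {i} overlaps or touches a previous shape")
        canvas |= m
        blocked |= ndimage.binary_dilation(m, structure=np.ones((3, 3), bool))
        exp = s.expected()
        exp["pixel_count"] = int(m.sum())
        expected.append(exp)
    return canvas, expected


def render_shapes_image(
    shapes: list[ShapeSpec],
    shape: tuple[int, int],
    background: int = 255,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> GrayImage:
    """Render shapes as dark objects on a light background (no anti-aliasing)."""
    canvas = np.full(shape, background, dtype=np.uint8)
    for s in shapes:
        canvas[s.render(shape)] = s.intensity
    return GrayImage(canvas, pixel_size_um)


# ---------------------------------------------------------------------------
# tumor-like images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphologySpec:
    """Appearance parameters of one synthetic tumor image.

    Background intensities stay strictly above the fixed thresholds in use
    (>= 251 for the 220/240/250 batch), stain intensities strictly below
    (<= 180), so fixed thresholds segment objects exactly.  Three stained
    object classes:

    * *clusters* — irregular epithelial sheets, unions of 15-50 disks along
      a random walk (low circularity; the 0.8 filter must reject them);
    * *single cells* — hard disks whose target areas are uniform on the
      20-60 px single-cell band (~7-11 um equivalent diameter at 1.4 um/px);
    * *debris* — staining noise, emulating the abundant small
      non-prognostic particles of real sections: round specks (1-13 px,
      whose capped circularity passes shape filters but whose size does
      not), small fragments (10-19 px blobs of any circularity, diluting
      the 10-px size subsets) and large elongated fragments (20-50 px at
      mid circularity, diluting the mid-circularity subsets).
    """

    shape: tuple[int, int] = (176, 176)
    background_mean: float = 253.0
    background_sd: float = 1.0
    background_floor: int = 251
    n_clusters: int = 2
    cluster_intensity_range: tuple[int, int] = (60, 170)
    cluster_walk_steps: tuple[int, int] = (10, 50)
    cluster_disk_radius: tuple[float, float] = (2.0, 5.0)
    cluster_step_length: tuple[float, float] = (3.0, 7.0)
    n_single_cells: int = 10
    cell_intensity_range: tuple[int, int] = (40, 150)
    cell_area_band: tuple[int, int] = (20, 60)
    n_specks: int = 0
    speck_radius: tuple[float, float] = (0.5, 2.05)
    n_fragments: int = 0
    fragment_large_fraction: float = 0.6
    # small fragments: 10-19 px blobs, circularity anywhere up to the cap
    fragment_small_disks: tuple[int, int] = (2, 3)
    fragment_small_radius: tuple[float, float] = (1.05, 1.65)
    # large fragments: 20-50 px elongated pieces, mid circularity
    fragment_large_disks: tuple[int, int] = (6, 9)
    fragment_large_radius: tuple[float, float] = (1.2, 1.7)
    # stride between chain disks as a multiple of the current disk radius;
    # kept below 2 so consecutive disks stay 8-connected
    fragment_step_factor: tuple[float, float] = (1.4, 1.9)
    fragment_turn_sd: float = 0.25
    debris_intensity_range: tuple[int, int] = (40, 170)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if min(self.n_single_cells, self.n_clusters, self.n_specks, self.n_fragments) < 0:
            raise ValueError("object counts must be >= 0")
        if self.background_floor <= max(
            self.cluster_intensity_range[1],
            self.cell_intensity_range[1],
            self.debris_intensity_range[1],
        ):
            raise ValueError("background must stay strictly above stain intensities")


def _stamp_disk(shape, cy, cx, radius):
    r0 = max(0, int(cy - radius) - 1)
    r1 = min(shape[0], int(cy + radius) + 2)
    c0 = max(0, int(cx - radius) - 1)
    c1 = min(shape[1], int(cx + radius) + 2)
    dy = (np.arange(r0, r1) - cy) ** 2
    dx = (np.arange(c0, c1) - cx) ** 2
    sub = dy[:, None] + dx[None, :] <= radius**2
    return (slice(r0, r1), slice(c0, c1)), sub


def generate_tumor_image(
    spec: MorphologySpec, seed: int | np.random.Generator
) -> tuple[GrayImage, dict]:
    """Render one synthetic stained section; bit-identical under the same seed.

    Returns the image and a ground-truth dict with the rendered single-cell
    and cluster counts plus their masks.

    Raises
    ------
    ValueError
        If the requested objects cannot be placed without overlap (image too
        small / too crowded).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = spec.shape
    img = np.clip(
        np.rint(rng.normal(spec.background_mean, spec.background_sd, spec.shape)),
        spec.background_floor,
        255,
    ).astype(np.uint8)

    cluster_mask = np.zeros(spec.shape, bool)
    margin = 4
    for _ in range(spec.n_clusters):
        n_steps = int(rng.integers(spec.cluster_walk_steps[0], spec.cluster_walk_steps[1] + 1))
        cy = rng.uniform(margin + 8, rows - margin - 8)
        cx = rng.uniform(margin + 8, cols - margin - 8)
        one = np.zeros(spec.shape, bool)
        for _ in range(n_steps):
            rad = rng.uniform(*spec.cluster_disk_radius)
            sl, sub = _stamp_disk(spec.shape, cy, cx, rad)
            one[sl] |= sub
            theta = rng.uniform(0, 2 * np.pi)
            step = rng.uniform(*spec.cluster_step_length)
            cy = float(np.clip(cy + step * np.sin(theta), margin, rows - margin))
            cx = float(np.clip(cx + step * np.cos(theta), margin, cols - margin))
        intensity = int(rng.integers(spec.cluster_intensity_range[0], spec.cluster_intensity_range[1] + 1))
        img[one] = intensity
        cluster_mask |= one

    # separate every object from every other by >= 1 px so 8-connected
    # labeling preserves the rendered counts exactly
    blocked = ndimage.binary_dilation(cluster_mask, np.ones((3, 3), bool))
    _3x3 = np.ones((3, 3), bool)

    def _place(make_blob, n_wanted, what, strict=True):
        """Rejection-place n_wanted blobs; returns (union mask, n placed).

        Blobs are bbox-local (slices, submask, intensity) tuples; overlap
        checks and the 1-px separation dilation stay local to the bbox.
        Strict placement raises when the image cannot hold the request;
        best-effort placement (debris) stops once the image saturates
        (a long run of consecutive rejections).
        """
        placed_mask = np.zeros(spec.shape, bool)
        placed = 0
        tries = 0
        consecutive_misses = 0
        max_tries = 400 * max(1, n_wanted)
        while placed < n_wanted:
            if tries > max_tries or (not strict and consecutive_misses > 150):
                if strict:
                    raise ValueError(
                        f"could not place {n_wanted} {what} in a {rows}x{cols} "
                        f"image without overlap"
                    )
                break
            tries += 1
            blob = make_blob()
            if blob is None:
                continue
            sl, sub, intensity = blob
            if (blocked[sl] & sub).any():
                consecutive_misses += 1
                continue
            consecutive_misses = 0
            img[sl][sub] = intensity
            placed_mask[sl] |= sub
            grow = (slice(max(0, sl[0].start - 1), min(rows, sl[0].stop + 1)),
                    slice(max(0, sl[1].start - 1), min(cols, sl[1].stop + 1)))
            pad = np.zeros((grow[0].stop - grow[0].start,
                            grow[1].stop - grow[1].start), bool)
            pad[sl[0].start - grow[0].start:sl[0].stop - grow[0].start,
                sl[1].start - grow[1].start:sl[1].stop - grow[1].start] = sub
            blocked[grow] |= ndimage.binary_dilation(pad, _3x3)
            placed += 1
        return placed_mask, placed

    lo_a, hi_a = spec.cell_area_band

    def _make_cell():
        # uniform over the single-cell area band
        rad = math.sqrt(rng.uniform(lo_a, hi_a) / math.pi)
        cy = rng.uniform(rad + 1.5, rows - rad - 2.5)
        cx = rng.uniform(rad + 1.5, cols - rad - 2.5)
        sl, sub = _stamp_disk(spec.shape, cy, cx, rad)
        if not lo_a <= int(sub.sum()) <= hi_a:
            return None
        intensity = int(rng.integers(spec.cell_intensity_range[0],
                                     spec.cell_intensity_range[1] + 1))
        return sl, sub, intensity

    def _stain_intensity():
        return int(rng.integers(spec.debris_intensity_range[0],
                                spec.debris_intensity_range[1] + 1))

    def _make_speck():
        rad = rng.uniform(*spec.speck_radius)
        cy = rng.uniform(rad + 1.5, rows - rad - 2.5)
        cx = rng.uniform(rad + 1.5, cols - rad - 2.5)
        sl, sub = _stamp_disk(spec.shape, cy, cx, rad)
        return sl, sub, _stain_intensity()

    def _make_fragment():
        if rng.random() < spec.fragment_large_fraction:
            disks, radii = spec.fragment_large_disks, spec.fragment_large_radius
        else:
            disks, radii = spec.fragment_small_disks, spec.fragment_small_radius
        n_disks = int(rng.integers(disks[0], disks[1] + 1))
        reach = radii[1] * (1 + 2 * n_disks) + 2
        cy0 = rng.uniform(reach, rows - reach)
        cx0 = rng.uniform(reach, cols - reach)
        theta = rng.uniform(0, 2 * np.pi)
        cy, cx = cy0, cx0
        stamps = []
        for _ in range(n_disks):
            rad = rng.uniform(*radii)
            stamps.append(_stamp_disk(spec.shape, cy, cx, rad))
            theta += rng.normal(0, spec.fragment_turn_sd)
            step = rad * rng.uniform(*spec.fragment_step_factor)
            cy += step * np.sin(theta)
            cx += step * np.cos(theta)
        r0 = min(s[0].start for s, _ in stamps)
        r1 = max(s[0].stop for s, _ in stamps)
        c0 = min(s[1].start for s, _ in stamps)
        c1 = max(s[1].stop for s, _ in stamps)
        sub = np.zeros((r1 - r0, c1 - c0), bool)
        for (slr, slc), disk in stamps:
            sub[slr.start - r0:slr.stop - r0, slc.start - c0:slc.stop - c0] |= disk
        return (slice(r0, r1), slice(c0, c1)), sub, _stain_intensity()

    # cells before debris: the planted signal gets placement priority;
    # debris is best-effort (the canvas itself caps extreme junk draws)
    cell_mask, _ = _place(_make_cell, spec.n_single_cells, "single cells")
    speck_mask, n_specks = _place(_make_speck, spec.n_specks, "specks", strict=False)
    fragment_mask, n_fragments = _place(
        _make_fragment, spec.n_fragments, "fragments", strict=False
    )

    truth = dict(
        n_single_cells=int(spec.n_single_cells),
        n_clusters=int(spec.n_clusters),
        n_specks=int(n_specks),
        n_fragments=int(n_fragments),
        cell_mask=cell_mask,
        cluster_mask=cluster_mask,
        debris_mask=speck_mask | fragment_mask,
    )
    return GrayImage(img, spec.pixel_size_um), truth


# ---------------------------------------------------------------------------
# patient cohorts
# ---------------------------------------------------------------------------

def _d_for_auc(auc: float) -> float:
    """Standardized separation giving a binormal AUC of ``auc``."""
    return math.sqrt(2.0) * float(ndtri(auc))


@dataclass(frozen=True)
class CohortSimSpec:
    """Generating model of a synthetic patient cohort.

    ``effect_size_d`` is the standardized event/non-event difference of the
    per-patient latent log mean single-cell count; the generating AUC of the
    latent count is ``Phi(d/sqrt(2))`` (0.82 at the default d~1.295).
    Per-image counts are negative-binomial around the patient's latent mean
    (``nb_size -> inf`` recovers Poisson).  Event times are exponential with
    log-rate linear in the latent density; non-event follow-up is uniform on
    the study's observed window.
    """

    n_patients: int = 102
    n_events: int = 20
    images_per_patient: int = 5
    effect_size_d: float = _d_for_auc(0.82)
    baseline_mean_count: float = 6.0
    log_count_sd: float = 0.35
    nb_size: float = 20.0
    max_cells_per_image: int = 60
    # per-patient staining/sectioning scale: each patient's cell areas are
    # uniform on a +-halfwidth band around a patient-level centre (clipped to
    # the 20-60 px single-cell band), independent of outcome
    cell_area_center_range: tuple[float, float] = (26.0, 54.0)
    cell_area_halfwidth: float = 10.0
    # non-prognostic epithelial-content and staining-noise variation:
    # per-patient log-normal rates, per-image Poisson counts
    cluster_rate_mean: float = 3.5
    cluster_rate_logsd: float = 1.0
    max_clusters_per_image: int = 6
    speck_rate_mean: float = 18.0
    speck_rate_logsd: float = 1.0
    max_specks_per_image: int = 80
    fragment_rate_mean: float = 40.0
    fragment_rate_logsd: float = 1.0
    max_fragments_per_image: int = 120
    # per-patient fragmentation morphology: shifts the fragment chain stride
    # (hence mean fragment circularity/solidity) patient-wide, independent
    # of outcome
    fragment_elongation_range: tuple[float, float] = (0.0, 0.6)
    event_rate_loglinear: float = 0.5  # log-hazard slope per latent SD
    event_time_scale: float = 168.0
    event_time_range: tuple[float, float] = (6.0, 160.0)
    censor_range: tuple[float, float] = (77.0, 165.0)
    morphology: MorphologySpec = field(default_factory=MorphologySpec)

    def __post_init__(self) -> None:
        if self.effect_size_d < 0:
            raise ValueError("effect_size_d must be >= 0")
        if not 0 < self.n_events < self.n_patients:
            raise ValueError("need 0 < n_events < n_patients")
        if self.images_per_patient < 1:
            raise ValueError("need at least one image per patient")


@dataclass
class SimulatedCohort:
    """A generated cohort: patient table, per-patient images, ground truth."""

    table: pd.DataFrame
    images: dict[str, list[GrayImage]]
    spec: CohortSimSpec
    seed: int

    def write(self, out_dir) -> Path:
        """Write images (PNG) and the cohort CSV; returns the CSV path."""
        import imageio.v3 as iio

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        rows = []
        for _, rec in self.table.iterrows():
            pid = rec["patient_id"]
            paths = []
            for k, img in enumerate(self.images[pid]):
                p = out / "images" / f"{pid}_{k}.png"
                iio.imwrite(p, img.data)
                paths.append(str(p))
            row = rec.to_dict()
            row["image_paths"] = ";".join(paths)
            rows.append(row)
        cols = [
            "patient_id", "image_paths", "time_months", "event",
            "age", "tumor_size_mm", "grade", "er", "pr",
        ]
        df = pd.DataFrame(rows)
        csv_path = out / "cohort.csv"
        df[cols].to_csv(csv_path, index=False)
        return csv_path


def generate_cohort(
    spec: CohortSimSpec, seed: int, render_images: bool = True
) -> SimulatedCohort:
    """Draw a cohort with exactly ``n_events`` metastasis events.

    The returned table carries, per patient: outcome (``time_months``,
    ``event``), clinicopathological covariates, and the generating-model
    ground truth (``latent_mean_count``, ``true_mean_count`` = mean rendered
    single-cell count over the patient's images).
    """
    rng = np.random.default_rng(seed)
    n, k = spec.n_patients, spec.n_events

    event = np.zeros(n, dtype=int)
    event[rng.choice(n, size=k, replace=False)] = 1

    # latent log mean count: standardized z with class separation d
    z = rng.normal(0.0, 1.0, n) + spec.effect_size_d * event
    lam = spec.baseline_mean_count * np.exp(spec.log_count_sd * z)

    # per-image single-cell counts: negative binomial around the latent mean
    counts = np.empty((n, spec.images_per_patient), dtype=int)
    for i in range(n):
        if np.isfinite(spec.nb_size):
            p = spec.nb_size / (spec.nb_size + lam[i])
            counts[i] = rng.negative_binomial(spec.nb_size, p, spec.images_per_patient)
        else:
            counts[i] = rng.poisson(lam[i], spec.images_per_patient)
    counts = np.minimum(counts, spec.max_cells_per_image)

    # survival: exponential event times, log-rate linear in latent density
    zc = z - z.mean()
    t_event = spec.event_time_scale * rng.exponential(1.0, n) / np.exp(
        spec.event_rate_loglinear * zc
    )
    t_event = np.clip(t_event, *spec.event_time_range)
    t_censor = rng.uniform(*spec.censor_range, n)
    time = np.where(event == 1, t_event, t_censor)

    age = np.clip(np.rint(rng.normal(57, 9, n)), 37, 80).astype(int)
    tumor_size = np.clip(np.rint(rng.lognormal(np.log(18), 0.35, n)), 5, 50).astype(int)
    grade = rng.choice([1, 2], size=n, p=[0.4, 0.6])
    er = np.rint(rng.lognormal(np.log(20), 1.0, n)).astype(int)
    pr = np.rint(rng.lognormal(np.log(8), 1.0, n)).astype(int)

    pids = [f"P{i:04d}" for i in range(n)]
    table = pd.DataFrame(
        dict(
            patient_id=pids,
            time_months=np.round(time, 1),
            event=event,
            age=age,
            tumor_size_mm=tumor_size,
            grade=grade,
            er=er,
            pr=pr,
            latent_mean_count=lam,
            true_mean_count=counts.mean(axis=1),
        )
    )

    # non-prognostic variation in epithelial content and staining debris:
    # patients differ in cluster/debris density, independently of outcome
    def _lognormal_rate(mean, logsd):
        return mean * np.exp(rng.normal(0, logsd, n) - logsd**2 / 2)

    cluster_rate = _lognormal_rate(spec.cluster_rate_mean, spec.cluster_rate_logsd)
    speck_rate = _lognormal_rate(spec.speck_rate_mean, spec.speck_rate_logsd)
    fragment_rate = _lognormal_rate(spec.fragment_rate_mean, spec.fragment_rate_logsd)
    area_center = rng.uniform(*spec.cell_area_center_range, n)
    elongation = rng.uniform(*spec.fragment_elongation_range, n)

    images: dict[str, list[GrayImage]] = {}
    if render_images:
        from dataclasses import replace as _replace

        lo_band, hi_band = spec.morphology.cell_area_band
        for i, pid in enumerate(pids):
            band = (
                max(lo_band, area_center[i] - spec.cell_area_halfwidth),
                min(hi_band, area_center[i] + spec.cell_area_halfwidth),
            )
            imgs = []
            for j in range(spec.images_per_patient):
                mspec = _replace(
                    spec.morphology,
                    cell_area_band=band,
                    fragment_step_factor=(1.25 + 0.5 * elongation[i],
                                          1.65 + 0.5 * elongation[i]),
                    n_single_cells=int(counts[i, j]),
                    n_clusters=int(min(rng.poisson(cluster_rate[i]),
                                       spec.max_clusters_per_image)),
                    n_specks=int(min(rng.poisson(speck_rate[i]),
                                     spec.max_specks_per_image)),
                    n_fragments=int(min(rng.poisson(fragment_rate[i]),
                                        spec.max_fragments_per_image)),
                )
                img, _ = generate_tumor_image(mspec, rng)
                imgs.append(img)
            images[pid] = imgs
    return SimulatedCohort(table=table, images=images, spec=spec, seed=seed)
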