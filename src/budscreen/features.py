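"""Aggregation of filtered particles to image- and patient-level features.

Five features per filter subset: particle count, total stained area, average
particle size (total/count), mean circularity and mean solidity.  Images with
no retained particles contribute zeros to the size features but are excluded
from the shape-feature means (a "mean circularity" of an empty set is
missing, not zero); patient values are plain arithmetic means over images,
skipping missing entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .particles import Particle

__all__ = ["ImageFeatures", "FEATURE_NAMES", "image_features", "patient_features"]

#: Canonical feature order used in tables and screening records.
FEATURE_NAMES = ("count", "total_area", "average_size", "circularity", "solidity")


@dataclass(frozen=True)
class ImageFeatures:
    """Per-image summary of one filtered particle subset."""

    count: int
    total_area: float
    average_size: float
    mean_circularity: float  # NaN when count == 0
    mean_solidity: float     # NaN when count == 0

    def as_tuple(self) -> tuple:
        return (self.count, self.total_area, self.average_size,
                self.mean_circularity, self.mean_solidity)


def image_features(particles: list[Particle]) -> ImageFeatures:
    """Summarize one image's filtered particles.

    An empty list yields (0, 0, 0, NaN, NaN).
    """
    if not particles:
        return ImageFeatures(0, 0.0, 0.0, math.nan, math.nan)
    areas = [p.area_px for p in particles]
    total = float(sum(areas))
    return ImageFeatures(
        count=len(particles),
        total_area=total,
        average_size=total / len(particles),
        mean_circularity=float(np.mean([p.circularity for p in particles])),
        mean_solidity=float(np.mean([p.solidity for p in particles])),
    )


def patient_features(images: list[ImageFeatures]) -> dict[str, float]:
    """Average image features to one patient vector.

    Size features (count, total_area, average_size) average over all images;
    shape features skip missing (zero-particle) images and come back NaN if
    every image is missing.
    """
    if not images:
        raise ValueError("patient_features requires at least one image")
    arr = np.array([f.as_tuple() for f in images], dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(FEATURE_NAMES):
        col = arr[:, j]
        if name in ("circularity", "solidity"):
            valid = col[~np.isnan(col)]
            out[name] = float(valid.mean()) if valid.size else math.nan
        else:
            out[name] = float(col.mean())
    return out
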