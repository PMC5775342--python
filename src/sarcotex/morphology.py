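"""Per-cell size and shape metrics.

Definitions (evaluated on the segmented binary region, unweighted by
intensity):

* area — pixel count converted to μm² via the pixel size;
* elongation — major / minor axis length of the ellipse with the same second
  central moments as the region (≥ 1);
* circularity — 4π·Area/Perimeter², 1 for a perfect circle;
* eccentricity — focal distance / major axis length of the same-moments
  ellipse, 0 for a perfect circle.

The perimeter enters only through circularity and is the one genuinely
estimator-dependent quantity on a raster; the Crofton 4-direction estimator
is used because it is nearly unbiased on discs (naive chain-length counting
would push disc circularity well away from 1).  The estimator name is
recorded in :data:`PERIMETER_ESTIMATOR` and echoed into pipeline metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label, perimeter_crofton, regionprops

PERIMETER_ESTIMATOR = "crofton-4"


@dataclass(frozen=True)
class MorphologyMetrics:
    """Size/shape descriptors of one segmented cell."""

    area_um2: float
    elongation: float
    circularity: float
    eccentricity: float
    orientation_deg: float  # major-axis orientation, [0, 180), 0° = +x
    perimeter_um: float


def circularity(area: float, perimeter: float) -> float:
    """4π·Area/Perimeter² — exactly 1 for an ideal circle."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def eccentricity_from_axes(major: float, minor: float) -> float:
    """Focal distance over major axis: √(1 − (minor/major)²); 0 for a circle."""
    if not (0 < minor <= major):
        raise ValueError("axes must satisfy 0 < minor <= major")
    return math.sqrt(1.0 - (minor / major) ** 2)


def _orientation_deg(props) -> float:
    """Convert scikit-image's region orientation to the package convention.

    scikit-image measures the angle from the row axis to the major axis,
    counterclockwise in (row, col) coordinates, in (-pi/2, pi/2].  Because
    the row axis points down on screen, that sense is the mirror of the
    package convention (degrees in [0, 180), 0° along +x, counterclockwise
    on screen), hence the sign flip.
    """
    return (90.0 + math.degrees(props.orientation)) % 180.0


def compute_morphology(mask: np.ndarray, pixel_size_um: float) -> MorphologyMetrics:
    """Measure one connected, ≥16-pixel binary region.

    Raises ``ValueError`` for an empty or multi-component mask.
    """
    mask = np.asarray(mask, dtype=bool)
    lab = label(mask, connectivity=2)
    n = lab.max()
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        raise ValueError(f"mask has {n} connected components; expected exactly 1")
    props = regionprops(lab)[0]
    if props.area < 16:
        raise ValueError(f"mask area {props.area} px is below the 16-px minimum")

    perim_px = perimeter_crofton(mask, directions=4)
    major = props.axis_major_length
    minor = props.axis_minor_length
    if minor <= 0:  # degenerate (thin line) region
        minor = 1.0
        major = max(major, minor)
    return MorphologyMetrics(
        area_um2=float(props.area) * pixel_size_um**2,
        elongation=float(major / minor),
        circularity=circularity(float(props.area), float(perim_px)),
        eccentricity=float(props.eccentricity),
        orientation_deg=_orientation_deg(props),
        perimeter_um=float(perim_px) * pixel_size_um,
    )
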