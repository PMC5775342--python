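"""Pipeline configuration.

Every quantitative constant of the analysis is a configurable default here,
never hard-coded downstream.  The distance thresholds are stated in pixels at
the reference scale of 0.15625 μm/px (25 px ≡ 3.91 μm, 8 px ≡ 1.25 μm).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable parameters of the segmentation/texture pipeline.

    Attributes
    ----------
    pixel_size_um
        Physical pixel size (μm/px).
    bleed_ratio
        DAPI-to-(Nppa|Hcn4) intensity ratio above which a DAPI pixel is
        zeroed by the bleed-through correction.
    apply_bleed_correction
        Whether the batch pipeline runs that correction before nucleus
        detection.  Off by default: the ratio rule erases DAPI wherever the
        marker channels are dark, which destroys the nuclei of
        marker-negative cells unless the acquisition has strong marker
        bleed into DAPI.
    nppa_threshold, nppa_ring_px
        Perinuclear Nppa scoring: 90th-percentile intensity threshold and
        ring width in pixels.
    binucleate_px
        Maximum boundary-to-boundary distance for joining same-class nuclei.
    organization_threshold
        Sarcomere organization below which length/direction are suppressed.
    gaussian_radius_px, closing_radius_px, min_nucleus_area_px
        Nucleus-detection smoothing radius, closing structuring-element
        radius and small-object cutoff.
    gray_levels
        GLCM intensity bins (8 for grayscale, 2 for binary images).
    angle_step_deg, max_offset_px, interp_factor
        Resolution of the Haralick angle×offset surface and the sub-pixel
        interpolation factor of its per-angle traces.
    enclosure_fraction
        Fraction of nucleus pixels that must lie in a marker foreground to
        count as positive (1.0 = strict "fully within").
    """

    pixel_size_um: float = 0.15625
    bleed_ratio: float = 1.5
    apply_bleed_correction: bool = False
    nppa_threshold: float = 0.1
    nppa_ring_px: int = 8
    binucleate_px: float = 25.0
    organization_threshold: float = 0.1
    gaussian_radius_px: float = 4.0
    closing_radius_px: int = 3
    min_nucleus_area_px: int = 60
    gray_levels: int = 8
    angle_step_deg: float = 4.0
    max_offset_px: int = 40
    interp_factor: int = 8
    enclosure_fraction: float = 1.0
    compute_sota: bool = True
    compute_baselines: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um", "bleed_ratio", "nppa_threshold", "nppa_ring_px",
            "binucleate_px", "organization_threshold", "gaussian_radius_px",
            "min_nucleus_area_px", "gray_levels", "angle_step_deg",
            "max_offset_px", "interp_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.enclosure_fraction <= 1):
            raise ValueError("enclosure_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
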