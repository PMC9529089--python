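"""Processing parameters shared by the whole pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .errors import InvalidParameterError


@dataclass(frozen=True)
class GiftParameters:
    """User-tunable settings for one analysis run.

    Attributes
    ----------
    line_length_px
        Length (px) of the horizontal line structuring element used by the
        morphological opening. Longer lines demand straighter, more nearly
        horizontal edge segments. Default 8.
    threshold_percent
        Percent of image pixels retained as edge pixels after gradient
        thresholding; the cutoff adapts per image. Default 5.0 for
        micrographs; 1.0 is appropriate for binary synthetic images.
    angle_step_deg
        Step between rotated copies of the edge mask; 180/step copies are
        analyzed so fibers of every orientation present near-horizontal
        edges in some copy. Must divide 180 with quotient >= 2. Default 45
        (4 copies).
    bin_size
        Histogram bin width, in output units (um if a scale is given,
        otherwise px). Default 0.1.
    scale_px_per_um
        Pixels per micrometer. 1.0 means distances are reported in px.
    crop_height_px
        If set, keep only the top N rows (removes scale bars / banners).
    """

    line_length_px: int = 8
    threshold_percent: float = 5.0
    angle_step_deg: float = 45.0
    bin_size: float = 0.1
    scale_px_per_um: float = 1.0
    crop_height_px: int | None = None

    def __post_init__(self) -> None:
        if self.line_length_px < 1 or int(self.line_length_px) != self.line_length_px:
            raise InvalidParameterError(
                f"line_length_px must be a positive integer, got {self.line_length_px}"
            )
        if not (0.0 < self.threshold_percent <= 100.0):
            raise InvalidParameterError(
                f"threshold_percent must be in (0, 100], got {self.threshold_percent}"
            )
        n = 180.0 / self.angle_step_deg if self.angle_step_deg > 0 else float("nan")
        if not (0.0 < self.angle_step_deg <= 90.0) or not math.isclose(
            n, round(n), abs_tol=1e-9
        ):
            raise InvalidParameterError(
                "angle_step_deg must divide 180 with integer quotient >= 2, "
                f"got {self.angle_step_deg}"
            )
        if self.bin_size <= 0:
            raise InvalidParameterError(f"bin_size must be > 0, got {self.bin_size}")
        if self.scale_px_per_um <= 0:
            raise InvalidParameterError(
                f"scale_px_per_um must be > 0, got {self.scale_px_per_um}"
            )
        if self.crop_height_px is not None and self.crop_height_px < 1:
            raise InvalidParameterError(
                f"crop_height_px must be a positive integer, got {self.crop_height_px}"
            )

    @property
    def units(self) -> str:
        return "px" if self.scale_px_per_um == 1.0 else "um"

    def to_dict(self) -> dict:
        return asdict(self)
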