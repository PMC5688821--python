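"""Hue-threshold segmentation of a fruit-on-holder scene.

The scene is split into holder (dark blue), body (red), calyx (green) and
achene candidates (yellow-tan) purely by hue-range membership in HSV space,
with a minimum-saturation gate rejecting near-achromatic points. Strawberry
red straddles the 0 deg hue wrap, so hue intervals are circular and a
wraparound range (start > end) is first class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv as _sk_rgb2hsv

from .cloud_io import ColouredCloud


class SegmentationError(ValueError):
    """Raised when a segment required for calibration comes out empty."""


@dataclass(frozen=True)
class HueRange:
    """Half-open circular hue interval [start, end) in degrees.

    start > end means the interval wraps through 0 (e.g. strawberry red as
    [330, 30)). Half-open so adjacent windows sharing an endpoint stay
    disjoint.
    """

    start_deg: float
    end_deg: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_deg < 360 and 0 <= self.end_deg < 360):
            raise ValueError("hue bounds must lie in [0, 360)")

    def contains(self, hue_deg: np.ndarray) -> np.ndarray:
        h = np.asarray(hue_deg) % 360.0
        if self.start_deg <= self.end_deg:
            return (h >= self.start_deg) & (h < self.end_deg)
        return (h >= self.start_deg) | (h < self.end_deg)


@dataclass(frozen=True)
class SegmentationConfig:
    """Default hue windows match the rig's scene colours: dark-blue holder,
    red body, green calyx, yellow achene spots. All are configurable; the
    thresholds are deliberate choices, not measured constants."""

    holder_hue: HueRange = field(default_factory=lambda: HueRange(200.0, 260.0))
    calyx_hue: HueRange = field(default_factory=lambda: HueRange(70.0, 170.0))
    body_hue: HueRange = field(default_factory=lambda: HueRange(330.0, 30.0))
    achene_hue: HueRange = field(default_factory=lambda: HueRange(30.0, 70.0))
    min_saturation: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.min_saturation <= 1:
            raise ValueError("min_saturation must be in [0, 1]")
        ranges = [self.holder_hue, self.calyx_hue, self.body_hue, self.achene_hue]
        probe = np.arange(0.0, 360.0, 0.25)
        hits = sum(r.contains(probe).astype(int) for r in ranges)
        if hits.max() > 1:
            raise ValueError("hue ranges must be pairwise disjoint")


@dataclass
class SegmentedSample:
    """The five-way partition of one scene cloud."""

    holder: ColouredCloud
    body: ColouredCloud
    calyx: ColouredCloud
    achene_candidates: ColouredCloud
    unassigned: ColouredCloud

    @property
    def total_points(self) -> int:
        return (
            len(self.holder)
            + len(self.body)
            + len(self.calyx)
            + len(self.achene_candidates)
            + len(self.unassigned)
        )


def rgb_to_hsv(colors: np.ndarray) -> np.ndarray:
    """Convert RGB in [0,1] to (hue deg in [0,360), saturation, value).

    Standard hexcone model; achromatic colours (S = 0) get hue 0. Accepts a
    single triple or an (n, 3) array.
    """
    rgb = np.asarray(colors, dtype=np.float64)
    single = rgb.ndim == 1
    rgb = np.atleast_2d(rgb)
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("RGB channels must lie in [0, 1]")
    hsv = _sk_rgb2hsv(rgb)
    hsv[:, 0] = (hsv[:, 0] * 360.0) % 360.0
    return hsv[0] if single else hsv


def segment(
    cloud: ColouredCloud, config: SegmentationConfig | None = None
) -> SegmentedSample:
    """Partition a scene cloud into holder/body/calyx/achenes/unassigned.

    Achene hue takes precedence over body hue (achene spots sit on the body
    surface); points below ``min_saturation`` or outside every window are
    unassigned. Raises :class:`SegmentationError` when the holder or body
    segment is empty, because calibration and sizing are then impossible.
    """
    if config is None:
        config = SegmentationConfig()
    if len(cloud) == 0:
        raise SegmentationError("empty input cloud")
    hsv = rgb_to_hsv(cloud.colors)
    hue, sat = hsv[:, 0], hsv[:, 1]
    saturated = sat >= config.min_saturation

    masks = {}
    taken = ~saturated
    # achene window first: those points would otherwise match nothing or body
    for name, hue_range in (
        ("achene_candidates", config.achene_hue),
        ("body", config.body_hue),
        ("holder", config.holder_hue),
        ("calyx", config.calyx_hue),
    ):
        m = hue_range.contains(hue) & ~taken
        masks[name] = m
        taken = taken | m
    masks["unassigned"] = ~(
        masks["holder"] | masks["body"] | masks["calyx"] | masks["achene_candidates"]
    )

    sample = SegmentedSample(
        holder=cloud.subset(masks["holder"]),
        body=cloud.subset(masks["body"]),
        calyx=cloud.subset(masks["calyx"]),
        achene_candidates=cloud.subset(masks["achene_candidates"]),
        unassigned=cloud.subset(masks["unassigned"]),
    )
    if len(sample.holder) == 0:
        raise SegmentationError("empty holder segment: cannot calibrate scale")
    if len(sample.body) == 0:
        raise SegmentationError("empty body segment: no fruit found")
    return sample
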