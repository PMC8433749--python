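"""Intensity-profile segmentation and measurement-ROI selection.

The tube's reinforcement ribs cast static vertical shadow artifacts whose
horizontal position depends on how the tube was inserted into the sensor
and cannot be controlled — but since the tube does not move during an
irrigation, the artifacts are static and can be excluded once, at setup
time. This module inspects a horizontal intensity profile, labels columns
as background / transitional / artifact / measurement, and places the
measurement ROI in the widest artifact-free stretch.

All medians (rather than means) throughout, for robustness to hot pixels
and residual speckle. Columns are 0-based; intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoValidROIError, UnusableFrameError
from .simulate import DARK_LEVEL, IlluminationGeometry, SensorFrame

__all__ = [
    "IntensityProfile",
    "RegionSegmentation",
    "ROISpec",
    "extract_profile",
    "segment_profile",
    "select_roi",
    "setup_roi",
    "roi_reading",
    "default_row_band",
]

#: Columns shaved off each side of the chosen interval, guarding against
#: artifact tails that fall just under the detection threshold.
GUARD_COLS = 2


def default_row_band(height: int) -> tuple[int, int]:
    """Central 50% of rows — avoids tube-wall curvature at top/bottom."""
    return (height // 4, height - height // 4)


@dataclass(frozen=True)
class IntensityProfile:
    """Per-column robust intensity summary of one frame."""

    values: np.ndarray
    source_timestamp: float | None = None

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RegionSegmentation:
    """Ordered labeled column intervals (half-open, 0-based).

    Labels: ``background`` and ``transitional`` are copied from the fixed
    assembly geometry; within the illuminated interval, ``artifact``
    columns deviate from the robust baseline and ``measurement`` columns
    do not.
    """

    intervals: tuple[tuple[int, int, str], ...]
    baseline: float

    def by_label(self, label: str) -> list[tuple[int, int]]:
        return [(a, b) for a, b, lab in self.intervals if lab == label]


@dataclass(frozen=True)
class ROISpec:
    """The measurement region: a column interval times a row band."""

    col_start: int
    col_stop: int
    row_start: int
    row_stop: int

    def __post_init__(self) -> None:
        if self.col_start >= self.col_stop or self.row_start >= self.row_stop:
            raise ValueError("ROI intervals must be non-empty")

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start


def extract_profile(
    frame: SensorFrame, row_band: tuple[int, int] | None = None
) -> IntensityProfile:
    """Per-column median over a row band (default: central 50% of rows)."""
    pixels = np.asarray(frame.pixels, dtype=float)
    h = pixels.shape[0]
    r0, r1 = row_band if row_band is not None else default_row_band(h)
    if not (0 <= r0 < r1 <= h):
        raise ValueError(f"row band ({r0}, {r1}) invalid for height {h}")
    values = np.median(pixels[r0:r1, :], axis=0)
    return IntensityProfile(values=values, source_timestamp=frame.timestamp)


def segment_profile(
    profile: IntensityProfile,
    geometry: IlluminationGeometry,
    deviation_threshold: float = 0.05,
) -> RegionSegmentation:
    """Label the profile's columns.

    Within the illuminated interval the baseline is the median of the
    illuminated columns; any column whose relative deviation from that
    baseline exceeds ``deviation_threshold`` is an artifact, and maximal
    runs of the remaining columns are measurement intervals. Because the
    baseline is relative, the segmentation is independent of the current
    concentration.

    Raises
    ------
    UnusableFrameError
        If the illuminated baseline does not rise above the dark level
        (LED off, tube blocked, or sensor mispositioned).
    """
    if len(profile) != geometry.width:
        raise ValueError("profile length does not match geometry width")
    lo, hi = geometry.illuminated_cols
    ill = profile.values[lo:hi]
    baseline = float(np.median(ill))
    if baseline <= DARK_LEVEL:
        raise UnusableFrameError(
            f"illuminated baseline {baseline:.1f} not above dark level"
        )
    artifact_mask = np.abs(ill / baseline - 1.0) > deviation_threshold

    intervals: list[tuple[int, int, str]] = []
    (bl, tl, tr, br) = (
        geometry.background_cols[0],
        geometry.transitional_cols[0],
        geometry.transitional_cols[1],
        geometry.background_cols[1],
    )
    intervals.append((*bl, "background"))
    intervals.append((*tl, "transitional"))
    # maximal runs inside the illuminated interval
    start = 0
    for i in range(1, hi - lo + 1):
        if i == hi - lo or artifact_mask[i] != artifact_mask[start]:
            label = "artifact" if artifact_mask[start] else "measurement"
            intervals.append((lo + start, lo + i, label))
            start = i
    intervals.append((*tr, "transitional"))
    intervals.append((*br, "background"))
    return RegionSegmentation(intervals=tuple(intervals), baseline=baseline)


def select_roi(
    seg: RegionSegmentation,
    min_width: int = 8,
    frame_height: int = 120,
    row_band: tuple[int, int] | None = None,
) -> ROISpec:
    """Place the ROI in the widest measurement interval.

    The chosen interval is shrunk by a guard of 2 columns on each side;
    ties are broken leftmost. Fails if no interval survives with at least
    ``min_width`` columns — the sensor must be repositioned on the tube.
    """
    candidates = seg.by_label("measurement")
    best: tuple[int, int] | None = None
    for a, b in candidates:
        if best is None or (b - a) > (best[1] - best[0]):
            best = (a, b)
    if best is None:
        raise NoValidROIError("no measurement interval found")
    a, b = best[0] + GUARD_COLS, best[1] - GUARD_COLS
    if b - a < min_width:
        raise NoValidROIError(
            f"widest artifact-free interval ({b - a} cols after guards) "
            f"narrower than min_width={min_width}"
        )
    r0, r1 = row_band if row_band is not None else default_row_band(frame_height)
    return ROISpec(col_start=a, col_stop=b, row_start=r0, row_stop=r1)


def setup_roi(scenario, min_width: int = 8) -> ROISpec:
    """Setup-time ROI selection, as performed once when the sensor is
    mounted: a clear-fluid (c = 0), noiseless, low-exposure reference
    frame of the scenario's geometry and ribs is segmented and the ROI
    placed in its widest artifact-free stretch. Because the ribs are
    static, the ROI remains valid for the entire acquisition."""
    import dataclasses

    from .simulate import NOISELESS, render_frame

    ref_scenario = dataclasses.replace(
        scenario, concentration=lambda t: 0.0, bubbles=(), noise=NOISELESS
    )
    frame = render_frame(ref_scenario, 0.0, "low")
    profile = extract_profile(frame)
    seg = segment_profile(profile, scenario.geometry)
    return select_roi(seg, min_width=min_width, frame_height=scenario.geometry.height)


def roi_reading(frame: SensorFrame, roi: ROISpec) -> float:
    """The per-frame scalar: median of the ROI pixels, real-valued."""
    pixels = np.asarray(frame.pixels, dtype=float)
    h, w = pixels.shape
    if roi.col_stop > w or roi.row_stop > h:
        raise ValueError("ROI exceeds frame bounds")
    block = pixels[roi.row_start : roi.row_stop, roi.col_start : roi.col_stop]
    if block.size == 0:
        raise ValueError("empty ROI")
    return float(np.median(block))
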