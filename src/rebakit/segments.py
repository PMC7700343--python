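"""Body segments, joint ranges and the percent-of-range <-> degrees mapping.

Digital-human-model software of the Anthropos family reports joint
configurations as signed percentages of each joint's maximal anatomical
range rather than in degrees.  The maximal ranges used here are the unique
constants that make the published percent and degree band boundaries
coincide (11 % <-> 20 deg, 25 % <-> 45 deg, 50 % <-> 90 deg for the upper
arm; 50 % <-> 60 deg and 83 % <-> 100 deg for the lower arm; 25 % <-> 15 deg
for the wrist).  They can be overridden for other skeleton conventions.
"""

from __future__ import annotations

import enum


class Segment(str, enum.Enum):
    """Body segments scored by REBA, split into group B (arm chain) and group A."""

    UPPER_ARM = "upper_arm"
    LOWER_ARM = "lower_arm"
    WRIST = "wrist"
    TRUNK = "trunk"
    NECK = "neck"
    LEGS = "legs"


#: Group B segments, expressed by DHM software as percent of maximal range.
ARM_SEGMENTS = (Segment.UPPER_ARM, Segment.LOWER_ARM, Segment.WRIST)

#: Maximal joint range in degrees per arm segment (full scale = 100 %).
MAX_RANGE_DEG: dict[Segment, float] = {
    Segment.UPPER_ARM: 180.0,
    Segment.LOWER_ARM: 120.0,
    Segment.WRIST: 60.0,
}


class SegmentError(ValueError):
    """A segment/operation mismatch or an out-of-domain posture value."""


def percent_to_degrees(
    segment: Segment | str,
    percent: float,
    ranges: dict[Segment, float] | None = None,
) -> float:
    """Convert a signed percent-of-range posture indicator to degrees.

    Parameters
    ----------
    segment:
        One of the arm-chain segments (``upper_arm``, ``lower_arm``, ``wrist``).
    percent:
        Signed percentage of the segment's maximal range; flexion positive,
        extension negative.  Must satisfy ``|percent| <= 100``.
    ranges:
        Optional override of the maximal ranges (degrees per segment).

    Returns
    -------
    float
        The joint angle in degrees: ``percent / 100 * maximal_range``.
    """
    segment = Segment(segment)
    if segment not in ARM_SEGMENTS:
        raise SegmentError(
            f"percent-of-range conversion is defined for arm segments, not {segment.value!r}"
        )
    if abs(percent) > 100.0:
        raise SegmentError(f"|percent| must be <= 100, got {percent}")
    max_range = (ranges or MAX_RANGE_DEG)[segment]
    return percent / 100.0 * max_range


def degrees_to_percent(
    segment: Segment | str,
    degrees: float,
    ranges: dict[Segment, float] | None = None,
) -> float:
    """Inverse of :func:`percent_to_degrees`; exact round-trip by construction."""
    segment = Segment(segment)
    if segment not in ARM_SEGMENTS:
        raise SegmentError(
            f"percent-of-range conversion is defined for arm segments, not {segment.value!r}"
        )
    max_range = (ranges or MAX_RANGE_DEG)[segment]
    percent = degrees / max_range * 100.0
    if abs(percent) > 100.0 + 1e-9:
        raise SegmentError(
            f"{degrees} deg exceeds the {segment.value} maximal range of {max_range} deg"
        )
    return percent
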