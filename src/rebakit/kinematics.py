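"""Sagittal-plane arm chain: forward kinematics and minimum-code reaching.

The arm is a three-link planar chain (upper arm, forearm, hand) anchored at
the shoulder.  Flexion angles are cumulative: the upper arm's is measured
from the hanging vertical, the elbow's from the upper-arm axis and the
wrist's from the forearm axis, so a link whose cumulative flexion is ``phi``
points along ``(sin phi, -cos phi)``.  Postures are simulated in the
sagittal plane only, matching how DHM reach studies report one signed
indicator per arm segment.

Reaching a work point is deliberately underdetermined (the chain has three
joints for a two-dimensional target), so the chain is configured by the
rule that the hand lands on the target while the REBA partial codes of the
segments are lexicographically minimal (upper arm first, then lower arm,
then wrist); ties are broken by the smallest total angular deviation from
the neutral hanging posture, then by fixed grid order.  A sum-of-codes
objective is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import Mannequin
from .scoring import SegmentPosture, lower_arm_code, upper_arm_code, wrist_code
from .segments import MAX_RANGE_DEG, Segment, SegmentError

#: IK search ranges in degrees (flexion side of each joint; wrist symmetric).
JOINT_GRID_LIMITS = {
    "upper_arm": (0.0, 180.0),
    "elbow": (0.0, 120.0),
    "wrist": (-60.0, 60.0),
}


class ReachabilityError(ValueError):
    """The work point cannot be reached by the mannequin's arm chain."""


@dataclass(frozen=True)
class ArmPosture:
    """Joint angles of the planar arm chain, degrees of flexion."""

    upper_arm_flexion: float
    elbow_flexion: float
    wrist_flexion: float

    def __post_init__(self) -> None:
        for value, seg in (
            (self.upper_arm_flexion, Segment.UPPER_ARM),
            (self.elbow_flexion, Segment.LOWER_ARM),
            (self.wrist_flexion, Segment.WRIST),
        ):
            if abs(value) > MAX_RANGE_DEG[seg]:
                raise SegmentError(
                    f"{seg.value} angle {value} deg outside its maximal range "
                    f"of +/-{MAX_RANGE_DEG[seg]} deg"
                )

    def segment_postures(self) -> tuple[SegmentPosture, SegmentPosture, SegmentPosture]:
        return (
            SegmentPosture(Segment.UPPER_ARM, angle_deg=self.upper_arm_flexion),
            SegmentPosture(Segment.LOWER_ARM, angle_deg=self.elbow_flexion),
            SegmentPosture(Segment.WRIST, angle_deg=self.wrist_flexion),
        )

    def partial_codes(self) -> tuple[int, int, int]:
        ua, la, wr = self.segment_postures()
        return (upper_arm_code(ua), lower_arm_code(la), wrist_code(wr))

    def to_dict(self) -> dict:
        return {
            "upper_arm_flexion_deg": self.upper_arm_flexion,
            "elbow_flexion_deg": self.elbow_flexion,
            "wrist_flexion_deg": self.wrist_flexion,
        }


@dataclass(frozen=True)
class WorkPoint:
    """A reach target: horizontal offset from the shoulder vertical, height above floor (mm)."""

    horizontal_offset: float
    height: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise SegmentError(f"work-point height must be >= 0 mm, got {self.height}")


def _chain_xy(mannequin: Mannequin, ua, el, wr):
    """Hand position for (arrays of) joint angles in degrees."""
    a1 = np.deg2rad(ua)
    a2 = a1 + np.deg2rad(el)
    a3 = a2 + np.deg2rad(wr)
    x = mannequin.upper_arm * np.sin(a1) + mannequin.forearm * np.sin(a2) + mannequin.hand * np.sin(a3)
    y = mannequin.shoulder_height - (
        mannequin.upper_arm * np.cos(a1) + mannequin.forearm * np.cos(a2) + mannequin.hand * np.cos(a3)
    )
    return x, y


def forward(mannequin: Mannequin, posture: ArmPosture) -> tuple[tuple[float, float], float]:
    """Forward kinematics: hand position (mm) and eye-to-hand distance (mm).

    The shoulder sits at ``(0, shoulder_height)`` and the eye at
    ``(0, eye_height)`` on the mannequin's vertical axis.
    """
    x, y = _chain_xy(
        mannequin, posture.upper_arm_flexion, posture.elbow_flexion, posture.wrist_flexion
    )
    eye_to_hand = float(np.hypot(x - 0.0, y - mannequin.eye_height))
    return (float(x), float(y)), eye_to_hand


def max_reach(mannequin: Mannequin) -> float:
    """Total arm-chain length (mm): the outer radius of the reachable annulus."""
    return mannequin.upper_arm + mannequin.forearm + mannequin.hand


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def reach_min_reba(
    mannequin: Mannequin,
    target: WorkPoint,
    tol: float = 10.0,
    resolution: float = 1.0,
    objective: str = "lexicographic",
) -> ArmPosture:
    """Reach a work point with lexicographically minimal REBA partial codes.

    Grid-searches joint angles at ``resolution`` degrees; among postures
    whose hand lands within ``tol`` mm of the target, returns the one whose
    code vector (upper arm, lower arm, wrist) is minimal - lexicographically
    by default, by total sum with ``objective="sum"`` - breaking ties by the
    smallest total absolute angular deviation from neutral, then grid order.

    Raises
    ------
    ReachabilityError
        If no grid posture lands within ``tol`` of the target; the message
        names the mannequin's maximal reach.
    """
    if objective not in ("lexicographic", "sum"):
        raise ValueError(f"unknown objective {objective!r}")
    ua = _grid(*JOINT_GRID_LIMITS["upper_arm"], resolution)
    el = _grid(*JOINT_GRID_LIMITS["elbow"], resolution)
    wr = _grid(*JOINT_GRID_LIMITS["wrist"], resolution)

    UA, EL, WR = np.meshgrid(ua, el, wr, indexing="ij", sparse=True)
    x, y = _chain_xy(mannequin, UA, EL, WR)
    d2 = (x - target.horizontal_offset) ** 2 + (y - target.height) ** 2
    hit = d2 <= tol * tol
    if not hit.any():
        reach = max_reach(mannequin)
        dist = float(np.hypot(target.horizontal_offset, target.height - mannequin.shoulder_height))
        raise ReachabilityError(
            f"work point ({target.horizontal_offset:.0f}, {target.height:.0f}) mm is not "
            f"reachable within {tol:g} mm: shoulder-to-target distance {dist:.0f} mm, "
            f"maximal reach {reach:.0f} mm"
        )

    iua, iel, iwr = np.nonzero(hit)
    cand_ua, cand_el, cand_wr = ua[iua], el[iel], wr[iwr]
    codes = np.empty((3, cand_ua.size), dtype=np.int64)
    # vectorised Table 1 band coding of the candidate angles
    p_ua = cand_ua / MAX_RANGE_DEG[Segment.UPPER_ARM] * 100.0
    codes[0] = np.select([p_ua <= 11, p_ua <= 25, p_ua <= 50], [1, 2, 3], default=4)
    p_el = cand_el / MAX_RANGE_DEG[Segment.LOWER_ARM] * 100.0
    codes[1] = np.where((p_el >= 50) & (p_el <= 83), 1, 2)
    p_wr = np.abs(cand_wr) / MAX_RANGE_DEG[Segment.WRIST] * 100.0
    codes[2] = np.where(p_wr <= 25, 1, 2)

    deviation = np.abs(cand_ua) + np.abs(cand_el) + np.abs(cand_wr)
    grid_order = np.ravel_multi_index((iua, iel, iwr), (ua.size, el.size, wr.size))
    if objective == "sum":
        order = np.lexsort((grid_order, deviation, codes.sum(axis=0)))
    else:
        order = np.lexsort((grid_order, deviation, codes[2], codes[1], codes[0]))
    best = order[0]
    return ArmPosture(float(cand_ua[best]), float(cand_el[best]), float(cand_wr[best]))
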