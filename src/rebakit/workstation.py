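"""Workstation assessment and worksurface-height design strategies.

A workstation is reduced to the geometry that drives arm posture: the
work point (where the hands act) at a horizontal offset from the operator
and a height above the floor, tied to the work-surface or tool-holder
height.  Assessment places a mannequin at the station, solves the reach
posture under the minimum-partial-code rule and scores it with the
standing-manual REBA workflow.

Height correction follows the anchor-mannequin procedure: the anchor
mannequin first adopts an arm configuration inside the code-1 bands of
every segment (with the upper arm either at the centre of its optimal
band or at the 11 %-of-range border) whose hand lies on the work point's
horizontal offset; the work-point height is then set to that hand height.
Design strategies differ only in the anchor: the population's 50th
percentile individual (design for the average), or the 5th-percentile
female boundary mannequin (design for the smallest, optionally at the
band border - the most sensitive REBA setting).  Every strategy is
validated by re-assessing both boundary mannequins, including the
eye-to-work-point viewing distance against the 50-70 cm reading band.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .anthropometry import Mannequin, Population, Sex, boundary_pair, build_mannequin
from .kinematics import ArmPosture, ReachabilityError, WorkPoint, forward, reach_min_reba
from .scoring import ActivityContext, PostureB, RebaResult, assess_standing_manual
from .segments import MAX_RANGE_DEG, Segment

#: Recommended eye-to-object distance band for visual information that
#: requires reading, in millimetres.
DEFAULT_VIEWING_BAND = (500.0, 700.0)


class Strategy(str, enum.Enum):
    AS_IS = "as_is"
    ANCHOR_P50 = "anchor_p50"
    ANCHOR_P5 = "anchor_p5"
    BOUNDARY = "boundary"


class Anchor(str, enum.Enum):
    """How the anchor mannequin's upper arm is placed inside its optimal band."""

    OPTIMAL_CENTER = "optimal_center"
    OPTIMAL_BOUNDARY = "optimal_boundary"


class WorkstationConfigError(ValueError):
    """Invalid workstation specification or a non-adjustable adjustment."""


@dataclass(frozen=True)
class Workstation:
    """Parametric workstation geometry, millimetres."""

    name: str
    surface_height: float
    work_point: WorkPoint
    adjustable: frozenset[str] = field(default_factory=lambda: frozenset({"surface_height"}))

    def __post_init__(self) -> None:
        if self.surface_height < 0:
            raise WorkstationConfigError(
                f"surface_height must be >= 0 mm, got {self.surface_height}"
            )
        bad = set(self.adjustable) - {"surface_height", "tool_height"}
        if bad:
            raise WorkstationConfigError(f"unknown adjustable dimensions: {sorted(bad)}")
        object.__setattr__(self, "adjustable", frozenset(self.adjustable))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "surface_height_mm": self.surface_height,
            "work_point": {
                "horizontal_offset_mm": self.work_point.horizontal_offset,
                "height_mm": self.work_point.height,
            },
            "adjustable": sorted(self.adjustable),
        }


@dataclass(frozen=True)
class Assessment:
    """Outcome of placing one mannequin at one workstation."""

    mannequin: Mannequin
    posture: ArmPosture
    reba: RebaResult
    hand_position: tuple[float, float]
    eye_to_hand: float

    def to_dict(self) -> dict:
        return {
            "mannequin": self.mannequin.to_dict(),
            "posture": self.posture.to_dict(),
            "reba": self.reba.to_dict(),
            "hand_position_mm": list(self.hand_position),
            "eye_to_hand_mm": self.eye_to_hand,
        }


@dataclass(frozen=True)
class DesignEntry:
    """Per-mannequin validation row of a design strategy."""

    mannequin_id: str
    reba: RebaResult
    eye_to_hand: float
    viewing_ok: bool
    below_viewing_band: bool

    def to_dict(self) -> dict:
        return {
            "mannequin": self.mannequin_id,
            "reba": self.reba.to_dict(),
            "eye_to_hand_mm": self.eye_to_hand,
            "viewing_ok": self.viewing_ok,
            "below_viewing_band": self.below_viewing_band,
        }


@dataclass(frozen=True)
class DesignReport:
    """One strategy's redesigned workstation and its boundary-mannequin validation."""

    strategy: Strategy
    workstation: Workstation
    height_change: float
    entries: tuple[DesignEntry, ...]

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy.value,
            "workstation": self.workstation.to_dict(),
            "height_change_mm": self.height_change,
            "entries": [e.to_dict() for e in self.entries],
        }


def viewing_distance_check(
    eye_to_hand: float, band: tuple[float, float] = DEFAULT_VIEWING_BAND
) -> bool:
    """True iff the eye-to-object distance does not exceed the band maximum.

    Only the upper bound fails the check: too-large distances degrade the
    reading of visual information, whereas distances below the band are
    reported as a note but accepted.
    """
    lo, hi = band
    if not lo < hi:
        raise WorkstationConfigError(f"viewing band must satisfy min < max, got {band}")
    return eye_to_hand <= hi


def assess_workstation(
    mannequin: Mannequin,
    ws: Workstation,
    activity: ActivityContext = ActivityContext(static_hold=True),
    posture_override: PostureB | None = None,
    tol: float = 10.0,
    resolution: float = 1.0,
) -> Assessment:
    """Assess one mannequin at a workstation.

    The reach posture is solved by :func:`rebakit.kinematics.reach_min_reba`
    unless ``posture_override`` supplies the segment indicators directly
    (e.g. to score posture readouts from external DHM software); the
    override bypasses the chain and scores the given percentages.
    """
    if posture_override is not None:
        reba = assess_standing_manual(posture_override, activity=activity)
        posture = ArmPosture(
            posture_override.upper_arm.degrees,
            posture_override.lower_arm.degrees,
            posture_override.wrist.degrees,
        )
    else:
        try:
            posture = reach_min_reba(mannequin, ws.work_point, tol=tol, resolution=resolution)
        except ReachabilityError as err:
            raise ReachabilityError(f"[{mannequin.label} @ {ws.name}] {err}") from err
        reba = assess_standing_manual(
            PostureB.from_degrees(
                posture.upper_arm_flexion, posture.elbow_flexion, posture.wrist_flexion
            ),
            activity=activity,
        )
    hand, eye_to_hand = forward(mannequin, posture)
    return Assessment(mannequin, posture, reba, hand, eye_to_hand)


def anchor_posture(anchor: Anchor) -> ArmPosture:
    """The canonical code-1-band posture used to anchor a work-surface height.

    Every segment sits inside its optimal (code-1) band: the elbow at the
    centre of its 50-83 % band, the wrist neutral, and the upper arm either
    at the centre of its sub-11 % band (``optimal_center``) or right at the
    11 %-of-range border (``optimal_boundary``, the highest hand position
    that still keeps the most score-sensitive segment at code 1).  The
    angles are posture constants; the mannequin's stature turns them into
    a hand height.
    """
    ua_range = MAX_RANGE_DEG[Segment.UPPER_ARM]
    el_range = MAX_RANGE_DEG[Segment.LOWER_ARM]
    ua_pct = 5.5 if anchor is Anchor.OPTIMAL_CENTER else 11.0
    el_pct = (50.0 + 83.0) / 2.0
    return ArmPosture(
        upper_arm_flexion=ua_pct / 100.0 * ua_range,
        elbow_flexion=el_pct / 100.0 * el_range,
        wrist_flexion=0.0,
    )


def optimize_height(
    mannequin: Mannequin,
    ws: Workstation,
    anchor: Anchor = Anchor.OPTIMAL_CENTER,
) -> Workstation:
    """Set the work-point height to the anchor mannequin's optimal hand height.

    The mannequin adopts the code-1-band posture of :func:`anchor_posture`;
    the returned copy has its work point (and the surface height tied to
    it) moved to that posture's hand height.  The operation is a fixed
    point: optimizing an already-optimized station changes nothing.
    """
    if not ws.adjustable:
        raise WorkstationConfigError(
            f"workstation {ws.name!r} has no adjustable dimension"
        )
    posture = anchor_posture(anchor)
    (_, hand_y), _ = forward(mannequin, posture)
    delta = hand_y - ws.work_point.height
    return replace(
        ws,
        surface_height=max(0.0, ws.surface_height + delta),
        work_point=WorkPoint(ws.work_point.horizontal_offset, hand_y),
    )


def compare_strategies(
    population: Population,
    ws: Workstation,
    activity: ActivityContext = ActivityContext(static_hold=True),
    viewing_band: tuple[float, float] = DEFAULT_VIEWING_BAND,
    p50_mode: str = "combined",
) -> list[DesignReport]:
    """Evaluate the height-design strategies, each validated on the boundary pair.

    Strategies: ``as_is`` (no change); ``anchor_p50`` (height anchored to
    the population's 50th-percentile individual, upper arm at band centre);
    ``anchor_p5`` (anchored to the 5th-percentile female with the upper arm
    at the 11 % border - the REBA-sensitivity design); ``boundary``
    (anchored to the 5th-percentile female at band centre, the classic
    design-for-the-smallest).  ``p50_mode`` selects the combined-sex
    mixture median (default) or a per-sex 50th percentile.
    """
    p5f, p95m = boundary_pair(population)
    p50 = build_mannequin(population, Sex(p50_mode) if p50_mode != "combined" else Sex.COMBINED, 50.0)

    plans: list[tuple[Strategy, Mannequin | None, Anchor]] = [
        (Strategy.AS_IS, None, Anchor.OPTIMAL_CENTER),
        (Strategy.ANCHOR_P50, p50, Anchor.OPTIMAL_CENTER),
        (Strategy.ANCHOR_P5, p5f, Anchor.OPTIMAL_BOUNDARY),
        (Strategy.BOUNDARY, p5f, Anchor.OPTIMAL_CENTER),
    ]
    reports: list[DesignReport] = []
    for strategy, anchor_mannequin, anchor in plans:
        station = ws if anchor_mannequin is None else optimize_height(anchor_mannequin, ws, anchor)
        entries = []
        for m in (p5f, p95m):
            result = assess_workstation(m, station, activity)
            ok = viewing_distance_check(result.eye_to_hand, viewing_band)
            entries.append(
                DesignEntry(
                    mannequin_id=m.label,
                    reba=result.reba,
                    eye_to_hand=result.eye_to_hand,
                    viewing_ok=ok,
                    below_viewing_band=result.eye_to_hand < viewing_band[0],
                )
            )
        reports.append(
            DesignReport(
                strategy=strategy,
                workstation=station,
                height_change=station.work_point.height - ws.work_point.height,
                entries=tuple(entries),
            )
        )
    return reports
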