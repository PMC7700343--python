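"""Table-driven REBA scoring of working postures.

REBA (Rapid Entire Body Assessment) assigns a small integer code to each
body segment from its deviation band, combines group A (trunk, neck, legs)
and group B (upper arm, lower arm, wrist) codes through lookup tables,
crosses the two group scores in a third table, and adds activity increments
(+1 for static work, i.e. any segment held in the same position for at
least one minute).  The final score maps to one of five risk categories.

For standing, unforced manual work the group A score is always 1 (neutral
trunk and stable legs; even an extreme sagittal head tilt, neck code 2,
leaves the Table A cell at 1), so the risk is governed entirely by the arm
chain; :func:`assess_standing_manual` implements that simplified workflow.

Group B postures may be given either in degrees or as the signed
percent-of-range indicators produced by digital-human-model software; the
band boundaries below are calibrated so the two forms agree (see
:mod:`rebakit.segments`).  Percent bands are closed on the right
(11 % -> code 1, 25 % -> code 2, 50 % -> code 3) and the lower-arm optimum
band is closed on both ends (50-83 % -> code 1).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .segments import (
    ARM_SEGMENTS,
    MAX_RANGE_DEG,
    Segment,
    SegmentError,
    degrees_to_percent,
    percent_to_degrees,
)
from .tables import table_a, table_b, table_c


class Coupling(str, enum.Enum):
    """Hand-hold quality, adding 0-3 to the group B score."""

    GOOD = "good"
    FAIR = "fair"
    POOR = "poor"
    UNACCEPTABLE = "unacceptable"


COUPLING_SCORE = {
    Coupling.GOOD: 0,
    Coupling.FAIR: 1,
    Coupling.POOR: 2,
    Coupling.UNACCEPTABLE: 3,
}

#: Posture-adjustment flags admissible per segment.
SEGMENT_FLAGS: dict[Segment, frozenset[str]] = {
    Segment.UPPER_ARM: frozenset({"shoulder_raised", "arm_abducted", "arm_supported"}),
    Segment.LOWER_ARM: frozenset(),
    Segment.WRIST: frozenset({"wrist_deviated_or_twisted"}),
    Segment.TRUNK: frozenset({"trunk_twisted_or_side_flexed"}),
    Segment.NECK: frozenset({"neck_twisted_or_side_flexed"}),
    Segment.LEGS: frozenset({"legs_unstable", "knee_flex_30_60", "knee_flex_gt_60"}),
}

RISK_LABELS = {
    1: "negligible",
    2: "low",
    3: "medium",
    4: "high",
    5: "very high",
}


@dataclass(frozen=True)
class SegmentPosture:
    """Position of one body segment, in degrees or percent of maximal range.

    Exactly one of ``angle_deg`` / ``percent_of_range`` is given; for the
    arm-chain segments the two are interconvertible through the segment's
    maximal range.  Flexion is positive, extension negative.
    """

    segment: Segment
    angle_deg: float | None = None
    percent_of_range: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "segment", Segment(self.segment))
        object.__setattr__(self, "flags", frozenset(self.flags))
        if (self.angle_deg is None) == (self.percent_of_range is None):
            raise SegmentError(
                "exactly one of angle_deg / percent_of_range must be given"
            )
        bad = self.flags - SEGMENT_FLAGS[self.segment]
        if bad:
            raise SegmentError(
                f"flags {sorted(bad)} are not applicable to segment {self.segment.value!r}"
            )
        if self.percent_of_range is not None and self.segment not in ARM_SEGMENTS:
            raise SegmentError(
                f"percent-of-range input is only defined for arm segments, "
                f"not {self.segment.value!r}"
            )
        if self.percent_of_range is not None and abs(self.percent_of_range) > 100:
            raise SegmentError(f"|percent| must be <= 100, got {self.percent_of_range}")

    @property
    def percent(self) -> float:
        """Signed percent of maximal range (arm segments only)."""
        if self.percent_of_range is not None:
            return self.percent_of_range
        return degrees_to_percent(self.segment, self.angle_deg)

    @property
    def degrees(self) -> float:
        """Signed joint angle in degrees."""
        if self.angle_deg is not None:
            return self.angle_deg
        return percent_to_degrees(self.segment, self.percent_of_range)


def _require(posture: SegmentPosture, segment: Segment) -> None:
    if posture.segment is not segment:
        raise SegmentError(
            f"expected a {segment.value!r} posture, got {posture.segment.value!r}"
        )


@dataclass(frozen=True)
class PostureB:
    """Group B: the arm chain of the more heavily loaded limb."""

    upper_arm: SegmentPosture
    lower_arm: SegmentPosture
    wrist: SegmentPosture

    def __post_init__(self) -> None:
        _require(self.upper_arm, Segment.UPPER_ARM)
        _require(self.lower_arm, Segment.LOWER_ARM)
        _require(self.wrist, Segment.WRIST)

    @classmethod
    def from_percent(
        cls, upper_arm: float, lower_arm: float, wrist: float,
        upper_arm_flags: frozenset[str] = frozenset(),
        wrist_flags: frozenset[str] = frozenset(),
    ) -> "PostureB":
        """Build an arm-chain posture from percent-of-range indicators."""
        return cls(
            SegmentPosture(Segment.UPPER_ARM, percent_of_range=upper_arm, flags=upper_arm_flags),
            SegmentPosture(Segment.LOWER_ARM, percent_of_range=lower_arm),
            SegmentPosture(Segment.WRIST, percent_of_range=wrist, flags=wrist_flags),
        )

    @classmethod
    def from_degrees(
        cls, upper_arm: float, lower_arm: float, wrist: float,
        upper_arm_flags: frozenset[str] = frozenset(),
        wrist_flags: frozenset[str] = frozenset(),
    ) -> "PostureB":
        """Build an arm-chain posture from joint angles in degrees."""
        return cls(
            SegmentPosture(Segment.UPPER_ARM, angle_deg=upper_arm, flags=upper_arm_flags),
            SegmentPosture(Segment.LOWER_ARM, angle_deg=lower_arm),
            SegmentPosture(Segment.WRIST, angle_deg=wrist, flags=wrist_flags),
        )


@dataclass(frozen=True)
class PostureA:
    """Group A: trunk, neck and legs, plus the handled load."""

    trunk: SegmentPosture
    neck: SegmentPosture
    legs: SegmentPosture
    load_kg: float = 0.0
    shock_or_rapid_force: bool = False

    def __post_init__(self) -> None:
        _require(self.trunk, Segment.TRUNK)
        _require(self.neck, Segment.NECK)
        _require(self.legs, Segment.LEGS)
        if self.load_kg < 0:
            raise SegmentError(f"load_kg must be non-negative, got {self.load_kg}")


@dataclass(frozen=True)
class ActivityContext:
    """Activity modifiers: each true flag adds 1 to the final score."""

    static_hold: bool = False
    repeated_small_range: bool = False
    rapid_large_changes: bool = False
    coupling: Coupling = Coupling.GOOD

    def __post_init__(self) -> None:
        object.__setattr__(self, "coupling", Coupling(self.coupling))

    @property
    def increment(self) -> int:
        return int(self.static_hold) + int(self.repeated_small_range) + int(self.rapid_large_changes)


@dataclass(frozen=True)
class RebaResult:
    """Complete REBA outcome: partial codes, group scores and risk category."""

    code_upper_arm: int
    code_lower_arm: int
    code_wrist: int
    code_trunk: int
    code_neck: int
    code_legs: int
    score_a: int
    score_b: int
    score_c: int
    final_score: int
    risk_category: int
    risk_label: str

    def to_dict(self) -> dict:
        return {
            "codes": {
                "upper_arm": self.code_upper_arm,
                "lower_arm": self.code_lower_arm,
                "wrist": self.code_wrist,
                "trunk": self.code_trunk,
                "neck": self.code_neck,
                "legs": self.code_legs,
            },
            "score_a": self.score_a,
            "score_b": self.score_b,
            "score_c": self.score_c,
            "final_score": self.final_score,
            "risk_category": self.risk_category,
            "risk_label": self.risk_label,
        }


# --------------------------------------------------------------------------
# partial codes


def upper_arm_code(posture: SegmentPosture) -> int:
    """Upper-arm code 1-6 from its flexion/extension band plus adjustments.

    Flexion bands (percent of a 180-degree range, closed on the right):
    <=11 -> 1, (11, 25] -> 2, (25, 50] -> 3, >50 -> 4.  Extension within
    20 degrees keeps code 1, beyond it code 2.  +1 if the shoulder is
    raised, +1 if the arm is abducted, -1 if the arm is supported.
    """
    _require(posture, Segment.UPPER_ARM)
    p = posture.percent
    if p >= 0:
        if p <= 11:
            code = 1
        elif p <= 25:
            code = 2
        elif p <= 50:
            code = 3
        else:
            code = 4
    else:
        code = 1 if posture.degrees >= -20 else 2
    if "shoulder_raised" in posture.flags:
        code += 1
    if "arm_abducted" in posture.flags:
        code += 1
    if "arm_supported" in posture.flags:
        code -= 1
    return max(1, min(code, 6))


def lower_arm_code(posture: SegmentPosture) -> int:
    """Lower-arm code: 1 inside the optimum band 50-83 % (60-100 deg), else 2."""
    _require(posture, Segment.LOWER_ARM)
    return 1 if 50 <= posture.percent <= 83 else 2


def wrist_code(posture: SegmentPosture) -> int:
    """Wrist code: 1 within +/-25 % (+/-15 deg), else 2; +1 if deviated/twisted."""
    _require(posture, Segment.WRIST)
    code = 1 if abs(posture.percent) <= 25 else 2
    if "wrist_deviated_or_twisted" in posture.flags:
        code += 1
    return min(code, 3)


def trunk_code(posture: SegmentPosture) -> int:
    """Trunk code 1-5: upright 1; small flexion/extension 2; larger 3; deep flexion 4."""
    _require(posture, Segment.TRUNK)
    a = posture.degrees
    if a == 0:
        code = 1
    elif -20 <= a <= 20:
        code = 2
    elif a <= 60:  # 20-60 deg flexion, or any extension beyond 20 deg
        code = 3
    else:
        code = 4
    if "trunk_twisted_or_side_flexed" in posture.flags:
        code += 1
    return min(code, 5)


def neck_code(posture: SegmentPosture) -> int:
    """Neck code 1-3: flexion up to 20 deg is 1; beyond, or any extension, 2."""
    _require(posture, Segment.NECK)
    code = 1 if 0 <= posture.degrees <= 20 else 2
    if "neck_twisted_or_side_flexed" in posture.flags:
        code += 1
    return min(code, 3)


def legs_code(posture: SegmentPosture) -> int:
    """Legs code 1-4: bilateral stable 1, unstable 2; +1/+2 for knee flexion."""
    _require(posture, Segment.LEGS)
    code = 2 if "legs_unstable" in posture.flags else 1
    if "knee_flex_gt_60" in posture.flags:
        code += 2
    elif "knee_flex_30_60" in posture.flags:
        code += 1
    return min(code, 4)


# --------------------------------------------------------------------------
# group and final scores


def _load_score(load_kg: float, shock: bool) -> int:
    score = 0 if load_kg < 5 else (1 if load_kg <= 10 else 2)
    return score + int(shock)


def score_a(posture: PostureA) -> int:
    """Group A score: Table A over (trunk, neck, legs) codes plus the load score."""
    key = (trunk_code(posture.trunk), neck_code(posture.neck), legs_code(posture.legs))
    try:
        base = table_a()[key]
    except KeyError:  # pragma: no cover - codes are clamped upstream
        raise SegmentError(f"group A codes {key} outside Table A") from None
    return base + _load_score(posture.load_kg, posture.shock_or_rapid_force)


def score_b(ua_code: int, la_code: int, w_code: int, coupling: Coupling = Coupling.GOOD) -> int:
    """Group B score: Table B over (upper arm, lower arm, wrist) codes plus coupling."""
    key = (ua_code, la_code, w_code)
    try:
        base = table_b()[key]
    except KeyError:
        raise SegmentError(f"group B codes {key} outside Table B (6 x 2 x 3)") from None
    return base + COUPLING_SCORE[Coupling(coupling)]


def score_c(a: int, b: int) -> int:
    """Score C: the 12 x 12 cross table of group scores."""
    try:
        return table_c()[(a, b)]
    except KeyError:
        raise SegmentError(f"scores ({a}, {b}) outside Table C (1-12 each)") from None


def final_score(c: int, activity: ActivityContext) -> int:
    """Final score: score C plus 1 per true activity flag (static hold etc.)."""
    return c + activity.increment


def risk_category(final: int) -> tuple[int, str]:
    """Map a final score to the five-level action category.

    1 -> negligible; 2-3 -> low; 4-7 -> medium; 8-10 -> high; >=11 -> very high.
    """
    if final < 1:
        raise SegmentError(f"final score must be >= 1, got {final}")
    if final == 1:
        cat = 1
    elif final <= 3:
        cat = 2
    elif final <= 7:
        cat = 3
    elif final <= 10:
        cat = 4
    else:
        cat = 5
    return cat, RISK_LABELS[cat]


# --------------------------------------------------------------------------
# composed assessments


def assess(posture_a: PostureA, posture_b: PostureB, activity: ActivityContext) -> RebaResult:
    """Full REBA assessment from explicit group A and group B postures."""
    codes = (
        upper_arm_code(posture_b.upper_arm),
        lower_arm_code(posture_b.lower_arm),
        wrist_code(posture_b.wrist),
    )
    ct = trunk_code(posture_a.trunk)
    cn = neck_code(posture_a.neck)
    cl = legs_code(posture_a.legs)
    a = score_a(posture_a)
    b = score_b(*codes, coupling=activity.coupling)
    c = score_c(a, b)
    final = final_score(c, activity)
    cat, label = risk_category(final)
    return RebaResult(
        code_upper_arm=codes[0], code_lower_arm=codes[1], code_wrist=codes[2],
        code_trunk=ct, code_neck=cn, code_legs=cl,
        score_a=a, score_b=b, score_c=c,
        final_score=final, risk_category=cat, risk_label=label,
    )


def assess_standing_manual(
    posture_b: PostureB,
    neck: SegmentPosture | None = None,
    activity: ActivityContext = ActivityContext(),
) -> RebaResult:
    """Assess a standing, unforced manual task: neutral trunk, stable legs, no load.

    This is the simplified workflow for workstations where the operator
    stands upright: the group A score is fixed at 1 (first row of Table C)
    and the outcome is driven by the arm chain and the activity increments.
    """
    posture_a = PostureA(
        trunk=SegmentPosture(Segment.TRUNK, angle_deg=0.0),
        neck=neck if neck is not None else SegmentPosture(Segment.NECK, angle_deg=0.0),
        legs=SegmentPosture(Segment.LEGS, angle_deg=0.0),
        load_kg=0.0,
    )
    return assess(posture_a, posture_b, activity)
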