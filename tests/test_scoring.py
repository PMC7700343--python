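"""REBA scoring: band coding, percent conversion and the composed assessment.

The parametrised worked examples are the published posture readouts of the
two case-study stations (original and height-corrected variants), given as
percent-of-maximal-range indicators with their expected partial codes,
group B scores and final static-work scores.
"""

import pytest
from hypothesis import given, settings, strategies as st

from rebakit.scoring import (
    ActivityContext,
    Coupling,
    PostureA,
    PostureB,
    SegmentPosture,
    assess,
    assess_standing_manual,
    final_score,
    legs_code,
    lower_arm_code,
    neck_code,
    risk_category,
    score_a,
    score_b,
    score_c,
    trunk_code,
    upper_arm_code,
    wrist_code,
)
from rebakit.segments import (
    ARM_SEGMENTS,
    MAX_RANGE_DEG,
    Segment,
    SegmentError,
    degrees_to_percent,
    percent_to_degrees,
)

STATIC = ActivityContext(static_hold=True)


# --------------------------------------------------------------------------
# percent <-> degrees


@pytest.mark.parametrize(
    "segment, percent, degrees",
    [
        (Segment.UPPER_ARM, 25, 45.0),
        (Segment.UPPER_ARM, 11, 19.8),
        (Segment.UPPER_ARM, 50, 90.0),
        (Segment.LOWER_ARM, 50, 60.0),
        (Segment.LOWER_ARM, 83, 99.6),
        (Segment.WRIST, 25, 15.0),
        (Segment.WRIST, -25, -15.0),
        (Segment.UPPER_ARM, 0, 0.0),
        (Segment.LOWER_ARM, 0, 0.0),
        (Segment.WRIST, 0, 0.0),
    ],
)
def test_percent_to_degrees_band_boundaries(segment, percent, degrees):
    assert percent_to_degrees(segment, percent) == pytest.approx(degrees)
    assert degrees_to_percent(segment, degrees) == pytest.approx(percent)


def test_percent_conversion_domain_errors():
    with pytest.raises(SegmentError):
        percent_to_degrees(Segment.TRUNK, 10)
    with pytest.raises(SegmentError):
        percent_to_degrees(Segment.UPPER_ARM, 101)
    with pytest.raises(ValueError):
        percent_to_degrees("shoulder", 10)


@settings(deadline=None, derandomize=True)
@given(
    segment=st.sampled_from(ARM_SEGMENTS),
    percent=st.floats(min_value=-100, max_value=100, allow_nan=False),
)
def test_percent_degree_round_trip(segment, percent):
    assert degrees_to_percent(segment, percent_to_degrees(segment, percent)) == pytest.approx(
        percent, abs=1e-9
    )


# --------------------------------------------------------------------------
# partial codes: published posture readouts (station a/b, original and corrected)


@pytest.mark.parametrize(
    "percent, flags, expected",
    [
        (26, frozenset(), 3),
        (14, frozenset(), 2),
        (23, frozenset(), 2),
        (11, frozenset(), 1),
        (54, frozenset({"shoulder_raised"}), 5),
        (32, frozenset(), 3),
        (24, frozenset(), 2),
        (10, frozenset(), 1),
    ],
)
def test_upper_arm_codes_from_published_readouts(percent, flags, expected):
    posture = SegmentPosture(Segment.UPPER_ARM, percent_of_range=percent, flags=flags)
    assert upper_arm_code(posture) == expected


@pytest.mark.parametrize(
    "percent, expected",
    [(76, 1), (58, 1), (64, 1), (45, 2), (50, 1), (77, 1), (79, 1), (65, 1), (83, 1), (84, 2)],
)
def test_lower_arm_codes_from_published_readouts(percent, expected):
    assert lower_arm_code(SegmentPosture(Segment.LOWER_ARM, percent_of_range=percent)) == expected


@pytest.mark.parametrize(
    "percent, expected",
    [(42, 2), (18, 1), (11, 1), (67, 2), (28, 2), (21, 1), (25, 1), (-25, 1), (26, 2)],
)
def test_wrist_codes_from_published_readouts(percent, expected):
    assert wrist_code(SegmentPosture(Segment.WRIST, percent_of_range=percent)) == expected


def test_upper_arm_band_edges_closed_right():
    """Band edges belong to the lower code: 11 % -> 1, 25 % -> 2, 50 % -> 3."""
    for pct, code in [(11, 1), (11.01, 2), (25, 2), (25.01, 3), (50, 3), (50.01, 4), (100, 4)]:
        assert upper_arm_code(SegmentPosture(Segment.UPPER_ARM, percent_of_range=pct)) == code


def test_upper_arm_degree_input_agrees_with_percent_bands():
    # 60 deg lies inside the 45-90 deg band (code 3)
    assert upper_arm_code(SegmentPosture(Segment.UPPER_ARM, angle_deg=60.0)) == 3
    assert upper_arm_code(SegmentPosture(Segment.UPPER_ARM, angle_deg=0.0)) == 1
    assert upper_arm_code(SegmentPosture(Segment.UPPER_ARM, angle_deg=45.0)) == 2


def test_upper_arm_extension_and_adjustments():
    assert upper_arm_code(SegmentPosture(Segment.UPPER_ARM, angle_deg=-15.0)) == 1
    assert upper_arm_code(SegmentPosture(Segment.UPPER_ARM, angle_deg=-30.0)) == 2
    raised_abducted = SegmentPosture(
        Segment.UPPER_ARM, percent_of_range=60,
        flags=frozenset({"shoulder_raised", "arm_abducted"}),
    )
    assert upper_arm_code(raised_abducted) == 6
    supported_neutral = SegmentPosture(
        Segment.UPPER_ARM, percent_of_range=0, flags=frozenset({"arm_supported"})
    )
    assert upper_arm_code(supported_neutral) == 1  # floor at 1


def test_wrist_deviation_adjustment():
    deviated = SegmentPosture(
        Segment.WRIST, percent_of_range=0, flags=frozenset({"wrist_deviated_or_twisted"})
    )
    assert wrist_code(deviated) == 2
    worst = SegmentPosture(
        Segment.WRIST, percent_of_range=80, flags=frozenset({"wrist_deviated_or_twisted"})
    )
    assert wrist_code(worst) == 3


def test_group_a_segment_codes():
    assert trunk_code(SegmentPosture(Segment.TRUNK, angle_deg=0)) == 1
    assert trunk_code(SegmentPosture(Segment.TRUNK, angle_deg=15)) == 2
    assert trunk_code(SegmentPosture(Segment.TRUNK, angle_deg=40)) == 3
    assert trunk_code(SegmentPosture(Segment.TRUNK, angle_deg=70)) == 4
    # extreme sagittal head tilt codes 2, never more without a twist
    assert neck_code(SegmentPosture(Segment.NECK, angle_deg=25)) == 2
    assert neck_code(SegmentPosture(Segment.NECK, angle_deg=10)) == 1
    assert neck_code(SegmentPosture(Segment.NECK, angle_deg=-5)) == 2
    assert legs_code(SegmentPosture(Segment.LEGS, angle_deg=0)) == 1
    assert legs_code(
        SegmentPosture(Segment.LEGS, angle_deg=0, flags=frozenset({"legs_unstable"}))
    ) == 2
    assert legs_code(
        SegmentPosture(Segment.LEGS, angle_deg=0,
                       flags=frozenset({"legs_unstable", "knee_flex_gt_60"}))
    ) == 4


def test_segment_posture_construction_invariants():
    with pytest.raises(SegmentError):
        SegmentPosture(Segment.UPPER_ARM)  # neither representation
    with pytest.raises(SegmentError):
        SegmentPosture(Segment.UPPER_ARM, angle_deg=10, percent_of_range=10)  # both
    with pytest.raises(SegmentError):
        SegmentPosture(Segment.TRUNK, percent_of_range=10)  # % undefined for trunk
    with pytest.raises(SegmentError):
        SegmentPosture(Segment.LOWER_ARM, angle_deg=80, flags=frozenset({"shoulder_raised"}))
    with pytest.raises(SegmentError):
        wrist_code(SegmentPosture(Segment.UPPER_ARM, angle_deg=10))


# --------------------------------------------------------------------------
# group scores, final score, risk category


def _posture_a(trunk=0.0, neck=0.0, load=0.0, trunk_flags=frozenset(), legs_flags=frozenset()):
    return PostureA(
        trunk=SegmentPosture(Segment.TRUNK, angle_deg=trunk, flags=trunk_flags),
        neck=SegmentPosture(Segment.NECK, angle_deg=neck),
        legs=SegmentPosture(Segment.LEGS, angle_deg=0.0, flags=legs_flags),
        load_kg=load,
    )


def test_score_a_is_one_for_standing_unforced_work():
    """Neutral trunk and stable legs keep score A at 1, even with a full head tilt."""
    assert score_a(_posture_a(neck=0)) == 1
    assert score_a(_posture_a(neck=25)) == 1  # neck code 2, Table A cell still 1


def test_score_a_load_increments():
    assert score_a(_posture_a(load=4.9)) == 1
    assert score_a(_posture_a(load=7)) == 2
    assert score_a(_posture_a(load=12)) == 3


def test_score_b_examples_and_coupling():
    assert score_b(3, 1, 2) == 4
    assert score_b(5, 1, 2) == 7
    assert score_b(1, 1, 1) == 1
    assert score_b(2, 1, 1) == 1
    assert score_b(1, 1, 1, coupling=Coupling.UNACCEPTABLE) == 4
    with pytest.raises(SegmentError):
        score_b(7, 1, 1)


def test_score_c_lookup_and_domain():
    assert score_c(1, 4) == 2
    assert score_c(1, 1) == 1
    assert score_c(12, 12) == 12
    with pytest.raises(SegmentError):
        score_c(0, 5)


def test_final_score_activity_increments():
    assert final_score(2, STATIC) == 3
    assert final_score(1, STATIC) == 2
    assert final_score(1, ActivityContext()) == 1
    everything = ActivityContext(static_hold=True, repeated_small_range=True,
                                 rapid_large_changes=True)
    assert final_score(1, everything) == 4


@pytest.mark.parametrize(
    "final, category, label",
    [(1, 1, "negligible"), (2, 2, "low"), (3, 2, "low"), (4, 3, "medium"),
     (7, 3, "medium"), (8, 4, "high"), (10, 4, "high"), (11, 5, "very high"),
     (15, 5, "very high")],
)
def test_risk_category_action_bands(final, category, label):
    assert risk_category(final) == (category, label)


def test_risk_category_rejects_nonpositive():
    with pytest.raises(SegmentError):
        risk_category(0)


# --------------------------------------------------------------------------
# composed assessment: full published columns


@pytest.mark.parametrize(
    "percents, ua_flags, codes, b, final",
    [
        # original station (a): 5th percentile woman / 95th percentile man
        ((26, 76, 42), frozenset(), (3, 1, 2), 4, 3),
        ((14, 58, 18), frozenset(), (2, 1, 1), 1, 2),
        # corrected station (a)
        ((23, 64, 11), frozenset(), (2, 1, 1), 1, 2),
        ((11, 45, 11), frozenset(), (1, 2, 1), 1, 2),
        # corrected station (b)
        ((24, 79, 21), frozenset(), (2, 1, 1), 1, 2),
        ((10, 65, 11), frozenset(), (1, 1, 1), 1, 2),
        # original station (b), 95th percentile man
        ((32, 77, 28), frozenset(), (3, 1, 2), 4, 3),
    ],
)
def test_standing_assessment_reproduces_published_columns(percents, ua_flags, codes, b, final):
    result = assess_standing_manual(
        PostureB.from_percent(*percents, upper_arm_flags=ua_flags), activity=STATIC
    )
    assert (result.code_upper_arm, result.code_lower_arm, result.code_wrist) == codes
    assert result.score_a == 1
    assert result.score_b == b
    assert result.final_score == final


def test_station_b_worst_posture_partial_codes_and_raw_score():
    """The raised-shoulder 54 % posture codes 5/1/2 with group B score 7.

    The published summary row for this station reports the pre-increment
    score; both the raw score C and the always-incremented final score are
    exposed so either convention can be read off.
    """
    result = assess_standing_manual(
        PostureB.from_percent(54, 50, 67, upper_arm_flags=frozenset({"shoulder_raised"})),
        activity=STATIC,
    )
    assert (result.code_upper_arm, result.code_lower_arm, result.code_wrist) == (5, 1, 2)
    assert result.score_b == 7
    assert result.score_c == 4
    assert result.final_score == 5  # score C + 1 static
    assert result.risk_category == 3


def test_all_neutral_posture_scores_minimum():
    result = assess_standing_manual(PostureB.from_degrees(0, 90, 0), activity=ActivityContext())
    assert result.final_score == 1
    assert result.risk_category == 1
    assert result.risk_label == "negligible"


def test_minimal_codes_with_static_hold_score_two():
    result = assess_standing_manual(PostureB.from_degrees(0, 90, 0), activity=STATIC)
    assert result.final_score == 2
    assert result.risk_category == 2


def test_full_assessment_with_nonneutral_group_a():
    result = assess(
        _posture_a(trunk=40, neck=25, load=7),
        PostureB.from_percent(26, 76, 42),
        STATIC,
    )
    # trunk 3, neck 2, legs 1 -> Table A 4, +1 load = 5; B 4 -> C(5,4)=5, +1 static
    assert result.score_a == 5
    assert result.score_c == 5
    assert result.final_score == 6
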