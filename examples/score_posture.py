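"""Score working postures read out of DHM software as percent-of-range indicators.

Runs the standing-manual REBA workflow on the boundary-mannequin posture
readouts of an uncorrected assembly bench: upper arm / lower arm / wrist
as signed percentages of each joint's maximal range, with a static hold.
"""

from rebakit import ActivityContext, PostureB, assess_standing_manual

postures = {
    "5th-percentile woman": (26, 76, 42),
    "95th-percentile man": (14, 58, 18),
}

for who, percents in postures.items():
    result = assess_standing_manual(
        PostureB.from_percent(*percents),
        activity=ActivityContext(static_hold=True),
    )
    print(f"{who}: upper arm {percents[0]}%, lower arm {percents[1]}%, wrist {percents[2]}%")
    print(
        f"  partial codes {result.code_upper_arm}/{result.code_lower_arm}/{result.code_wrist}"
        f", score B {result.score_b}, final {result.final_score}"
        f" -> risk category {result.risk_category} ({result.risk_label})"
    )

print()
print(
    "The final score includes +1 for static work; category 2 means low WMSD risk\n"
    "but corrective action may be needed - here the bench is too high for the\n"
    "shorter worker, whose arm codes are uniformly worse."
)
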