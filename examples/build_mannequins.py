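"""Build percentile mannequins from a population's stature statistics.

Statures are normal quantiles per sex; all landmark heights and arm-segment
lengths are fixed fractions of stature.  The boundary pair (female 5th,
male 95th percentile) brackets the population for design validation, and
the combined 50th percentile is the median of the 50/50 sex mixture.
"""

from rebakit import DEFAULT_POPULATION, Sex, boundary_pair, build_mannequin

small, tall = boundary_pair(DEFAULT_POPULATION)
median = build_mannequin(DEFAULT_POPULATION, Sex.COMBINED, 50.0)

for m in (small, median, tall):
    print(
        f"{m.label:>12}: stature {m.stature:7.1f} mm, shoulder {m.shoulder_height:7.1f} mm, "
        f"eye {m.eye_height:7.1f} mm, arm chain "
        f"{m.upper_arm:.0f}+{m.forearm:.0f}+{m.hand:.0f} mm"
    )

print()
print(
    "The ~%.0f mm stature gap between the boundary mannequins is what a fixed\n"
    "work-surface height has to accommodate." % (tall.stature - small.stature)
)
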