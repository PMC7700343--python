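# rebakit

REBA posture scoring and work-surface-height design with anthropometric
percentile mannequins, for assessing and minimizing work-related
musculoskeletal disorder (WMSD) risk at standing manual workstations.

The package is aimed at ergonomists and engineers who evaluate workstation
geometry with digital human models (DHM): it scores postures with the REBA
(Rapid Entire Body Assessment) method — including the percent-of-maximal-range
posture indicators that DHM software such as Anthropos reports instead of
joint angles — builds percentile mannequins from population stature
statistics, solves sagittal-plane reach postures under a minimum-partial-code
rule, and compares strategies for anchoring an adjustable work-surface or
tool-holder height, each validated on boundary mannequins.

## The method

REBA assigns each body segment a small integer code from its deviation band.
Group A (trunk *t*, neck *n*, legs *l*) combines through a 5×3×4 lookup table
plus a load score; group B (upper arm *u*, lower arm *f*, wrist *w*) through
a 6×2×3 table plus a coupling score. The 12×12 cross table gives score C,
and the final score adds +1 per activity modifier (static hold ≥ 1 min,
high repetition, rapid large changes):

```
A = TableA[t, n, l] + load        B = TableB[u, f, w] + coupling
C = TableC[A, B]                  final = C + activity increments
```

Final scores map to five action categories (1 negligible … 5 very high).
For standing, unforced work A = 1, so risk is governed by the arm chain.

Group B indicators come as signed percentages of each joint's maximal range
(upper arm 180°, lower arm 120°, wrist 60°), with code bands closed on the
right: upper arm ≤ 11 % → 1, (11, 25] → 2, (25, 50] → 3, > 50 → 4 (+1 if the
shoulder is raised, +1 abducted, −1 supported); lower arm 1 inside
[50 %, 83 %] (60–100°), else 2; wrist 1 within ±25 % (±15°), else 2 (+1 if
deviated or twisted).

A mannequin's stature is the normal quantile `mean + z(p)·sd` of its sex;
segment lengths are fixed fractions of stature. Reach postures are solved on
a joint-angle grid by choosing, among postures whose hand lands on the work
point, the lexicographically smallest code vector (u, f, w), then the
smallest deviation from neutral. Height design anchors the work point to the
hand height of a mannequin posed with every segment in its code-1 band.

## Worked example

```sh
$ rebakit assess --ua-pct 26 --la-pct 76 --wrist-pct 42 --static
quantity       value
-------------  -------
upper_arm            3
lower_arm            1
wrist                2
trunk                1
neck                 1
legs                 1
score A              1
score B              4
score C              2
final score          3
risk category  2 (low)
```

A worker holding the upper arm at 26 %, lower arm at 76 % and wrist at 42 %
of their ranges (a short operator at a too-high bench) codes 3/1/2, giving
group B score 4, score C 2 and a final score of 3 after the +1 static-work
increment: risk category 2 — low risk, but corrective action may be needed.

The same from Python, plus a design comparison:

```python
from rebakit import ActivityContext, PostureB, assess_standing_manual, compare_strategies
from rebakit.io import bundled_workstation, default_population

result = assess_standing_manual(
    PostureB.from_percent(26, 76, 42), activity=ActivityContext(static_hold=True)
)
print(result.final_score, result.risk_category)   # 3 2

reports = compare_strategies(default_population(), bundled_workstation("b"),
                             ActivityContext(static_hold=True))
for r in reports:
    print(r.strategy.value, round(r.height_change), [e.reba.final_score for e in r.entries])
# as_is 0 [2, 2]
# anchor_p50 -340 [2, 2]
# anchor_p5 -372 [2, 2]
# boundary -451 [2, 2]
```

Lowering the hanging-tool work point by ~340 mm to the 50th-percentile
optimum brings the 5th-percentile female's upper-arm code from 3 back to 1;
under a static hold no design can score below 2. The `examples/` scripts
walk through each capability with commentary.

## Layout

| module | contents |
| --- | --- |
| `rebakit.scoring` | posture types, partial-code bands, group and final scores |
| `rebakit.segments` | joint ranges, percent ↔ degree conversion |
| `rebakit.tables` | checksummed REBA lookup matrices (CSV) |
| `rebakit.anthropometry` | populations, percentile mannequins, boundary pair |
| `rebakit.kinematics` | planar arm chain, forward kinematics, minimum-code reach |
| `rebakit.workstation` | station assessment, height anchoring, strategy comparison |
| `rebakit.io`, `rebakit.cli`, `rebakit.fixtures` | YAML configs, reports, CLI, synthetic fixtures |
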