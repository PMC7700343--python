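# Methods

## Scope and model

`rebakit` models the ergonomic assessment of standing manual workstations
with digital human models (DHM), reduced to the pieces that determine REBA
risk at such stations: a percentile mannequin (stature-proportional segment
lengths), a sagittal-plane arm chain, the REBA scoring tables, and a
work-point height that can be anchored to a mannequin's optimal posture.

The central simplification is the *standing-manual* workflow. Operators
stand upright with stable bilateral weight bearing and no external load, so
the trunk and legs code 1 and even an extreme sagittal head tilt (neck code
2) leaves the group A table cell at 1. The whole assessment then lives in
the first row of the score-C matrix and is driven by the arm chain plus the
+1 static-work increment, which applies whenever a segment is held in place
for a minute or more — true of essentially all workstation tasks modelled
here. The general scorer (`rebakit.scoring.assess`) with non-neutral trunk,
neck, legs, load and coupling is implemented and tested, but the design
machinery always goes through the standing workflow.

## Scoring conventions

**Lookup tables.** The group A (5×3×4), group B (6×2×3) and cross (12×12)
matrices are shipped as CSV files with a SHA-256 manifest verified at load
time. The test suite compares every cell against a second, independently
transcribed copy kept in a different layout, and checks the structural
invariants (60/36/144 cells, monotonicity of the cross table in both
arguments and of table B in the upper-arm and wrist codes).

**Percent-of-range indicators.** DHM software of the Anthropos family
reports joint positions as signed percentages of each joint's maximal
range. The maximal ranges (upper arm 180°, lower arm 120°, wrist 60°) are
the unique constants under which the percent and degree forms of all the
published band boundaries coincide (11 % ↔ 19.8°≈20°, 25 % ↔ 45°,
50 % ↔ 90°; 50 % ↔ 60°, 83 % ↔ 99.6°≈100°; 25 % ↔ 15°). They are named
constants and can be overridden per call for other skeletons.

**Band-edge convention.** Published band notations are ambiguous at the
edges (a boundary printed as "<11" in one place is scored as code 1 at
exactly 11 % elsewhere). All percent bands here are closed on the right
(≤ 11 → 1, (11, 25] → 2, (25, 50] → 3, > 50 → 4) and the lower-arm optimum
band is closed on both ends ([50, 83] → 1), which reproduces every worked
readout in the source material. 45° of upper-arm flexion therefore codes 2,
not 3.

**Extension.** Angles are signed (flexion positive). Upper-arm extension
within 20° keeps code 1 and codes 2 beyond, per the published method; this
path lies outside the case-study readouts and is covered by unit tests
only. Wrist bands are symmetric by construction.

**Static increment.** The final score always adds 1 per true activity flag.
One published summary row reports scores without the static increment its
sibling tables include; rather than guess a convention, `RebaResult`
exposes both the raw score C and the incremented final score, and the
engine never silently drops an increment.

## Anthropometry

Stature within each sex is normal; the p-th percentile mannequin has
stature `mean + z(p)·sd`. Landmark heights and segment lengths are fixed
fractions of stature (defaults: shoulder 0.818, eye 0.936, upper arm 0.186,
forearm 0.146, hand 0.108 — classic stature-proportion values). The bundled
"eastern_europe_synthetic" population (female 1620 ± 62 mm, male
1770 ± 67 mm) is an illustrative stand-in, *not* survey data: the
population databases inside commercial DHM suites are proprietary. No
geometry-dependent test or acceptance value depends on these defaults; they
only have to be plausible adult statures.

The "50th-percentile individual" used for design is, by default, the median
of the 50/50 female/male stature mixture, found by root-finding on the
mixture CDF; `p50_mode` switches to a per-sex median. This choice was open —
the source workflow does not say which convention its DHM used — and the
mixture median is the interpretation that matches "average member of the
(whole) adult population".

## Kinematics

The arm is a three-link planar chain (upper arm, forearm, hand) in the
sagittal plane, anchored at the shoulder on the body axis; cumulative
flexion angles measure from the hanging vertical, so a link at cumulative
angle φ points along (sin φ, −cos φ). Planarity mirrors how DHM reach
studies report one signed indicator per arm segment; abduction, shoulder
girdle motion and trunk lean are out of scope, which also means the
`shoulder_raised`/`arm_abducted` adjustments never arise from the solver —
they are input flags for externally observed postures.

Reaching a 2-D work point with three joints is underdetermined. The solver
grid-searches the joint box (upper arm 0–180°, elbow 0–120°, wrist ±60°) at
1° resolution (configurable), keeps postures whose hand lands within 10 mm
(configurable) of the target, and picks the lexicographically smallest REBA
code vector — upper arm first, then lower arm, then wrist — breaking ties
by total absolute angular deviation from neutral, then by fixed grid order,
which makes the result fully deterministic. Lexicographic order was chosen
over a code sum because the segment-wise "minimum partial indicators" rule
prioritises the most score-sensitive segment (the upper arm drives table B
hardest); a `objective="sum"` mode is available. Unreachable targets raise
an error naming the mannequin's maximal reach. The grid search is
vectorised; a full-resolution solve costs ~0.1 s, and tests that compare
against exhaustive enumeration use a shared 6° grid so the brute-force
oracle stays cheap.

## Height design

`anchor_posture` defines the canonical code-1-band posture: elbow at the
centre of its 50–83 % band, wrist neutral, upper arm either at the centre
of its sub-11 % band (`optimal_center`) or exactly at the 11 % border
(`optimal_boundary` — the highest hand position that keeps the most
sensitive segment at code 1). These are posture constants; a mannequin's
stature turns them into a hand height, and `optimize_height` moves the work
point (and the surface or tool height tied to it) there. The operation is
idempotent, and the anchor hand height is strictly increasing in stature.

An alternative design, solving the anchor posture under the station's fixed
horizontal offset, was considered and rejected: with the offset constrained,
small changes of the upper-arm anchor force large compensating elbow/wrist
excursions and the resulting heights lose their monotone, stature-like
behaviour. With free anchor postures the border-anchored p5 female design
lands a few centimetres below the p50-centre design — the compensating
behaviour that makes "design for the smallest, at the band border" a viable
strategy for the whole population.

`compare_strategies` evaluates four designs — `as_is`, `anchor_p50`,
`anchor_p5` (p5 female, border anchor), `boundary` (p5 female, centre
anchor) — each validated by re-assessing both boundary mannequins
(female p5, male p95), reporting scores, height changes, eye-to-work-point
distances and a viewing check. The viewing band defaults to 500–700 mm
(the recommendation for visual information that requires reading); only the
upper bound fails the check, distances below the band are noted but
accepted, since the ergonomic concern at lowered work points is excessive
distance.

## Synthetic fixtures

The bundled stations are parametric stand-ins for unpublished industrial
CAD geometry (filenames and specs say `synthetic`). Both place the work
point above even the 95th-percentile male's optimal hand height — station A
(fixed assembly bench) by 30–70 mm, station B (hanging-tool holder) by
220–300 mm, horizontal offsets 410–440 mm — drawn deterministically from a
seed, so the as-is assessments reproduce the qualitative signature of a
station built for tall workers: the 5th-percentile female's upper-arm code
is strictly worse than the male's. What the fixtures do *not* emulate:
real stations constrain stance and vision, induce shoulder raising and
wrist deviation (flags the solver never sets), and their published height
corrections and eye distances depend on the true CAD dimensions — so
passing fixture tests demonstrates the properties of the method (optimizer
post-condition, p50-anchoring dominance, static risk floor of 2), not the
specific centimetre values of any real redesign.

## Numerical choices and limitations

- Grid resolutions: 1° IK default (≈8 mm hand motion per joint degree at
  adult arm lengths, comfortably inside the 10 mm tolerance); tests use 5–6°
  with matching tolerances for brute-force comparability.
- The mixture-median root-find uses Brent's method on an 8-SD bracket,
  tolerance 1e-6 mm.
- Degenerate inputs: zero-length viewing bands, non-adjustable stations,
  single-sex populations, out-of-range percentiles and angles all raise
  typed errors early.
- Risk floor: under a static hold no height design can score below 2; the
  package reports this rather than pretending a perfect station exists.
- Not modelled: 3-D shoulder kinematics, seated work, temporal load
  accumulation, force/EMG biomechanics, field-of-view imagery (only the
  scalar eye-to-work-point distance), and alternative observational methods
  (RULA, OWAS).
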