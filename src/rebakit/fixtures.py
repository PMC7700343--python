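"""Deterministic generation of synthetic fixture stations and a default population.

The real stations behind this kind of study are company CAD models that are
never published, so the package ships parametric stand-ins: station A (a
manual-assembly bench whose fixed work surface sits moderately above the
average operator's optimal hand height) and station B (a hanging-tool
station whose tool holder sits far too high).  Both are constructed
relative to the bundled population's 50th-percentile optimum, so the
"as-is" assessments reproduce the qualitative pattern of a station
designed for taller operators: the 5th-percentile female scores worse than
the 95th-percentile male.  Generation is deterministic per seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .anthropometry import Population, Sex, build_mannequin
from .kinematics import WorkPoint, forward
from .workstation import Anchor, Workstation, anchor_posture

#: Synthetic illustrative stature statistics (mm) and classic
#: stature-proportion coefficients; not survey values.
DEFAULT_POPULATION = Population(
    name="eastern_europe_synthetic",
    stature_mean_mm={"female": 1620.0, "male": 1770.0},
    stature_sd_mm={"female": 62.0, "male": 67.0},
    proportion_coefficients={
        "shoulder_height": 0.818,
        "eye_height": 0.936,
        "upper_arm_length": 0.186,
        "forearm_length": 0.146,
        "hand_length": 0.108,
    },
)


def optimal_hand_height(population: Population, sex: Sex, percentile: float) -> float:
    """Hand height (mm) of a mannequin's band-centre anchor posture."""
    m = build_mannequin(population, sex, percentile)
    (_, y), _ = forward(m, anchor_posture(Anchor.OPTIMAL_CENTER))
    return y


def make_fixture_stations(
    population: Population, seed: int = 0
) -> tuple[Workstation, Workstation]:
    """Build the two synthetic stations, work points above the p50 optimum.

    Both stations are built for tall operators: their work points sit above
    even the 95th-percentile male's optimal hand height - station A (a
    fixed assembly bench) by 30-70 mm, station B (a hanging-tool holder)
    by 220-300 mm - so the as-is assessments penalise the short boundary
    mannequin hardest.  Horizontal offsets and elevations are drawn
    deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    offset_a = float(rng.uniform(410.0, 440.0))
    offset_b = float(rng.uniform(410.0, 440.0))
    above_a = float(rng.uniform(30.0, 70.0))
    above_b = float(rng.uniform(220.0, 300.0))
    opt_a = optimal_hand_height(population, Sex.MALE, 95.0)
    opt_b = opt_a
    station_a = Workstation(
        name="station_a_synthetic",
        surface_height=opt_a + above_a,
        work_point=WorkPoint(offset_a, opt_a + above_a),
        adjustable=frozenset({"surface_height"}),
    )
    station_b = Workstation(
        name="station_b_synthetic",
        surface_height=opt_b,  # bench height; the tool holder carries the work point
        work_point=WorkPoint(offset_b, opt_b + above_b),
        adjustable=frozenset({"tool_height"}),
    )
    return station_a, station_b


def generate_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write the default population and both fixture stations to ``outdir``.

    Returns the written paths keyed by ``population`` / ``station_a`` /
    ``station_b``.  Re-running with the same seed reproduces the files
    byte for byte.
    """
    from .io import save_population, save_workstation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    station_a, station_b = make_fixture_stations(DEFAULT_POPULATION, seed)
    paths = {
        "population": outdir / "eastern_europe_synthetic.yaml",
        "station_a": outdir / "station_a_synthetic.yaml",
        "station_b": outdir / "station_b_synthetic.yaml",
    }
    save_population(DEFAULT_POPULATION, paths["population"])
    save_workstation(station_a, paths["station_a"])
    save_workstation(station_b, paths["station_b"])
    return paths
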