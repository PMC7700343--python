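"""Reading and writing of population/workstation specs and result reports.

Config files are YAML; the only units are millimetres (lengths, stated in
every schema via ``*_mm`` keys) and degrees (angles).  Reports are emitted
as JSON with provenance metadata (library version, lookup-table checksums,
random seed) and as aligned plain-text tables.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import yaml

from . import __version__
from .anthropometry import Population, PopulationError
from .kinematics import WorkPoint
from .tables import table_checksums
from .workstation import DesignReport, Workstation, WorkstationConfigError

_DATA = resources.files("rebakit") / "data"


# --------------------------------------------------------------------------
# population specs


def population_to_dict(population: Population) -> dict:
    return {
        "name": population.name,
        "stature_mm": {
            sex: {
                "mean": float(population.stature_mean_mm[sex]),
                "sd": float(population.stature_sd_mm[sex]),
            }
            for sex in population.stature_mean_mm
        },
        "proportions_of_stature": dict(population.proportion_coefficients),
    }


def population_from_dict(doc: dict) -> Population:
    try:
        stature = doc["stature_mm"]
        return Population(
            name=str(doc["name"]),
            stature_mean_mm={sex: float(v["mean"]) for sex, v in stature.items()},
            stature_sd_mm={sex: float(v["sd"]) for sex, v in stature.items()},
            proportion_coefficients={
                k: float(v) for k, v in doc["proportions_of_stature"].items()
            },
        )
    except KeyError as err:
        raise PopulationError(f"population spec is missing key {err}") from None


def load_population(path: str | Path) -> Population:
    with open(path) as fh:
        return population_from_dict(yaml.safe_load(fh))


def save_population(population: Population, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(population_to_dict(population), sort_keys=False))


def default_population() -> Population:
    """The bundled synthetic illustrative population."""
    ref = _DATA / "populations" / "eastern_europe_synthetic.yaml"
    return population_from_dict(yaml.safe_load(ref.read_text()))


# --------------------------------------------------------------------------
# workstation specs


def workstation_to_dict(ws: Workstation) -> dict:
    return {
        "name": ws.name,
        "surface_height_mm": float(ws.surface_height),
        "work_point": {
            "horizontal_offset_mm": float(ws.work_point.horizontal_offset),
            "height_mm": float(ws.work_point.height),
        },
        "adjustable": sorted(ws.adjustable),
    }


def workstation_from_dict(doc: dict) -> Workstation:
    try:
        wp = doc["work_point"]
        return Workstation(
            name=str(doc["name"]),
            surface_height=float(doc["surface_height_mm"]),
            work_point=WorkPoint(
                horizontal_offset=float(wp["horizontal_offset_mm"]),
                height=float(wp["height_mm"]),
            ),
            adjustable=frozenset(doc.get("adjustable", ["surface_height"])),
        )
    except KeyError as err:
        raise WorkstationConfigError(f"workstation spec is missing key {err}") from None


def load_workstation(path: str | Path) -> Workstation:
    with open(path) as fh:
        return workstation_from_dict(yaml.safe_load(fh))


def save_workstation(ws: Workstation, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(workstation_to_dict(ws), sort_keys=False))


def bundled_workstation(which: str) -> Workstation:
    """Load a bundled synthetic fixture station (``"a"`` or ``"b"``)."""
    ref = _DATA / "workstations" / f"station_{which}_synthetic.yaml"
    return workstation_from_dict(yaml.safe_load(ref.read_text()))


# --------------------------------------------------------------------------
# reports


def report_metadata(seed: int | None = None) -> dict:
    return {
        "library": "rebakit",
        "version": __version__,
        "table_checksums": table_checksums(),
        "seed": seed,
    }


def report_json(payload: dict, seed: int | None = None) -> str:
    """Serialise a result payload with provenance metadata, deterministically."""
    doc = {"metadata": report_metadata(seed), **payload}
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def format_table(headers: list[str], rows: Iterable[Iterable[Any]]) -> str:
    """Render an aligned plain-text table (left-aligned text, right-aligned numbers)."""
    rows = [[_fmt(c) for c in row] for row in rows]
    widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
              for i, h in enumerate(headers)]
    out = [
        "  ".join(h.ljust(w) for h, w in zip(headers, widths)),
        "  ".join("-" * w for w in widths),
    ]
    for row in rows:
        out.append("  ".join(c.rjust(w) if _numeric(c) else c.ljust(w)
                             for c, w in zip(row, widths)))
    return "\n".join(out)


def _fmt(cell: Any) -> str:
    if isinstance(cell, float):
        return f"{cell:.1f}"
    return str(cell)


def _numeric(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def render_design_reports(reports: list[DesignReport]) -> str:
    """Aligned text summary of compare_strategies output."""
    rows = []
    for report in reports:
        for entry in report.entries:
            rows.append([
                report.strategy.value,
                f"{report.height_change:+.0f}",
                entry.mannequin_id,
                entry.reba.score_b,
                entry.reba.final_score,
                entry.reba.risk_category,
                f"{entry.eye_to_hand:.0f}",
                "yes" if entry.viewing_ok else "NO",
            ])
    return format_table(
        ["strategy", "dH (mm)", "mannequin", "score B", "final", "risk cat", "eye (mm)", "view ok"],
        rows,
    )
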