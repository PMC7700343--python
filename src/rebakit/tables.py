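"""Loading and integrity checking of the REBA lookup matrices.

The three matrices of the published REBA method are shipped as plain CSV
files in long format and verified against a SHA-256 manifest at load time.
Table A combines trunk (1-5), neck (1-3) and legs (1-4) codes into 60 cells;
Table B combines upper arm (1-6), lower arm (1-2) and wrist (1-3) codes into
36 cells; Table C maps the 144 (score A, score B) pairs to score C.
"""

from __future__ import annotations

import csv
import hashlib
import json
from functools import lru_cache
from importlib import resources

_TABLE_DIR = resources.files("rebakit") / "data" / "tables"


class TableIntegrityError(RuntimeError):
    """A shipped lookup table does not match its recorded checksum."""


def table_checksums() -> dict[str, str]:
    """Return the recorded SHA-256 checksum of each lookup-table CSV."""
    with (_TABLE_DIR / "checksums.json").open() as fh:
        return json.load(fh)


def _read_table(name: str, key_fields: tuple[str, ...], value_field: str) -> dict[tuple[int, ...], int]:
    path = _TABLE_DIR / name
    data = path.read_bytes()
    expected = table_checksums()[name]
    actual = hashlib.sha256(data).hexdigest()
    if actual != expected:
        raise TableIntegrityError(
            f"{name}: checksum {actual} does not match recorded {expected}"
        )
    out: dict[tuple[int, ...], int] = {}
    for row in csv.DictReader(data.decode().splitlines()):
        key = tuple(int(row[f]) for f in key_fields)
        out[key] = int(row[value_field])
    return out


@lru_cache(maxsize=None)
def table_a() -> dict[tuple[int, int, int], int]:
    """Table A: (trunk, neck, legs) -> posture score, 60 cells."""
    return _read_table("table_a.csv", ("trunk", "neck", "legs"), "score")


@lru_cache(maxsize=None)
def table_b() -> dict[tuple[int, int, int], int]:
    """Table B: (upper_arm, lower_arm, wrist) -> posture score, 36 cells."""
    return _read_table("table_b.csv", ("upper_arm", "lower_arm", "wrist"), "score")


@lru_cache(maxsize=None)
def table_c() -> dict[tuple[int, int], int]:
    """Table C: (score A, score B) -> score C, 144 cells."""
    return _read_table("table_c.csv", ("score_a", "score_b"), "score_c")
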