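"""File formats: cell tables, screen tables, GMT gene sets, configs.

Cell tables are TSV with header columns ``strain, replicate, cell_id,
divisions, end_state, division_times``.  The file vocabulary for end states
is {dead, alive} -- "alive" marks a cell still dividing when the experiment
ended and maps to the internal censored state.  ``division_times`` is an
optional semicolon-separated list of minutes from experiment start.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .simulate import CENSORED, DEAD, CellRecord

__all__ = [
    "CellTableError",
    "read_cell_table",
    "write_cell_table",
    "read_gmt",
    "read_gene_list",
    "load_config",
]

CELL_COLUMNS = ["strain", "replicate", "cell_id", "divisions", "end_state", "division_times"]
_STATE_TO_FILE = {DEAD: "dead", CENSORED: "alive"}
_STATE_FROM_FILE = {"dead": DEAD, "alive": CENSORED}


class CellTableError(ValueError):
    """Malformed cell table, with the offending line number."""


def write_cell_table(records: Sequence[CellRecord], path: str | Path) -> None:
    lines = ["\t".join(CELL_COLUMNS)]
    for rec in records:
        times = (
            ";".join(format(t, ".10g") for t in rec.division_times)
            if rec.division_times is not None
            else ""
        )
        lines.append(
            "\t".join(
                [
                    rec.strain_id,
                    rec.replicate_id,
                    rec.cell_id,
                    str(rec.divisions),
                    _STATE_TO_FILE[rec.end_state],
                    times,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cell_table(path: str | Path) -> list[CellRecord]:
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise CellTableError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    required = CELL_COLUMNS[:5]
    if header[: len(required)] != required and set(required) - set(header):
        raise CellTableError(
            f"{path}:1: expected header columns {required}, got {header}"
        )
    idx = {name: header.index(name) for name in header}
    records: list[CellRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise CellTableError(f"{path}:{lineno}: expected >= 5 tab-separated fields")
        try:
            divisions = int(fields[idx["divisions"]])
        except ValueError as exc:
            raise CellTableError(
                f"{path}:{lineno}: divisions must be an integer, got {fields[idx['divisions']]!r}"
            ) from exc
        if divisions < 0:
            raise CellTableError(f"{path}:{lineno}: divisions must be nonnegative")
        state_raw = fields[idx["end_state"]].strip()
        if state_raw not in _STATE_FROM_FILE:
            raise CellTableError(
                f"{path}:{lineno}: end_state must be 'dead' or 'alive', got {state_raw!r}"
            )
        times = None
        if "division_times" in idx and len(fields) > idx["division_times"]:
            raw = fields[idx["division_times"]].strip()
            if raw:
                try:
                    times = tuple(float(t) for t in raw.split(";"))
                except ValueError as exc:
                    raise CellTableError(
                        f"{path}:{lineno}: malformed division_times {raw!r}"
                    ) from exc
        try:
            records.append(
                CellRecord(
                    strain_id=fields[idx["strain"]],
                    replicate_id=fields[idx["replicate"]],
                    cell_id=fields[idx["cell_id"]],
                    divisions=divisions,
                    end_state=_STATE_FROM_FILE[state_raw],
                    division_times=times,
                )
            )
        except ValueError as exc:
            raise CellTableError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise CellTableError(f"{path}: no data rows")
    return records


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: term <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT rows need term, description and >= 1 gene")
        sets[fields[0]] = {g.strip() for g in fields[2:] if g.strip()}
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def read_gene_list(path: str | Path) -> list[str]:
    """One gene identifier per line; blank lines ignored."""
    genes = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    return genes


def load_config(path: str | Path) -> dict:
    """YAML or JSON configuration file."""
    p = Path(path)
    text = p.read_text(encoding="utf-8")
    if p.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
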