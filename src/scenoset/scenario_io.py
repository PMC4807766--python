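"""Reading, validating and writing scenario delta tables and gridded cell tables.

A scenario delta table has one row per climate-change scenario (an AOGCM x
forcing combination) and one column per regional climate delta.  Cell tables
are flat per-cell numeric tables keyed by a ``cell_id`` column; they carry
climatologies, occurrence data and probability maps through the pipeline.

Both formats are plain delimited text (comma or tab) with a header row.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Identifier columns of a scenario table, in canonical order.
ID_COLUMNS = ("center", "model", "sres")


def _sniff_delimiter(path: str | Path) -> str:
    """Pick comma or tab from the header line; explicit override wins upstream."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if header.count("\t") > header.count(","):
        return "\t"
    return ","


@dataclass(frozen=True)
class ScenarioDelta:
    """One climate-change scenario: identifiers plus an ordered map of deltas.

    Temperature deltas are additive (degrees C); precipitation and
    precipitation-ratio deltas are relative (percent).
    """

    center_id: str
    model_id: str
    forcing_id: str
    deltas: Mapping[str, float]

    @property
    def key(self) -> tuple[str, str]:
        """The unique scenario key: (AOGCM name, forcing name)."""
        return (self.model_id, self.forcing_id)

    @property
    def label(self) -> str:
        return f"{self.model_id}:{self.forcing_id}"


@dataclass
class ScenarioTable:
    """An ordered collection of scenarios sharing one delta variable set."""

    scenarios: list[ScenarioDelta]
    variables: list[str]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        for i, s in enumerate(self.scenarios):
            if s.key in seen:
                raise ValidationError(
                    f"duplicate scenario key {s.key} at rows {seen[s.key]} and {i}"
                )
            seen[s.key] = i
            if list(s.deltas.keys()) != list(self.variables):
                raise ValidationError(
                    f"scenario {s.key} variables {list(s.deltas)} differ from "
                    f"table variables {self.variables}"
                )
            for v, x in s.deltas.items():
                if not math.isfinite(x):
                    raise ValidationError(f"non-finite delta {v}={x!r} in scenario {s.key}")

    def __len__(self) -> int:
        return len(self.scenarios)

    @property
    def keys(self) -> list[tuple[str, str]]:
        return [s.key for s in self.scenarios]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.scenarios]

    @property
    def model_ids(self) -> list[str]:
        """Distinct AOGCM names in first-appearance order."""
        return list(dict.fromkeys(s.model_id for s in self.scenarios))

    @property
    def forcing_ids(self) -> list[str]:
        return list(dict.fromkeys(s.forcing_id for s in self.scenarios))

    def delta_matrix(self) -> np.ndarray:
        """n x p array of delta values in table/variable order."""
        return np.array(
            [[s.deltas[v] for v in self.variables] for s in self.scenarios], dtype=float
        )

    def get(self, model_id: str, forcing_id: str) -> ScenarioDelta:
        for s in self.scenarios:
            if s.key == (model_id, forcing_id):
                return s
        raise ValidationError(f"no scenario ({model_id}, {forcing_id}) in table")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"center": s.center_id, "model": s.model_id, "sres": s.forcing_id,
             **{v: s.deltas[v] for v in self.variables}}
            for s in self.scenarios
        ]
        return pd.DataFrame(rows, columns=[*ID_COLUMNS, *self.variables])


def read_scenario_table(path: str | Path, delimiter: str | None = None) -> ScenarioTable:
    """Read a scenario delta table from delimited text.

    The header must name the three id columns (``center``, ``model``,
    ``sres``) and at least one delta column; every non-id column is taken as
    a delta and carried through.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"scenario table not found: {path}")
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"scenario table {path} is missing id column(s) {missing}; "
            f"found columns {list(df.columns)}"
        )
    delta_cols = [c for c in df.columns if c not in ID_COLUMNS]
    if not delta_cols:
        raise ValidationError(f"scenario table {path} has no delta columns")
    scenarios = []
    for i, row in df.iterrows():
        deltas = {}
        for c in delta_cols:
            raw = row[c]
            try:
                deltas[c] = float(str(raw).replace("−", "-"))
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric delta {raw!r} at row {i}, column {c!r} of {path}"
                ) from None
        scenarios.append(
            ScenarioDelta(str(row["center"]), str(row["model"]), str(row["sres"]), deltas)
        )
    return ScenarioTable(scenarios, delta_cols)


def write_scenario_table(table: ScenarioTable, path: str | Path, delimiter: str = ",") -> None:
    table.to_frame().to_csv(path, sep=delimiter, index=False)


def summarize_deltas(table: ScenarioTable) -> dict[str, dict]:
    """Per-variable mean, sample SD, min/max and the scenario keys attaining them.

    Requires at least two scenarios (the sample SD is undefined for one).
    The result is invariant under row permutation.
    """
    if len(table) < 2:
        raise ValidationError("delta summary needs at least 2 scenarios (SD undefined)")
    X = table.delta_matrix()
    keys = table.keys
    out: dict[str, dict] = {}
    for j, v in enumerate(table.variables):
        col = X[:, j]
        imin, imax = int(np.argmin(col)), int(np.argmax(col))
        out[v] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)),
            "min": float(col[imin]),
            "max": float(col[imax]),
            "argmin": keys[imin],
            "argmax": keys[imax],
        }
    return out


def summary_to_json(summary: dict[str, dict]) -> str:
    enc = {v: {**d, "argmin": list(d["argmin"]), "argmax": list(d["argmax"])}
           for v, d in summary.items()}
    return json.dumps(enc, indent=2)


@dataclass
class CellTable:
    """Opaque cell identifiers plus named per-cell numeric columns."""

    cell_ids: np.ndarray
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            dup = pd.Series(self.cell_ids).duplicated()
            raise ValidationError(
                f"duplicate cell ids: {list(pd.Series(self.cell_ids)[dup])[:5]}"
            )
        for name in list(self.columns):
            vec = np.asarray(self.columns[name], dtype=float)
            if vec.shape != (len(self.cell_ids),):
                raise ValidationError(
                    f"column {name!r} has length {vec.shape} but table has "
                    f"{len(self.cell_ids)} cells"
                )
            self.columns[name] = vec

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.columns:
            raise ValidationError(f"cell table has no column {name!r}; has {list(self.columns)}")
        return self.columns[name]

    def with_columns(self, **cols: np.ndarray) -> "CellTable":
        """A copy with columns added or replaced."""
        merged = {**self.columns, **{k: np.asarray(v, dtype=float) for k, v in cols.items()}}
        return CellTable(self.cell_ids.copy(), merged)

    def same_cells(self, other: "CellTable") -> bool:
        return self.n_cells == other.n_cells and bool(
            np.all(self.cell_ids == other.cell_ids)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, **self.columns})


def read_cell_table(path: str | Path, delimiter: str | None = None) -> CellTable:
    """Read a cell table; errors on ragged rows, duplicate ids, non-numeric data."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cell table not found: {path}")
    sep = delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"cell_id": str},
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed cell table {path}: {exc}") from exc
    if "cell_id" not in df.columns:
        raise ValidationError(f"cell table {path} lacks a 'cell_id' column")
    cols = {}
    for c in df.columns:
        if c == "cell_id":
            continue
        vec = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(np.isnan(vec) & df[c].notna().to_numpy())
        if bad.size:
            raise ValidationError(
                f"non-numeric value at row {bad[0]}, column {c!r} of {path}"
            )
        if np.isnan(vec).any():
            raise ValidationError(f"missing value (ragged row?) in column {c!r} of {path}")
        cols[c] = vec
    return CellTable(df["cell_id"].to_numpy(dtype=object), cols)


def write_cell_table(table: CellTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a cell table losslessly (round-trips at full float precision)."""
    # default float formatting is the shortest round-trip repr: exact
    table.to_frame().to_csv(path, sep=delimiter, index=False)
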