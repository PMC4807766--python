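"""Change-field projection of scenario deltas onto a baseline climatology.

Temperature deltas are added; precipitation and precipitation-ratio deltas
are applied as relative (percent) scalings, the ratio being clipped back
into [0, 1] with clip events logged.  Per-cell ensemble percentile fields
summarize a set of projected grids, optionally with per-grid weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .scenario_io import CellTable, ScenarioDelta

log = logging.getLogger("scenoset.projection")

#: delta column -> (grid column, transform). ``additive`` adds the delta;
#: ``relative`` scales by (1 + delta/100); ``relative_clipped`` additionally
#: clips the result into [0, 1].
DELTA_RULES: dict[str, tuple[str, str]] = {
    "dTavg": ("tavg", "additive"),
    "dPrec": ("prec", "relative"),
    "dPrat": ("prat", "relative_clipped"),
}

CLIMATE_VARIABLES = ("tavg", "prec", "prat")


@dataclass
class ClimateGrid:
    """A per-cell climatology (tavg degC, prec mm, prat ratio in [0,1])."""

    cells: CellTable
    period: str = "reference"

    def __post_init__(self) -> None:
        for v in CLIMATE_VARIABLES:
            if v not in self.cells.columns:
                raise ValidationError(f"climate grid lacks column {v!r}")
        if (self.cells["prec"] < 0).any():
            raise ValidationError("negative precipitation in climate grid")
        prat = self.cells["prat"]
        if (prat < 0).any() or (prat > 1).any():
            raise ValidationError("precipitation ratio outside [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.cells.n_cells

    def __getitem__(self, v: str) -> np.ndarray:
        return self.cells[v]


def apply_change_field(baseline: ClimateGrid, delta: ScenarioDelta,
                       rules: dict[str, tuple[str, str]] = DELTA_RULES) -> ClimateGrid:
    """Project a baseline grid under one scenario's deltas.

    Deltas are uniform over cells when scalar; a per-cell array of matching
    length applies a spatially explicit delta field through the same rules.
    The projection is affine per variable and commutes with cell subsetting.
    """
    missing = [d for d in rules if d not in delta.deltas]
    if missing:
        raise ValidationError(
            f"scenario {delta.key} lacks delta(s) {missing} required by the rules"
        )
    n = baseline.n_cells
    new_cols = dict(baseline.cells.columns)
    for dname, (var, kind) in rules.items():
        dval = np.asarray(delta.deltas[dname], dtype=float)
        if dval.ndim not in (0, 1) or (dval.ndim == 1 and dval.shape[0] != n):
            raise ValidationError(f"delta field {dname} has shape {dval.shape}, "
                                  f"expected scalar or ({n},)")
        base = baseline[var]
        if kind == "additive":
            out = base + dval
        elif kind in ("relative", "relative_clipped"):
            factor = 1.0 + dval / 100.0
            if np.any(factor < 0):
                raise ValidationError(
                    f"{dname} <= -100% would make {var!r} negative"
                )
            out = base * factor
            if kind == "relative_clipped":
                clipped = int(((out < 0) | (out > 1)).sum())
                if clipped:
                    log.warning("%s: clipped %d cell(s) of %r into [0, 1] under %s",
                                delta.label, clipped, var, dname)
                out = np.clip(out, 0.0, 1.0)
        else:  # pragma: no cover - rules are a closed vocabulary
            raise ValidationError(f"unknown transform kind {kind!r}")
        new_cols[var] = out
    return ClimateGrid(CellTable(baseline.cells.cell_ids.copy(), new_cols),
                       period=delta.label)


# ---------------------------------------------------------------------------
# Ensemble percentile fields
# ---------------------------------------------------------------------------

def weighted_quantile(values: np.ndarray, q: float,
                      weights: np.ndarray | None = None) -> np.ndarray:
    """Left-continuous inverse of the weighted empirical CDF, along axis 0.

    Returns, per column, the smallest value x with CDF(x) >= q.
    """
    V = np.asarray(values, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
        squeeze = True
    else:
        squeeze = False
    m = V.shape[0]
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (m,) or (w < 0).any() or w.sum() <= 0:
        raise ValidationError("weights must be non-negative, length-matched, not all zero")
    order = np.argsort(V, axis=0, kind="stable")
    sorted_v = np.take_along_axis(V, order, axis=0)
    cumw = np.cumsum(w[order], axis=0)
    target = q * w.sum()
    pick = (cumw >= target - 1e-12).argmax(axis=0)
    out = np.take_along_axis(sorted_v, pick[None, :], axis=0)[0]
    return out[0] if squeeze else out


@dataclass
class EnsemblePercentileField:
    """Per-cell 10th percentile, weighted mean and 90th percentile fields."""

    cell_ids: np.ndarray
    p10: dict[str, np.ndarray]
    mean: dict[str, np.ndarray]
    p90: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for v in self.p10:
            if np.any(self.p10[v] > self.p90[v] + 1e-12):
                raise ValidationError(f"p10 exceeds p90 for variable {v!r}")


def percentile_fields(grids: list[ClimateGrid],
                      weights: np.ndarray | None = None,
                      variables: tuple[str, ...] = CLIMATE_VARIABLES
                      ) -> EnsemblePercentileField:
    """Weighted per-cell mean / 10th / 90th percentile across an ensemble of grids."""
    if not grids:
        raise ValidationError("percentile_fields needs at least one grid")
    first = grids[0]
    for g in grids[1:]:
        if not g.cells.same_cells(first.cells):
            raise ValidationError(f"grid {g.period!r} has a different cell set")
    w = np.ones(len(grids)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (len(grids),):
        raise ValidationError("one weight per grid required")
    p10, mean, p90 = {}, {}, {}
    for v in variables:
        V = np.stack([g[v] for g in grids])          # n_grids x n_cells
        mean[v] = (w[:, None] * V).sum(0) / w.sum()
        p10[v] = weighted_quantile(V, 0.10, w)
        p90[v] = weighted_quantile(V, 0.90, w)
    return EnsemblePercentileField(first.cells.cell_ids.copy(), p10, mean, p90)
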