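"""Synthetic inputs with known ground truth, plus the packaged scenario table.

Everything here is a pure function of its seed so test runs are
bit-reproducible.  The packaged 27-scenario delta table (9 AOGCMs x 3 SRES
forcings, regional deltas for 2071-2100 vs 1961-1990) is embedded verbatim
and guarded by a checksum.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.special import expit

from .errors import ComputationError, ValidationError
from .projection import ClimateGrid
from .scenario_io import CellTable, ScenarioDelta, ScenarioTable
from .sdm import OccurrenceData

# (center, AOGCM, forcing, dTavg degC, dPrec %, dPrat %)
_SCENARIO_ROWS: tuple[tuple[str, str, str, float, float, float], ...] = (
    ("CCCMA", "CGCM3.1 (T47)", "A2", 5.0, 18.2, -4.2),
    ("CCCMA", "CGCM3.1 (T47)", "A1B", 3.9, 15.3, -3.6),
    ("CCCMA", "CGCM3.1 (T47)", "B1", 2.8, 7.7, -3.2),
    ("CNRM", "CM3", "A2", 4.5, 9.4, -4.0),
    ("CNRM", "CM3", "A1B", 3.5, 8.4, -3.1),
    ("CNRM", "CM3", "B1", 2.2, 5.4, -2.5),
    ("CSIRO", "MK3.0", "A2", 3.9, 11.8, -1.6),
    ("CSIRO", "MK3.0", "A1B", 2.8, 6.7, -2.8),
    ("CSIRO", "MK3.0", "B1", 1.8, 4.8, -1.5),
    ("CSIRO", "MK3.5", "A2", 4.7, 11.0, -2.7),
    ("CSIRO", "MK3.5", "A1B", 3.9, 15.4, -0.7),
    ("CSIRO", "MK3.5", "B1", 2.9, 7.3, -2.5),
    ("GFDL", "CM2.0", "A2", 5.2, 3.9, -7.4),
    ("GFDL", "CM2.0", "A1B", 4.3, 9.6, -3.4),
    ("GFDL", "CM2.0", "B1", 2.8, 8.1, -2.0),
    ("IPSL", "CM4", "A2", 6.9, 2.8, -2.4),
    ("IPSL", "CM4", "A1B", 5.8, 5.4, -2.8),
    ("IPSL", "CM4", "B1", 4.2, 1.6, -2.2),
    ("CCSR", "MIROC3.2 (Medres)", "A2", 6.8, -0.8, -9.3),
    ("CCSR", "MIROC3.2 (Medres)", "A1B", 5.8, 3.1, -7.1),
    ("CCSR", "MIROC3.2 (Medres)", "B1", 4.0, 5.7, -5.2),
    ("MIUB", "ECHO-G", "A2", 5.0, 12.6, -0.1),
    ("MIUB", "ECHO-G", "A1B", 4.8, 11.4, -0.2),
    ("MIUB", "ECHO-G", "B1", 3.4, 5.9, 0.3),
    ("MRI", "CGCM2.3.2", "A2", 3.7, 13.7, -1.1),
    ("MRI", "CGCM2.3.2", "A1B", 3.3, 11.0, -1.3),
    ("MRI", "CGCM2.3.2", "B1", 2.5, 8.9, 0.2),
)

SCENARIO_VARIABLES = ("dTavg", "dPrec", "dPrat")

#: sha256 of the canonical serialization of the rows above
SCENARIO_TABLE_SHA256 = (
    "b1fa8dad4dccf718ef05fe03682f88a1234e03593f1514f489a7b3eb433ee870"
)


def _canonical_serialization() -> str:
    return "\n".join(
        "{}|{}|{}|{:.1f}|{:.1f}|{:.1f}".format(*row) for row in _SCENARIO_ROWS
    )


def table2_fixture() -> ScenarioTable:
    """The packaged 27-scenario delta table (checksum-verified)."""
    digest = hashlib.sha256(_canonical_serialization().encode()).hexdigest()
    if digest != SCENARIO_TABLE_SHA256:
        raise ComputationError(
            f"packaged scenario table corrupted (sha256 {digest})"
        )
    scenarios = [
        ScenarioDelta(center, model, sres,
                      dict(zip(SCENARIO_VARIABLES, (dt, dp, dr))))
        for center, model, sres, dt, dp, dr in _SCENARIO_ROWS
    ]
    return ScenarioTable(scenarios, list(SCENARIO_VARIABLES))


# ---------------------------------------------------------------------------
# Synthetic climate landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientSpec:
    """Endpoints of the smooth climate gradients over the unit square.

    Temperature runs south (y=0) to north (y=1); precipitation west to east;
    the useful-precipitation ratio follows a mixed diagonal gradient.
    """

    tavg_south: float = 14.0
    tavg_north: float = -2.0
    prec_west: float = 700.0
    prec_east: float = 1300.0
    prat_low: float = 0.35
    prat_high: float = 0.65
    noise_tavg: float = 0.6
    noise_prec: float = 50.0
    noise_prat: float = 0.02
    smoothing: int = 3           # moving-average kernel width on the lattice


def make_baseline_grid(n_cells: int, spec: GradientSpec | None = None,
                       rng_seed: int = 0) -> ClimateGrid:
    """A reference-period climatology on a near-square lattice of n_cells.

    Smooth multi-gradient fields plus seeded spatially correlated noise
    (white noise passed through a fixed moving-average kernel).  With all
    noise amplitudes zero the gradients are exactly linear in the cell
    coordinates.  Deterministic per seed.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    spec = spec or GradientSpec()
    ncols = max(1, math.ceil(math.sqrt(n_cells)))
    nrows = math.ceil(n_cells / ncols)
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(1,)))

    ii, jj = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    y = ii / max(nrows - 1, 1)
    x = jj / max(ncols - 1, 1)

    def correlated_noise(amp: float) -> np.ndarray:
        white = rng.standard_normal((nrows, ncols))
        return amp * uniform_filter(white, size=spec.smoothing, mode="nearest")

    tavg = spec.tavg_south + (spec.tavg_north - spec.tavg_south) * y
    tavg = tavg + correlated_noise(spec.noise_tavg)
    prec = spec.prec_west + (spec.prec_east - spec.prec_west) * x
    prec = np.maximum(prec + correlated_noise(spec.noise_prec), 1.0)
    prat = spec.prat_low + (spec.prat_high - spec.prat_low) * (0.5 * x + 0.5 * y)
    prat = np.clip(prat + correlated_noise(spec.noise_prat), 0.01, 0.99)

    flat = slice(0, n_cells)
    cell_ids = np.array([f"r{i:03d}c{j:03d}" for i, j in
                         zip(ii.ravel()[flat], jj.ravel()[flat])], dtype=object)
    cells = CellTable(cell_ids, {
        "x": x.ravel()[flat], "y": y.ravel()[flat],
        "tavg": tavg.ravel()[flat], "prec": prec.ravel()[flat],
        "prat": prat.ravel()[flat],
    })
    return ClimateGrid(cells, period="reference")


# ---------------------------------------------------------------------------
# Virtual species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VirtualSpeciesSpec:
    """A logistic occurrence response on z-scored climate covariates.

    True probability = expit(intercept + sum_v linear[v]*z_v
    + sum_v quadratic[v]*z_v^2), sampled as Bernoulli draws.
    """

    intercept: float = 0.3
    linear: dict = field(default_factory=lambda: {"tavg": 3.0, "prec": 1.2})
    quadratic: dict = field(default_factory=lambda: {"tavg": -2.0})
    rng_seed: int = 0


def true_probability(grid: ClimateGrid, spec: VirtualSpeciesSpec,
                     standardizers: dict[str, tuple[float, float]] | None = None
                     ) -> np.ndarray:
    """The species' known occurrence-probability surface on a grid.

    ``standardizers`` (variable -> (mean, sd)) default to the grid's own
    column statistics; pass the baseline grid's statistics when evaluating
    the same species on a projected grid.
    """
    covs = set(spec.linear) | set(spec.quadratic)
    missing = [c for c in covs if c not in grid.cells.columns]
    if missing:
        raise ValidationError(f"grid lacks covariate(s) {missing} used by the species")
    eta = np.full(grid.n_cells, float(spec.intercept))
    if not math.isfinite(spec.intercept):
        raise ValidationError("species intercept must be finite")
    for v in sorted(covs):
        col = grid[v]
        if standardizers and v in standardizers:
            mean, sd = standardizers[v]
        else:
            mean, sd = float(col.mean()), float(col.std(ddof=1))
        z = (col - mean) / (sd if sd > 0 else 1.0)
        eta = eta + spec.linear.get(v, 0.0) * z + spec.quadratic.get(v, 0.0) * z ** 2
    return expit(eta)


def make_virtual_species(grid: ClimateGrid, spec: VirtualSpeciesSpec | None = None
                         ) -> OccurrenceData:
    """Bernoulli occurrences from the species' true probability surface.

    The truth is retained in a ``true_prob`` column for recovery tests.
    Degenerate realized prevalence (all present or all absent) is an error
    advising a coefficient change.
    """
    spec = spec or VirtualSpeciesSpec()
    p = true_probability(grid, spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed, spawn_key=(2,)))
    presence = rng.binomial(1, p).astype(float)
    if presence.sum() in (0, len(presence)):
        raise ValidationError(
            "degenerate realized prevalence; adjust the species coefficients "
            "(e.g. bring the intercept toward 0)"
        )
    cells = grid.cells.with_columns(presence=presence, true_prob=p)
    return OccurrenceData(cells, presence_col="presence",
                          covariate_cols=("tavg", "prec", "prat"))
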