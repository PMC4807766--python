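"""Occurrence-model contract: split-sample calibration, a ridge-stabilized
logistic reference learner, rank-based AUC, and probability-stack projection.

Only one learner ships; the ensemble machinery accepts any number of
"algorithm slots" (learner configurations) and externally supplied
probability stacks, so the split/AUC/consensus plumbing is learner-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .errors import ComputationError, ValidationError
from .projection import ClimateGrid
from .scenario_io import CellTable

DEFAULT_COVARIATES = ("tavg", "prec", "prat")


@dataclass
class OccurrenceData:
    """A cell table holding one binary presence column plus climate covariates."""

    cells: CellTable
    presence_col: str = "presence"
    covariate_cols: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        y = self.cells[self.presence_col]
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValidationError(f"presence column {self.presence_col!r} is not binary")
        for c in self.covariate_cols:
            if c not in self.cells.columns:
                raise ValidationError(f"missing covariate column {c!r}")

    @property
    def n_cells(self) -> int:
        return self.cells.n_cells

    @property
    def presence(self) -> np.ndarray:
        return self.cells[self.presence_col].astype(int)

    def covariates(self) -> np.ndarray:
        return np.column_stack([self.cells[c] for c in self.covariate_cols])


def split_sample(data: OccurrenceData, calib_fraction: float = 0.7, repeats: int = 20,
                 rng_seed: int = 0, max_retries: int = 100,
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated random 70/30 partitions of the cells.

    Each split is redrawn (up to ``max_retries`` times) until both classes
    appear in both halves, so models can be fitted and AUC-evaluated on
    every split.  Deterministic given ``rng_seed``.
    """
    if not 0 < calib_fraction < 1:
        raise ValidationError("calib_fraction must be in (0, 1)")
    n = data.n_cells
    n_cal = round(calib_fraction * n)
    if n_cal == 0 or n_cal == n:
        raise ValidationError(f"calibration fraction {calib_fraction} leaves an empty half")
    y = data.presence
    if y.sum() == 0 or y.sum() == n:
        raise ValidationError("occurrence data needs both presences and absences")
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(0,)))
    splits = []
    for _ in range(repeats):
        for attempt in range(max_retries + 1):
            perm = rng.permutation(n)
            cal, ev = np.sort(perm[:n_cal]), np.sort(perm[n_cal:])
            if 0 < y[cal].sum() < len(cal) and 0 < y[ev].sum() < len(ev):
                splits.append((cal, ev))
                break
        else:
            raise ValidationError(
                f"could not draw a split with both classes in both halves "
                f"after {max_retries} retries"
            )
    return splits


# ---------------------------------------------------------------------------
# Reference learner: ridge-stabilized logistic response via IRLS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LearnerSpec:
    """Configuration of one algorithm slot of the reference learner."""

    name: str
    quadratic: bool = True
    ridge: float = 1e-4


def default_algorithm_slots(n: int = 7) -> list[LearnerSpec]:
    """n distinct reference-learner configurations standing in for an algorithm set."""
    base = [
        LearnerSpec("glm-lin-r4", quadratic=False, ridge=1e-4),
        LearnerSpec("glm-quad-r4", quadratic=True, ridge=1e-4),
        LearnerSpec("glm-lin-r2", quadratic=False, ridge=1e-2),
        LearnerSpec("glm-quad-r2", quadratic=True, ridge=1e-2),
        LearnerSpec("glm-lin-r0", quadratic=False, ridge=1.0),
        LearnerSpec("glm-quad-r0", quadratic=True, ridge=1.0),
        LearnerSpec("glm-quad-r10", quadratic=True, ridge=10.0),
    ]
    if n <= len(base):
        return base[:n]
    extra = [replace(base[i % len(base)], name=f"{base[i % len(base)].name}-x{i}")
             for i in range(len(base), n)]
    return base + extra


def _design(X: np.ndarray, means: np.ndarray, sds: np.ndarray,
            quadratic: bool) -> np.ndarray:
    Zc = (X - means) / sds
    cols = [np.ones(len(X)), *Zc.T]
    if quadratic:
        cols += [z ** 2 for z in Zc.T]
    return np.column_stack(cols)


@dataclass
class FittedModel:
    """A fitted logistic-response occurrence model (one algorithm slot x split)."""

    model_id: str
    coef: np.ndarray
    cov_means: np.ndarray
    cov_sds: np.ndarray
    covariate_cols: tuple[str, ...]
    quadratic: bool
    ridge: float
    converged: bool
    split_id: int = 0
    auc: float = float("nan")
    coef_cov: np.ndarray | None = None

    def feature_names(self) -> list[str]:
        names = ["intercept", *self.covariate_cols]
        if self.quadratic:
            names += [f"{c}^2" for c in self.covariate_cols]
        return names

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return expit(_design(np.asarray(X, dtype=float), self.cov_means,
                             self.cov_sds, self.quadratic) @ self.coef)

    def predict_grid(self, grid: ClimateGrid) -> np.ndarray:
        missing = [c for c in self.covariate_cols if c not in grid.cells.columns]
        if missing:
            raise ValidationError(
                f"grid {grid.period!r} lacks covariate column(s) {missing}"
            )
        X = np.column_stack([grid[c] for c in self.covariate_cols])
        return self.predict_matrix(X)


def fit_reference_model(data: OccurrenceData, indices: np.ndarray | None = None,
                        quadratic: bool = True, ridge: float = 1e-4,
                        max_iter: int = 100, tol: float = 1e-8,
                        model_id: str = "glm", split_id: int = 0) -> FittedModel:
    """Fit the logistic response by iteratively reweighted least squares.

    Covariates are z-scored on the training sample; an L2 penalty of
    ``ridge`` on the non-intercept coefficients bounds the fit under
    complete separation.  Past ``max_iter`` the model is returned with
    ``converged=False`` rather than raising.  Deterministic given the data.
    """
    idx = np.arange(data.n_cells) if indices is None else np.asarray(indices)
    y = data.presence[idx].astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("training sample needs both classes")
    X = data.covariates()[idx]
    means, sds = X.mean(axis=0), X.std(axis=0, ddof=1)
    sds = np.where(sds == 0, 1.0, sds)
    D = _design(X, means, sds, quadratic)
    p = D.shape[1]
    pen = ridge * np.eye(p)
    pen[0, 0] = 0.0
    beta = np.zeros(p)
    converged = False
    H = pen + np.eye(p)
    for _ in range(max_iter):
        mu = expit(D @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = D.T @ (y - mu) - pen @ beta
        H = (D * w[:, None]).T @ D + pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), grad)
        # halve overlong steps to keep IRLS stable under separation
        nrm = np.abs(step).max()
        if nrm > 10.0:
            step *= 10.0 / nrm
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    return FittedModel(model_id, beta, means, sds, data.covariate_cols, quadratic,
                       ridge, converged, split_id, coef_cov=np.linalg.inv(H))


def auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """ROC AUC as the tie-aware Mann-Whitney rank statistic.

    Equals the probability that a random presence outscores a random
    absence, with ties counted one half; invariant under strictly monotone
    transforms of the scores.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth)
    if s.shape != t.shape:
        raise ValidationError("scores and truth differ in length")
    if not np.isin(t, (0, 1)).all():
        raise ValidationError("truth must be binary")
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: truth has a single class")
    ranks = rankdata(s)
    return float((ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def fit_ensemble(data: OccurrenceData, repeats: int = 20,
                 slots: list[LearnerSpec] | None = None,
                 rng_seed: int = 0) -> list[FittedModel]:
    """The split-sample protocol: repeats x slots fitted and AUC-evaluated models."""
    slots = default_algorithm_slots() if slots is None else slots
    splits = split_sample(data, repeats=repeats, rng_seed=rng_seed)
    models = []
    for split_id, (cal, ev) in enumerate(splits):
        for spec in slots:
            m = fit_reference_model(data, indices=cal, quadratic=spec.quadratic,
                                    ridge=spec.ridge,
                                    model_id=f"{spec.name}.s{split_id:02d}",
                                    split_id=split_id)
            scores = m.predict_matrix(data.covariates()[ev])
            m.auc = auc(scores, data.presence[ev])
            models.append(m)
    return models


# ---------------------------------------------------------------------------
# Probability stacks
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityStack:
    """Per-cell occurrence probabilities indexed by (statistical model, scenario).

    ``values`` has shape (n_models, n_scenarios, n_cells); the index grid is
    complete by construction.  ``model_aucs`` carries the per-model AUC
    weights; scenario keys are (AOGCM, forcing) pairs.
    """

    values: np.ndarray
    model_ids: list[str]
    model_aucs: np.ndarray
    scenario_keys: list[tuple[str, str]]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.model_aucs = np.asarray(self.model_aucs, dtype=float)
        self.scenario_keys = [tuple(k) for k in self.scenario_keys]
        nm, ns, nc = self.values.shape
        if len(self.model_ids) != nm or self.model_aucs.shape != (nm,):
            raise ValidationError("model axis metadata does not match values")
        if len(self.scenario_keys) != ns:
            raise ValidationError("scenario axis metadata does not match values")
        if len(self.cell_ids) != nc:
            raise ValidationError("cell axis metadata does not match values")
        if np.any((self.values < 0) | (self.values > 1)) or np.isnan(self.values).any():
            raise ValidationError("stack probabilities must lie in [0, 1]")

    @property
    def n_models(self) -> int:
        return self.values.shape[0]

    @property
    def n_scenarios(self) -> int:
        return self.values.shape[1]

    @property
    def n_cells(self) -> int:
        return self.values.shape[2]

    @property
    def entries_per_cell(self) -> int:
        """The (model, scenario) count aggregated per cell."""
        return self.n_models * self.n_scenarios

    @property
    def aogcms(self) -> list[str]:
        return list(dict.fromkeys(m for m, _ in self.scenario_keys))

    @property
    def forcings(self) -> list[str]:
        return list(dict.fromkeys(f for _, f in self.scenario_keys))

    def subset_scenarios(self, keys: list[tuple[str, str]]) -> "ProbabilityStack":
        pos = {k: i for i, k in enumerate(self.scenario_keys)}
        missing = [k for k in keys if tuple(k) not in pos]
        if missing:
            raise ValidationError(f"stack lacks scenario(s) {missing}")
        sel = [pos[tuple(k)] for k in keys]
        return ProbabilityStack(self.values[:, sel, :], self.model_ids,
                                self.model_aucs, [tuple(k) for k in keys],
                                self.cell_ids)


def stack_to_frame(stack: ProbabilityStack):
    """Long-format export: one row per (cell, model, scenario) probability."""
    import pandas as pd

    nm, ns, nc = stack.values.shape
    mi, sj, ck = np.meshgrid(np.arange(nm), np.arange(ns), np.arange(nc),
                             indexing="ij")
    return pd.DataFrame({
        "cell_id": stack.cell_ids[ck.ravel()],
        "model_id": np.array(stack.model_ids, dtype=object)[mi.ravel()],
        "auc": stack.model_aucs[mi.ravel()],
        "aogcm": np.array([k[0] for k in stack.scenario_keys], dtype=object)[sj.ravel()],
        "sres": np.array([k[1] for k in stack.scenario_keys], dtype=object)[sj.ravel()],
        "p": stack.values.ravel(),
    })


def stack_from_frame(df) -> ProbabilityStack:
    """Rebuild a stack from the long format; the (model, scenario) grid must be complete."""
    required = {"cell_id", "model_id", "auc", "aogcm", "sres", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"stack table lacks column(s) {sorted(missing)}")
    model_ids = list(dict.fromkeys(df["model_id"]))
    keys = list(dict.fromkeys(zip(df["aogcm"], df["sres"])))
    cell_ids = np.array(list(dict.fromkeys(df["cell_id"])), dtype=object)
    nm, ns, nc = len(model_ids), len(keys), len(cell_ids)
    if len(df) != nm * ns * nc:
        raise ValidationError(
            f"stack table has {len(df)} rows; expected complete grid "
            f"{nm} models x {ns} scenarios x {nc} cells = {nm * ns * nc}"
        )
    mpos = {m: i for i, m in enumerate(model_ids)}
    spos = {k: j for j, k in enumerate(keys)}
    cpos = {c: k for k, c in enumerate(cell_ids)}
    values = np.full((nm, ns, nc), np.nan)
    aucs = np.full(nm, np.nan)
    mi = df["model_id"].map(mpos).to_numpy()
    sj = np.array([spos[k] for k in zip(df["aogcm"], df["sres"])])
    ck = df["cell_id"].map(cpos).to_numpy()
    values[mi, sj, ck] = df["p"].to_numpy(dtype=float)
    aucs[mi] = df["auc"].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("stack table has duplicate or missing (model, scenario, cell) entries")
    return ProbabilityStack(values, model_ids, aucs, keys, cell_ids)


def project_stack(models: list[FittedModel], grids: list[ClimateGrid]
                  ) -> ProbabilityStack:
    """Project every fitted model under every scenario grid.

    Grid ``period`` tags of the form ``AOGCM:forcing`` become the scenario
    keys.  All grids must share one cell set.
    """
    if not models or not grids:
        raise ValidationError("need at least one model and one grid")
    first = grids[0]
    keys = []
    for g in grids:
        if not g.cells.same_cells(first.cells):
            raise ValidationError(f"grid {g.period!r} has a mismatched cell set")
        parts = g.period.split(":", 1)
        keys.append(tuple(parts) if len(parts) == 2 else (g.period, ""))
    values = np.empty((len(models), len(grids), first.n_cells))
    for i, m in enumerate(models):
        for j, g in enumerate(grids):
            values[i, j] = m.predict_grid(g)
    return ProbabilityStack(values, [m.model_id for m in models],
                            np.array([m.auc for m in models]), keys,
                            first.cells.cell_ids.copy())
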