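"""Consequences of arbitrary AOGCM selection.

For each q, every (or a capped, seeded subsample of every) q-subset of the
available AOGCMs is turned into an AUC-weighted consensus over the subset's
scenarios (all forcings per AOGCM), binarized with the reference threshold,
and scored as gain/loss percentages; per-q spreads (max - min) summarize
how much the projection depends on the choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .consensus import binarize, consensus_auc_weighted, range_change
from .errors import ValidationError
from .sdm import ProbabilityStack

DEFAULT_COMBINATION_CAP = 10_000


def enumerate_combinations(model_ids: list[str], q: int,
                           cap: int = DEFAULT_COMBINATION_CAP,
                           rng_seed: int = 0) -> list[tuple[str, ...]]:
    """All C(m, q) unordered subsets in lexicographic (input-order) order.

    When C(m, q) exceeds ``cap`` a seeded uniform subsample of ``cap``
    distinct subsets is returned instead, so CMIP5-scale inputs stay finite.
    """
    m = len(model_ids)
    if not 1 <= q <= m:
        raise ValidationError(f"q={q} out of range 1..{m}")
    total = comb(m, q)
    if total <= cap:
        return [tuple(c) for c in itertools.combinations(model_ids, q)]
    rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(q,)))
    seen: set[tuple[int, ...]] = set()
    while len(seen) < cap:
        pick = tuple(sorted(rng.choice(m, size=q, replace=False).tolist()))
        seen.add(pick)
    return [tuple(model_ids[i] for i in pick) for pick in sorted(seen)]


@dataclass
class CombinationRun:
    """Gain/loss outcome of one q-subset of AOGCMs."""

    q: int
    combination: tuple[str, ...]
    gains_pct: float
    losses_pct: float
    n_projections: int           # models x scenarios aggregated per cell


def run_combination(stack: ProbabilityStack, combination: tuple[str, ...],
                    reference_binary, threshold: float,
                    forcings: list[str] | None = None) -> CombinationRun:
    """AUC-weighted consensus of one AOGCM subset, thresholded and scored.

    Every selected AOGCM contributes all available forcings; a missing
    (AOGCM, forcing) pair in the stack is an error listing the gap.
    """
    forcings = stack.forcings if forcings is None else forcings
    wanted = [(m, f) for m in combination for f in forcings]
    have = set(stack.scenario_keys)
    missing = [k for k in wanted if k not in have]
    if missing:
        raise ValidationError(f"stack lacks scenario(s) {missing}")
    sub = stack.subset_scenarios(wanted)
    cons = binarize(consensus_auc_weighted(sub), threshold)
    rc = range_change(reference_binary, cons)
    return CombinationRun(len(combination), tuple(combination),
                          rc.gains_pct, rc.losses_pct, sub.entries_per_cell)


@dataclass
class SpreadSummary:
    """Per-q max-min spreads of gains and losses across combinations."""

    gain_spread: dict[int, float]
    loss_spread: dict[int, float]
    n_runs: dict[int, int]


def spread_summary(runs: list[CombinationRun]) -> SpreadSummary:
    if not runs:
        raise ValidationError("no combination runs to summarize")
    gains: dict[int, list[float]] = {}
    losses: dict[int, list[float]] = {}
    for r in runs:
        gains.setdefault(r.q, []).append(r.gains_pct)
        losses.setdefault(r.q, []).append(r.losses_pct)
    return SpreadSummary(
        {q: max(v) - min(v) for q, v in gains.items()},
        {q: max(v) - min(v) for q, v in losses.items()},
        {q: len(v) for q, v in gains.items()},
    )


def run_sensitivity(stack: ProbabilityStack, reference_binary, threshold: float,
                    qs: list[int] | None = None,
                    cap: int = DEFAULT_COMBINATION_CAP,
                    rng_seed: int = 0) -> tuple[list[CombinationRun], SpreadSummary]:
    """Enumerate and score all q-of-m AOGCM combinations for every requested q."""
    aogcms = stack.aogcms
    qs = list(range(1, len(aogcms) + 1)) if qs is None else list(qs)
    runs = []
    for q in qs:
        for combo in enumerate_combinations(aogcms, q, cap=cap, rng_seed=rng_seed):
            runs.append(run_combination(stack, combo, reference_binary, threshold))
    return runs, spread_summary(runs)
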