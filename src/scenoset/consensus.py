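"""Consensus aggregation of probability stacks, thresholding, and range change.

Two weighting modes are provided: AUC-only (scenarios uniform), used for the
reference period and the full-ensemble future, and the double-weighted mode
where each scenario additionally carries its cluster-size weight so small
clusters are not over-represented:

    xbar* = sum_i sum_j x_ij * (AUC_i / sum_m AUC_m) * (nk_j / sum_p nk_p)

Probabilities are binarized by the sensitivity+specificity maximizing
threshold calibrated on the reference period, and gains/losses are counted
relative to the reference presences under unlimited dispersal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import RepresentativeSet
from .errors import ValidationError
from .sdm import OccurrenceData, ProbabilityStack


@dataclass
class ConsensusMap:
    """A per-cell consensual occurrence probability, optionally thresholded."""

    cell_ids: np.ndarray
    probability: np.ndarray
    provenance: dict = field(default_factory=dict)
    threshold: float | None = None
    binary: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probability = np.asarray(self.probability, dtype=float)
        if self.probability.shape != (len(self.cell_ids),):
            raise ValidationError("probability vector does not match cell ids")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValidationError("consensual probabilities must lie in [0, 1]")


def _model_weights(stack: ProbabilityStack) -> np.ndarray:
    if np.any(stack.model_aucs <= 0):
        raise ValidationError("every model AUC must be > 0 to serve as a weight")
    return stack.model_aucs / stack.model_aucs.sum()


def consensus_auc_weighted(stack: ProbabilityStack) -> ConsensusMap:
    """AUC-weighted mean over models, uniform over scenarios."""
    wm = _model_weights(stack)
    ws = np.full(stack.n_scenarios, 1.0 / stack.n_scenarios)
    prob = np.einsum("ijc,i,j->c", stack.values, wm, ws)
    return ConsensusMap(stack.cell_ids.copy(), np.clip(prob, 0.0, 1.0),
                        provenance={"mode": "auc",
                                    "scenarios": [list(k) for k in stack.scenario_keys],
                                    "n_models": stack.n_models})


def consensus_eq1(stack: ProbabilityStack,
                  representatives: RepresentativeSet) -> ConsensusMap:
    """Double-weighted consensus: AUC over models x cluster size over scenarios.

    The stack's scenario axis must consist of the representative scenarios;
    the joint weights sum to 1 by construction.
    """
    wm = _model_weights(stack)
    sizes = np.array([representatives.size_of(k) for k in stack.scenario_keys],
                     dtype=float)
    if len(stack.scenario_keys) != len(representatives.representatives):
        raise ValidationError(
            f"stack has {len(stack.scenario_keys)} scenarios but the representative "
            f"set has {len(representatives.representatives)}"
        )
    ws = sizes / sizes.sum()
    joint = np.outer(wm, ws)
    assert abs(joint.sum() - 1.0) < 1e-12
    prob = np.einsum("ijc,ij->c", stack.values, joint)
    return ConsensusMap(stack.cell_ids.copy(), np.clip(prob, 0.0, 1.0),
                        provenance={"mode": "eq1",
                                    "scenarios": [list(k) for k in stack.scenario_keys],
                                    "cluster_sizes": sizes.astype(int).tolist(),
                                    "n_models": stack.n_models})


def max_sss_threshold(consensus: ConsensusMap, observed: OccurrenceData) -> float:
    """Threshold maximizing sensitivity + specificity on the reference period.

    Candidates are the distinct consensual probabilities; presence is
    predicted where p >= t; among maximizers the smallest threshold wins.
    """
    if not np.array_equal(consensus.cell_ids, observed.cells.cell_ids):
        raise ValidationError("consensus and observations cover different cells")
    y = observed.presence
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("maxSSS needs both presences and absences")
    p = consensus.probability
    candidates = np.unique(p)
    # sweep candidates in one pass: for t = candidates[c], predictions are
    # p >= t, so sens/spec are suffix/prefix counts over the sorted values
    order = np.argsort(p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    first_idx = np.searchsorted(p_sorted, candidates, side="left")
    cum_pos = np.concatenate([[0], np.cumsum(y_sorted)])
    cum_neg = np.concatenate([[0], np.cumsum(1 - y_sorted)])
    sens = (n_pos - cum_pos[first_idx]) / n_pos      # predicted present: p >= t
    spec = cum_neg[first_idx] / n_neg                # predicted absent: p < t
    score = sens + spec
    best = int(np.flatnonzero(score >= score.max() - 1e-12)[0])
    return float(candidates[best])


def binarize(consensus: ConsensusMap, threshold: float) -> ConsensusMap:
    """Presence where p >= threshold; the threshold provenance is recorded."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    return ConsensusMap(consensus.cell_ids.copy(), consensus.probability.copy(),
                        provenance={**consensus.provenance,
                                    "threshold_source": "reference-period maxSSS"},
                        threshold=float(threshold),
                        binary=(consensus.probability >= threshold).astype(int))


def _binary_of(x) -> np.ndarray:
    if isinstance(x, ConsensusMap):
        if x.binary is None:
            raise ValidationError("consensus map has not been binarized")
        return x.binary
    arr = np.asarray(x)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("binary map must contain only 0/1")
    return arr.astype(int)


@dataclass
class RangeChange:
    """Gain/loss percentages relative to the reference-period presence count."""

    gains_pct: float
    losses_pct: float
    cells_gained: int
    cells_lost: int
    cells_ref: int


def range_change(reference_binary, future_binary) -> RangeChange:
    """Gained = absent at reference, present in future; lost = the converse.

    Both are expressed as percentages of the reference presences (unlimited
    dispersal), so gains may exceed 100%.
    """
    ref = _binary_of(reference_binary)
    fut = _binary_of(future_binary)
    if ref.shape != fut.shape:
        raise ValidationError("reference and future maps cover different cells")
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValidationError("no reference-period presences: gains/losses undefined")
    gained = int(((ref == 0) & (fut == 1)).sum())
    lost = int(((ref == 1) & (fut == 0)).sum())
    return RangeChange(100.0 * gained / n_ref, 100.0 * lost / n_ref,
                       gained, lost, n_ref)


#: category codes of a difference map
AGREE_PRESENCE, AGREE_ABSENCE, ONLY_A, ONLY_B = (
    "agree-presence", "agree-absence", "only-in-a", "only-in-b")


@dataclass
class DifferenceMap:
    """Per-cell 4-way agreement categories between two binary maps."""

    cell_ids: np.ndarray
    category: np.ndarray

    def counts(self) -> dict[str, int]:
        cats, cnt = np.unique(self.category, return_counts=True)
        out = {c: 0 for c in (AGREE_PRESENCE, AGREE_ABSENCE, ONLY_A, ONLY_B)}
        out.update({str(c): int(n) for c, n in zip(cats, cnt)})
        return out


def difference_map(binary_a, binary_b, cell_ids: np.ndarray | None = None
                   ) -> DifferenceMap:
    a = _binary_of(binary_a)
    b = _binary_of(binary_b)
    if a.shape != b.shape:
        raise ValidationError("maps cover different cells")
    if cell_ids is None:
        cell_ids = (binary_a.cell_ids if isinstance(binary_a, ConsensusMap)
                    else np.arange(len(a)).astype(object))
    cat = np.empty(len(a), dtype=object)
    cat[(a == 1) & (b == 1)] = AGREE_PRESENCE
    cat[(a == 0) & (b == 0)] = AGREE_ABSENCE
    cat[(a == 1) & (b == 0)] = ONLY_A
    cat[(a == 0) & (b == 1)] = ONLY_B
    return DifferenceMap(np.asarray(cell_ids, dtype=object), cat)
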