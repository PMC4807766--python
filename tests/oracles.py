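"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written for clarity, not speed, and deliberately avoids
the code paths under test: plain loops, exhaustive enumeration, direct
summation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def pairwise_distance_loop(V: np.ndarray) -> np.ndarray:
    """Naive double-loop Euclidean distance matrix."""
    n = len(V)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            D[a, b] = math.sqrt(sum((V[a, v] - V[b, v]) ** 2
                                    for v in range(V.shape[1])))
    return D


def partitions_into_k(items: list, k: int):
    """Every partition of `items` into exactly k non-empty blocks."""
    if k == 1:
        yield [list(items)]
        return
    if k == len(items):
        yield [[x] for x in items]
        return
    first, rest = items[0], items[1:]
    # first joins an existing block of a (k)-partition of rest
    for part in partitions_into_k(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
    # or forms its own block next to a (k-1)-partition of rest
    for part in partitions_into_k(rest, k - 1):
        yield [[first]] + part


def within_ss(V: np.ndarray, blocks: list[list[int]]) -> float:
    total = 0.0
    for block in blocks:
        pts = V[block]
        c = pts.mean(axis=0)
        total += float(((pts - c) ** 2).sum())
    return total


def best_partition_within_ss(V: np.ndarray, k: int) -> float:
    """Exhaustive minimum within-cluster SS over all k-partitions (n <= ~10)."""
    return min(within_ss(V, p) for p in partitions_into_k(list(range(len(V))), k))


def ward_merges_brute(V: np.ndarray):
    """Agglomerate by recomputing the SS increase of every candidate merge.

    Returns [(members_a, members_b, delta_ss)] in merge order; ties break on
    the smallest active-cluster index pair, matching the implementation.
    """
    clusters: list[list[int] | None] = [[i] for i in range(len(V))]
    merges = []
    for _ in range(len(V) - 1):
        best = (math.inf, -1, -1)
        for i in range(len(clusters)):
            if clusters[i] is None:
                continue
            for j in range(i + 1, len(clusters)):
                if clusters[j] is None:
                    continue
                delta = (within_ss(V, [clusters[i] + clusters[j]])
                         - within_ss(V, [clusters[i]])
                         - within_ss(V, [clusters[j]]))
                if delta < best[0] - 1e-12:
                    best = (delta, i, j)
        delta, i, j = best
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), delta))
        clusters[i] = clusters[i] + clusters[j]
        clusters[j] = None
    return merges


def auc_pair_count(scores: np.ndarray, truth: np.ndarray) -> float:
    """O(n^2) Mann-Whitney pair count, ties worth one half."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def max_sss_sweep(probs: np.ndarray, truth: np.ndarray) -> float:
    """Exhaustive sweep of distinct probabilities; p >= t predicts presence;
    ties -> smallest threshold."""
    best_t, best_score = None, -math.inf
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    for t in sorted(set(probs.tolist())):
        pred = probs >= t
        sens = float((pred & (truth == 1)).sum()) / n_pos
        spec = float((~pred & (truth == 0)).sum()) / n_neg
        if sens + spec > best_score + 1e-12:
            best_score, best_t = sens + spec, t
    return best_t


def eq1_direct(values: np.ndarray, aucs: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Direct nested-loop double-weighted summation per cell."""
    nm, ns, nc = values.shape
    out = np.zeros(nc)
    for c in range(nc):
        acc = 0.0
        for i in range(nm):
            for j in range(ns):
                acc += (values[i, j, c]
                        * (aucs[i] / aucs.sum())
                        * (sizes[j] / sizes.sum()))
        out[c] = acc
    return out
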