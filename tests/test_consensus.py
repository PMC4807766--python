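import numpy as np
import pytest

import oracles
from scenoset.clustering import Representative, RepresentativeSet
from scenoset.consensus import (ConsensusMap, binarize, consensus_auc_weighted,
                                consensus_eq1, difference_map,
                                max_sss_threshold, range_change)
from scenoset.errors import ValidationError
from scenoset.scenario_io import CellTable
from scenoset.sdm import OccurrenceData, ProbabilityStack


def _stack(values, aucs, keys=None):
    values = np.asarray(values, dtype=float)
    nm, ns, nc = values.shape
    keys = keys or [(f"G{j}", "A2") for j in range(ns)]
    return ProbabilityStack(values, [f"m{i}" for i in range(nm)],
                            np.asarray(aucs, dtype=float), keys,
                            np.array([f"c{k}" for k in range(nc)], dtype=object))


def _reps(keys, sizes):
    return RepresentativeSet([
        Representative(j + 1, k, j, s, 0.0)
        for j, (k, s) in enumerate(zip(keys, sizes))])


def _occ(presence, probs_like):
    n = len(presence)
    cells = CellTable(np.array([f"c{k}" for k in range(n)], dtype=object),
                      {"tavg": np.zeros(n), "prec": np.ones(n),
                       "prat": np.full(n, 0.5),
                       "presence": np.asarray(presence, dtype=float)})
    return OccurrenceData(cells)


class TestConsensusAucWeighted:
    def test_equal_aucs_give_plain_mean(self):
        stack = _stack(np.random.default_rng(0).random((3, 4, 5)),
                       [0.7, 0.7, 0.7])
        cons = consensus_auc_weighted(stack)
        np.testing.assert_allclose(cons.probability,
                                   stack.values.mean(axis=(0, 1)))

    def test_single_model_single_scenario_identity(self):
        stack = _stack([[[0.2, 0.9]]], [0.8])
        cons = consensus_auc_weighted(stack)
        np.testing.assert_allclose(cons.probability, [0.2, 0.9])

    def test_three_model_hand_computation(self):
        # one cell, one scenario; AUCs 0.6/0.8/1.0, probabilities 0/0.5/1
        stack = _stack(np.array([[[0.0]], [[0.5]], [[1.0]]]), [0.6, 0.8, 1.0])
        cons = consensus_auc_weighted(stack)
        direct = (0.0 * 0.6 + 0.5 * 0.8 + 1.0 * 1.0) / (0.6 + 0.8 + 1.0)
        assert cons.probability[0] == pytest.approx(direct)

    def test_nonpositive_auc_rejected(self):
        stack = _stack([[[0.5]]], [0.8])
        stack.model_aucs = np.array([0.0])
        with pytest.raises(ValidationError, match="AUC"):
            consensus_auc_weighted(stack)

    def test_probability_within_contributing_range(self):
        rng = np.random.default_rng(1)
        stack = _stack(rng.random((4, 3, 6)), rng.uniform(0.6, 1.0, 4))
        cons = consensus_auc_weighted(stack)
        assert np.all(cons.probability >= stack.values.min(axis=(0, 1)) - 1e-12)
        assert np.all(cons.probability <= stack.values.max(axis=(0, 1)) + 1e-12)


class TestConsensusEq1:
    def test_uniform_weights_reduce_to_mean(self):
        rng = np.random.default_rng(2)
        stack = _stack(rng.random((2, 3, 4)), [0.8, 0.8])
        reps = _reps(stack.scenario_keys, [2, 2, 2])
        cons = consensus_eq1(stack, reps)
        np.testing.assert_allclose(cons.probability,
                                   stack.values.mean(axis=(0, 1)))

    def test_degenerate_weight_selects_single_scenario(self):
        rng = np.random.default_rng(3)
        v = rng.random((1, 1, 5))
        stack = _stack(v, [0.9], keys=[("G0", "A2")])
        cons = consensus_eq1(stack, _reps([("G0", "A2")], [27]))
        np.testing.assert_allclose(cons.probability, v[0, 0])

    def test_two_by_two_matches_four_term_hand_summation(self):
        # 2 models (AUC 0.8, 0.9) x 2 clusters (nk 2, 4), one cell
        v = np.array([[[0.1], [0.3]], [[0.6], [0.9]]])
        stack = _stack(v, [0.8, 0.9], keys=[("A", "A2"), ("B", "A2")])
        cons = consensus_eq1(stack, _reps(stack.scenario_keys, [2, 4]))
        expected = (0.1 * (0.8 / 1.7) * (2 / 6) + 0.3 * (0.8 / 1.7) * (4 / 6)
                    + 0.6 * (0.9 / 1.7) * (2 / 6) + 0.9 * (0.9 / 1.7) * (4 / 6))
        assert cons.probability[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_summation_oracle_on_random_draws(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            nm, ns, nc = rng.integers(1, 5), rng.integers(1, 5), rng.integers(1, 4)
            v = rng.random((nm, ns, nc))
            aucs = rng.uniform(0.5, 1.0, nm)
            sizes = rng.integers(1, 9, ns)
            keys = [(f"G{j}", "A2") for j in range(ns)]
            cons = consensus_eq1(_stack(v, aucs, keys), _reps(keys, sizes))
            np.testing.assert_allclose(
                cons.probability, oracles.eq1_direct(v, aucs, sizes), atol=1e-12)

    def test_missing_cluster_size_errors(self):
        stack = _stack(np.full((1, 2, 1), 0.5), [0.9],
                       keys=[("A", "A2"), ("B", "A2")])
        with pytest.raises(ValidationError):
            consensus_eq1(stack, _reps([("A", "A2")], [3]))

    def test_permutation_invariance_in_both_indices(self):
        rng = np.random.default_rng(5)
        v = rng.random((3, 4, 2))
        aucs = rng.uniform(0.6, 1, 3)
        sizes = np.array([1, 2, 3, 4])
        keys = [(f"G{j}", "A2") for j in range(4)]
        base = consensus_eq1(_stack(v, aucs, keys), _reps(keys, sizes))
        pm, ps = rng.permutation(3), rng.permutation(4)
        permuted = consensus_eq1(
            _stack(v[pm][:, ps], aucs[pm], [keys[j] for j in ps]),
            _reps([keys[j] for j in ps], sizes[ps]))
        np.testing.assert_allclose(base.probability, permuted.probability,
                                   atol=1e-12)

    def test_degenerate_homogeneity_equivalence(self):
        # every cluster member's map equals its representative's map:
        # eq1 over representatives == auc-weighted over the full stack, exactly
        rng = np.random.default_rng(6)
        nm, nc = 3, 8
        aucs = rng.uniform(0.6, 1.0, nm)
        sizes = [3, 1, 2]
        rep_maps = [rng.random((nm, nc)) for _ in sizes]
        rep_keys = [(f"R{j}", "A2") for j in range(len(sizes))]
        full_values = np.stack(
            [m for m, s in zip(rep_maps, sizes) for _ in range(s)], axis=1)
        full_keys = [(f"R{j}_{c}", "A2")
                     for j, s in enumerate(sizes) for c in range(s)]
        full = consensus_auc_weighted(_stack(full_values, aucs, full_keys))
        rep_values = np.stack(rep_maps, axis=1)
        eq1 = consensus_eq1(_stack(rep_values, aucs, rep_keys),
                            _reps(rep_keys, sizes))
        np.testing.assert_allclose(eq1.probability, full.probability, atol=1e-14)


class TestMaxSssThreshold:
    def _cons(self, probs):
        p = np.asarray(probs, dtype=float)
        return ConsensusMap(np.array([f"c{k}" for k in range(len(p))],
                                     dtype=object), p)

    def test_perfect_separation_returns_lowest_presence_probability(self):
        probs = [0.1, 0.2, 0.7, 0.9]
        truth = [0, 0, 1, 1]
        assert max_sss_threshold(self._cons(probs), _occ(truth, probs)) == 0.7

    def test_six_cell_toy_matches_sweep(self):
        probs = np.array([0.2, 0.4, 0.4, 0.6, 0.8, 0.9])
        truth = np.array([0, 1, 0, 1, 0, 1])
        t = max_sss_threshold(self._cons(probs), _occ(truth, probs))
        assert t == oracles.max_sss_sweep(probs, truth)

    def test_all_presence_errors(self):
        with pytest.raises(ValidationError):
            max_sss_threshold(self._cons([0.1, 0.9]), _occ([1, 1], None))

    def test_matches_brute_force_sweep_on_200_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            probs = np.round(rng.random(n), 2)
            truth = rng.integers(0, 2, n)
            if truth.sum() in (0, n):
                truth[0], truth[1] = 0, 1
            got = max_sss_threshold(self._cons(probs), _occ(truth, probs))
            assert got == oracles.max_sss_sweep(probs, truth)


class TestBinarizeAndRangeChange:
    def test_threshold_zero_all_presence(self):
        cons = ConsensusMap(np.array(["a", "b"], dtype=object),
                            np.array([0.0, 0.6]))
        assert binarize(cons, 0.0).binary.tolist() == [1, 1]

    def test_threshold_above_max_all_absence(self):
        cons = ConsensusMap(np.array(["a", "b"], dtype=object),
                            np.array([0.2, 0.6]))
        assert binarize(cons, 0.61).binary.tolist() == [0, 0]

    def test_rethresholding_idempotent(self):
        cons = ConsensusMap(np.array(["a", "b"], dtype=object),
                            np.array([0.2, 0.6]))
        once = binarize(cons, 0.5)
        twice = binarize(once, 0.5)
        np.testing.assert_array_equal(once.binary, twice.binary)

    def test_identical_maps_no_change(self):
        m = np.array([1, 0, 1, 0])
        rc = range_change(m, m)
        assert rc.gains_pct == 0.0 and rc.losses_pct == 0.0

    def test_gains_can_exceed_100(self):
        ref = np.array([1, 1, 0, 0, 0])   # A, B present
        fut = np.array([0, 0, 1, 1, 1])   # C, D, E present
        rc = range_change(ref, fut)
        assert rc.gains_pct == pytest.approx(150.0)
        assert rc.losses_pct == pytest.approx(100.0)

    def test_matches_set_operation_oracle(self):
        rng = np.random.default_rng(8)
        ref = rng.integers(0, 2, 50)
        fut = rng.integers(0, 2, 50)
        if ref.sum() == 0:
            ref[0] = 1
        rc = range_change(ref, fut)
        ref_set = {i for i in range(50) if ref[i]}
        fut_set = {i for i in range(50) if fut[i]}
        assert rc.cells_gained == len(fut_set - ref_set)
        assert rc.cells_lost == len(ref_set - fut_set)
        assert rc.gains_pct == pytest.approx(100 * len(fut_set - ref_set) / len(ref_set))

    def test_zero_reference_presences_error(self):
        with pytest.raises(ValidationError):
            range_change(np.zeros(5, dtype=int), np.ones(5, dtype=int))


class TestEndToEndOnSyntheticLandscape:
    """Reduced-ensemble consensus must track the full ensemble, with
    disagreements concentrated at the probability margins of the range."""

    @pytest.fixture(scope="class")
    @staticmethod
    def maps():
        from scenoset.clustering import cluster_scenarios
        from scenoset.fixtures import (VirtualSpeciesSpec, make_baseline_grid,
                                       make_virtual_species, table2_fixture)
        from scenoset.projection import apply_change_field
        from scenoset.sdm import (default_algorithm_slots, fit_ensemble,
                                  project_stack)
        table = table2_fixture()
        grid = make_baseline_grid(900, rng_seed=11)
        occ = make_virtual_species(grid, VirtualSpeciesSpec(rng_seed=11))
        res = cluster_scenarios(table, k=6, restarts=200, rng_seed=11)
        models = fit_ensemble(occ, repeats=5,
                              slots=default_algorithm_slots(3), rng_seed=11)
        ref_cons = consensus_auc_weighted(project_stack(models, [grid]))
        thr = max_sss_threshold(ref_cons, occ)
        ref_bin = binarize(ref_cons, thr)
        grids = [apply_change_field(grid, s) for s in table.scenarios]
        stack = project_stack(models, grids)
        full = binarize(consensus_auc_weighted(stack), thr)
        rep_stack = stack.subset_scenarios(res.representatives.keys)
        eq1 = binarize(consensus_eq1(rep_stack, res.representatives), thr)
        return ref_bin, full, eq1, thr

    def test_gains_losses_track_within_tolerance_band(self, maps):
        ref_bin, full, eq1, _ = maps
        rc_full = range_change(ref_bin, full)
        rc_eq1 = range_change(ref_bin, eq1)
        # pre-registered band: within 15 percentage points of the full ensemble
        assert abs(rc_eq1.gains_pct - rc_full.gains_pct) < 15.0
        assert abs(rc_eq1.losses_pct - rc_full.losses_pct) < 15.0

    def test_disagreement_cells_sit_near_the_threshold_margin(self, maps):
        _, full, eq1, thr = maps
        diff = difference_map(full, eq1)
        disagree = np.isin(diff.category, ["only-in-a", "only-in-b"])
        if not disagree.any():
            pytest.skip("maps agree everywhere on this fixture draw")
        margin = np.abs(full.probability - thr)
        assert margin[disagree].mean() < margin[~disagree].mean()


class TestDifferenceMap:
    def test_identical_maps_only_agree(self):
        m = np.array([1, 0, 1])
        d = difference_map(m, m)
        counts = d.counts()
        assert counts["only-in-a"] == 0 and counts["only-in-b"] == 0
        assert counts["agree-presence"] == 2 and counts["agree-absence"] == 1

    def test_complementary_maps_only_disagree(self):
        a = np.array([1, 0, 1, 0])
        d = difference_map(a, 1 - a)
        counts = d.counts()
        assert counts["agree-presence"] == 0 and counts["agree-absence"] == 0
        assert counts["only-in-a"] == 2 and counts["only-in-b"] == 2

    def test_categories_partition_cells(self):
        rng = np.random.default_rng(9)
        a, b = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        assert sum(difference_map(a, b).counts().values()) == 30
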