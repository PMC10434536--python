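import itertools

import numpy as np
import pytest

import _oracles as oracle
from noztree import (
    OUT_OF_RANGE,
    BinningSpec,
    CellTable,
    aggregate_marker_attribution,
    evaluate_cell,
    fit_tree_model,
    score_sample,
)
from noztree.inference import _log_probabilities, scores_to_frame
from noztree.io_preprocess import normalize_and_bin


def _all_patterns(J, n_bins):
    return np.array(list(itertools.product(range(n_bins), repeat=J)))


class TestEvaluateCell:
    def test_training_cell_of_minimal_model_has_positive_probability(self):
        pool = CellTable("p", ("a", "b"), np.array([[0.0, 0.0], [1.0, 1.0]]))
        model = fit_tree_model(pool, BinningSpec(2))
        ev = evaluate_cell(model, [0, 0])
        assert ev.probability > 0
        assert not ev.is_zero
        assert ev.zero_factors == ()

    def test_root_hole_yields_zero_with_root_factor(self):
        # y values never reach the top bin of marker a once binned at Nx=4
        pool = CellTable(
            "p", ("a", "b"), np.array([[0.0, 0.0], [0.1, 1.0], [1.0, 0.5]])
        )
        model = fit_tree_model(pool, BinningSpec(4))
        root = model.tree.root
        empty_bins = np.nonzero(model.marginal(root) == 0)[0]
        assert empty_bins.size > 0
        cell = [0] * model.n_markers
        cell[root] = int(empty_bins[0])
        ev = evaluate_cell(model, cell)
        assert ev.is_zero and ev.probability == 0.0
        assert ("root", root) in ev.zero_factors

    def test_sentinel_zeroes_every_touching_factor(self, toy_model):
        cell = [0, 0, 0]
        cell[toy_model.tree.root] = OUT_OF_RANGE
        ev = evaluate_cell(toy_model, cell)
        assert ev.is_zero
        assert any(f[0] == "root" for f in ev.zero_factors)

    def test_dimensionality_mismatch(self, toy_model):
        with pytest.raises(ValueError):
            evaluate_cell(toy_model, [0, 1])

    def test_probabilities_match_first_principles_enumeration(self, toy_model):
        """Every J=3, Nx=2 bin pattern gets the hand-computable tree product."""
        training = [[0, 0, 0], [0, 1, 1], [1, 1, 0], [1, 1, 1]]
        parents = toy_model.tree.parent_map()
        for pattern in _all_patterns(3, 2):
            expected = oracle.tree_support_and_probability(
                training, toy_model.tree.root, parents, pattern
            )
            ev = evaluate_cell(toy_model, pattern)
            assert ev.probability == pytest.approx(expected, rel=1e-12, abs=1e-15)
            assert ev.is_zero == (expected == 0.0)


class TestDistributionProperties:
    @pytest.mark.parametrize("J,n_bins,seed", [(2, 3, 0), (3, 4, 1), (4, 6, 2)])
    def test_probability_sums_to_one_over_all_patterns(self, J, n_bins, seed):
        rng = np.random.default_rng(seed)
        pool = CellTable(
            "p", tuple(f"m{i}" for i in range(J)), rng.normal(size=(500, J))
        )
        model = fit_tree_model(pool, BinningSpec(n_bins))
        logp = _log_probabilities(model, _all_patterns(J, n_bins))
        total = np.exp(logp[np.isfinite(logp)]).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_per_cell_probability_is_rooting_invariant(self):
        rng = np.random.default_rng(3)
        pool = CellTable("p", ("a", "b", "c", "d"), rng.normal(size=(300, 4)))
        model = fit_tree_model(pool, BinningSpec(4))
        patterns = _all_patterns(4, 4)
        ref = _log_probabilities(model, patterns)
        for root in range(1, 4):
            alt = _log_probabilities(model.reroot(root), patterns)
            finite = np.isfinite(ref)
            assert (np.isfinite(alt) == finite).all()
            np.testing.assert_allclose(alt[finite], ref[finite], rtol=1e-12)

    def test_zero_set_matches_support_enumeration(self):
        """probability = 0 exactly when a tree factor's training count is 0."""
        rng = np.random.default_rng(4)
        values = rng.normal(size=(30, 3))  # sparse: many empty joint bins
        pool = CellTable("p", ("a", "b", "c"), values)
        model = fit_tree_model(pool, BinningSpec(3))
        binned, _ = normalize_and_bin(pool, BinningSpec(3))
        training = binned.bin_indices.tolist()
        parents = model.tree.parent_map()
        for pattern in _all_patterns(3, 3):
            expected = oracle.tree_support_and_probability(
                training, model.tree.root, parents, pattern
            )
            assert evaluate_cell(model, pattern).is_zero == (expected == 0.0)

    def test_bin_refinement_only_adds_zeros(self):
        """A cell zero under pairwise-merged bins stays zero at full resolution."""
        rng = np.random.default_rng(5)
        pool = CellTable("p", ("a", "b", "c"), rng.normal(size=(200, 3)))
        fine = fit_tree_model(pool, BinningSpec(8))
        coarse = fine.merge_bins(2)
        for pattern in _all_patterns(3, 8):
            if evaluate_cell(coarse, pattern // 2).is_zero:
                assert evaluate_cell(fine, pattern).is_zero


class TestScoreSample:
    def test_training_pool_scores_zero_noz_on_its_own_model(self, random_table):
        model = fit_tree_model(random_table, BinningSpec(5))
        score = score_sample(model, random_table)
        assert score.n_zero == 0
        assert score.noz_percent == 0.0

    def test_fully_out_of_range_sample_scores_100(self, random_table):
        model = fit_tree_model(
            random_table, BinningSpec(5, oob_policy="zero"), normalization="from_training"
        )
        shifted = CellTable(
            "far", random_table.marker_names, random_table.values + 100.0
        )
        score = score_sample(model, shifted)
        assert score.noz_percent == 100.0

    def test_missing_model_marker_is_an_error(self, random_table):
        model = fit_tree_model(random_table, BinningSpec(4))
        partial = random_table.select_markers(list(random_table.marker_names[:2]))
        with pytest.raises(KeyError):
            score_sample(model, partial)

    def test_extra_markers_are_ignored(self, random_table):
        model = fit_tree_model(
            random_table.select_markers(["m0", "m1", "m2"]), BinningSpec(4)
        )
        score = score_sample(model, random_table)
        assert score.marker_names == ("m0", "m1", "m2")

    def test_n_zero_matches_per_cell_evaluation(self):
        rng = np.random.default_rng(6)
        pool = CellTable("p", ("a", "b", "c"), rng.normal(size=(50, 3)))
        model = fit_tree_model(pool, BinningSpec(4))
        test = CellTable("t", ("a", "b", "c"), rng.normal(size=(200, 3)) * 1.2)
        score = score_sample(model, test)
        binned, _ = normalize_and_bin(test, BinningSpec(4))
        n_zero = sum(
            evaluate_cell(model, row).is_zero for row in binned.bin_indices
        )
        assert score.n_zero == n_zero


class TestAttribution:
    def test_no_zeros_flags_empty(self, random_table):
        model = fit_tree_model(random_table, BinningSpec(4))
        s = score_sample(model, random_table)
        freq, any_zeros = aggregate_marker_attribution([s])
        assert not any_zeros
        assert (freq == 0).all()

    def test_single_zero_edge_splits_half_half(self, toy_model):
        # pattern (1,0,...) with an empty joint bin on one edge only
        patterns = _all_patterns(3, 2)
        for pattern in patterns:
            ev = evaluate_cell(toy_model, pattern)
            edge_zeros = [f for f in ev.zero_factors if f[0] == "edge"]
            if len(ev.zero_factors) == 1 and len(edge_zeros) == 1:
                _, c, p = edge_zeros[0]
                counts = np.zeros(3, dtype=np.int64)
                counts[c] += 1
                counts[p] += 1
                from noztree.inference import SampleScore

                s = SampleScore("x", None, 1, 1, toy_model.marker_names, counts)
                freq, any_zeros = aggregate_marker_attribution([s])
                assert any_zeros
                assert freq[c] == freq[p] == pytest.approx(0.5)
                return
        pytest.skip("toy model exposes no single-edge-zero pattern")

    def test_mixed_model_scores_rejected(self):
        from noztree.inference import SampleScore

        a = SampleScore("a", None, 1, 0, ("x", "y"), np.zeros(2, dtype=np.int64))
        b = SampleScore("b", None, 1, 0, ("x", "z"), np.zeros(2, dtype=np.int64))
        with pytest.raises(ValueError, match="different models"):
            aggregate_marker_attribution([a, b])

    def test_scores_frame_has_contract_columns(self, random_table):
        model = fit_tree_model(random_table, BinningSpec(4))
        df = scores_to_frame([score_sample(model, random_table, label="control")])
        for col in ("sample_id", "label", "n_cells", "n_zero", "noz_percent"):
            assert col in df.columns
        assert all(m in df.columns for m in random_table.marker_names)
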