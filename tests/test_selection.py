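import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mcslbp import (
    ColorSpaceSet,
    FeatureMatrix,
    LBPParams,
    accuracy_curve,
    extract_features,
    interleave_combined,
    rank_bins_global,
    rank_histograms,
    run_strategy,
    select_dimension,
)
from mcslbp.lbp import feature_provenance

from conftest import random_rgb_image


class TestRanking:
    def test_ascending_sort(self):
        r = rank_histograms(np.array([3.0, 1.0, 2.0]))
        assert r.order.tolist() == [1, 2, 0]
        assert r.granularity == "histogram"

    def test_ties_keep_original_order(self):
        r = rank_bins_global(np.array([1.0, 1.0, 0.5, 1.0]))
        assert r.order.tolist() == [2, 0, 1, 3]

    def test_infinite_scores_rank_last(self):
        r = rank_histograms(np.array([np.inf, 0.2, np.inf, 0.1]))
        assert r.order.tolist() == [3, 1, 0, 2]

    def test_reversed_scores_reverse_the_order(self):
        s = np.array([4.0, 3.0, 2.0, 1.0])
        assert rank_bins_global(s).order.tolist() == [3, 2, 1, 0]

    def test_order_is_a_permutation(self, rng):
        s = rng.random(50)
        assert sorted(rank_bins_global(s).order.tolist()) == list(range(50))


class TestInterleaveCombined:
    def test_worked_example_three_histograms_six_bins(self):
        """Three ranked histograms of six bins give six triplet groups, the
        first holding each histogram's best bin in histogram-rank order."""
        hist_order = np.array([2, 0, 1])  # H3 first, then H1, H2
        bin_orders = [np.array([1, 0, 2, 3, 4, 5]),
                      np.array([5, 4, 3, 2, 1, 0]),
                      np.array([0, 1, 2, 3, 4, 5])]
        r = interleave_combined(hist_order, bin_orders)
        assert len(r.order) == 18
        # first triplet: top bin of H3 (bin 0), H1 (bin 1), H2 (bin 5)
        assert r.order[:3].tolist() == [2 * 6 + 0, 0 * 6 + 1, 1 * 6 + 5]
        assert sorted(r.order.tolist()) == list(range(18))

    def test_single_histogram_reduces_to_its_own_bin_order(self):
        bin_order = np.array([3, 1, 0, 2])
        r = interleave_combined(np.array([0]), [bin_order])
        assert r.order.tolist() == bin_order.tolist()

    def test_preserves_within_histogram_bin_order(self, rng):
        M, Q = 5, 8
        hist_order = rng.permutation(M)
        bin_orders = [rng.permutation(Q) for _ in range(M)]
        r = interleave_combined(hist_order, bin_orders)
        for m in range(M):
            mine = [c - m * Q for c in r.order if m * Q <= c < (m + 1) * Q]
            assert mine == bin_orders[m].tolist()

    def test_rejects_non_permutation_bin_order(self):
        with pytest.raises(ValueError):
            interleave_combined(np.array([0]), [np.array([0, 0, 2])])


class TestSelectDimension:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([0.5, 0.9, 0.9, 0.7], 1),  # first maximum wins ties
            ([0.1, 0.2, 0.3], 2),
            ([0.4], 0),
        ],
    )
    def test_first_argmax(self, curve, expected):
        assert select_dimension(np.array(curve)) == expected

    def test_rejects_empty_curve(self):
        with pytest.raises(ValueError):
            select_dimension(np.array([]))


class TestAccuracyCurve:
    def _data(self, rng, n_train=10, n_val=6, d=12):
        Xtr = rng.random((n_train, d))
        ytr = np.array(["a", "b"] * (n_train // 2))
        Xv = rng.random((n_val, d))
        yv = np.array(["a", "b"] * (n_val // 2))
        return Xtr, ytr, Xv, yv

    def test_incremental_equals_from_scratch_at_every_prefix(self, rng):
        Xtr, ytr, Xv, yv = self._data(rng)
        units = [np.array([c]) for c in rng.permutation(12)]
        prefixes, accs = accuracy_curve(units, Xtr, ytr, Xv, yv, block=5)
        for t, acc in zip(prefixes, accs):
            cols = np.concatenate(units[:t])
            dist = cdist(Xv[:, cols], Xtr[:, cols], metric="cityblock")
            pred = ytr[np.argmin(dist, axis=1)]
            assert acc == pytest.approx(np.mean(pred == yv))

    def test_perfect_first_unit_starts_at_one(self):
        Xtr = np.array([[0.0, 0.3], [1.0, 0.1], [0.0, 0.9], [1.0, 0.4]])
        ytr = np.array(["a", "b", "a", "b"])
        Xv = np.array([[0.0, 0.6], [1.0, 0.2]])
        yv = np.array(["a", "b"])
        _, accs = accuracy_curve([np.array([0]), np.array([1])], Xtr, ytr, Xv, yv)
        assert accs[0] == 1.0

    def test_values_bounded_and_stride_subsamples(self, rng):
        Xtr, ytr, Xv, yv = self._data(rng)
        units = [np.array([c]) for c in range(12)]
        prefixes, accs = accuracy_curve(units, Xtr, ytr, Xv, yv, stride=5)
        assert prefixes.tolist() == [5, 10, 12]  # final prefix always evaluated
        assert ((accs >= 0) & (accs <= 1)).all()

    def test_histogram_units_match_bin_units(self, rng):
        """A block unit contributes exactly the sum of its bins' distances."""
        Xtr, ytr, Xv, yv = self._data(rng)
        block_units = [np.arange(0, 6), np.arange(6, 12)]
        p1, a1 = accuracy_curve(block_units, Xtr, ytr, Xv, yv)
        bin_units = [np.array([c]) for c in range(12)]
        p2, a2 = accuracy_curve(bin_units, Xtr, ytr, Xv, yv)
        assert a1[0] == a2[5] and a1[1] == a2[11]

    def test_rejects_empty_validation(self, rng):
        Xtr, ytr, _, _ = self._data(rng)
        with pytest.raises(ValueError):
            accuracy_curve([np.array([0])], Xtr, ytr, np.empty((0, 12)), np.array([]))


@pytest.fixture(scope="module")
def tiny_problem():
    """Small two-space extraction with signal in R: 2 classes x 4 + 4."""
    from mcslbp import SyntheticConfig, generate_arrays

    config = SyntheticConfig(n_classes=2, images_per_class_per_subset=4, size=32,
                             seed=7)
    images, labels, subsets, ids = generate_arrays(config, subsets=("train", "test"))
    spaces = ColorSpaceSet(("RGB", "HSV"))
    fm = extract_features(images, labels, spaces, sample_ids=ids)
    return fm.subset_rows(subsets == "train"), fm.subset_rows(subsets == "test")


class TestRunStrategy:
    def test_none_returns_the_full_feature_set(self, tiny_problem):
        train, val = tiny_problem
        res = run_strategy("none", train, val)
        assert res.selected_dimension == train.n_features == 4608

    @pytest.mark.parametrize("strategy", ["MCSHS", "MCSBS", "MCSHBS"])
    def test_selected_accuracy_at_least_full_dimension(self, tiny_problem, strategy):
        """Argmax over prefixes includes the full set, so the selected
        dimension can never validate worse than no selection."""
        train, val = tiny_problem
        res = run_strategy(strategy, train, val)
        full = run_strategy("none", train, val)
        assert res.best_validation_accuracy >= full.best_validation_accuracy
        assert res.accuracy_curve[select_dimension(res.accuracy_curve)] == \
            res.best_validation_accuracy

    def test_mcshs_prefix_count_bounded_by_histograms(self, tiny_problem):
        train, val = tiny_problem
        res = run_strategy("MCSHS", train, val)
        assert res.granularity == "histogram"
        assert len(res.accuracy_curve) == 18  # delta_max * NS for two spaces
        assert res.selected_dimension == res.selected_units * 256

    def test_mcsbs_evaluates_every_bin_prefix(self, tiny_problem):
        train, val = tiny_problem
        res = run_strategy("MCSBS", train, val, stride=64)
        assert res.evaluated_prefixes[-1] == 4608
        assert res.selected_dimension == res.selected_units

    def test_mcshbs_degenerates_to_provenance_order_on_tied_scores(self):
        """All-equal histogram and bin scores leave the stable ranking in
        original provenance order."""
        rng = np.random.default_rng(0)
        Q = 4
        prov = feature_provenance(ColorSpaceSet(("RGB",)), LBPParams())  # ignored len
        values = rng.random((4, 3 * Q))
        fm = FeatureMatrix(values, ["a", "a", "b", "b"], prov[: 3 * Q])
        from mcslbp.selection import interleave_combined, rank_histograms

        h = rank_histograms(np.zeros(3))
        orders = [np.argsort(np.zeros(Q), kind="stable") for _ in range(3)]
        r = interleave_combined(h.order, orders)
        expected = [m * Q + q for q in range(Q) for m in range(3)]
        assert r.order.tolist() == expected

    def test_unknown_strategy_rejected(self, tiny_problem):
        train, val = tiny_problem
        with pytest.raises(ValueError):
            run_strategy("best", train, val)
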