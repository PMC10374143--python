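"""Resampling suite: worked examples, contracts, and brute-force equivalence
on toy instances.  Large-scale fuzzed oracle equivalence lives in the
acceptance tests."""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pytest

from resamplebench.datasets import MAJORITY, MINORITY, SYNTHETIC, LabeledDataset
from resamplebench.resampling import (
    REGISTRY,
    adasyn,
    all_knn,
    apply_method,
    borderline_smote,
    cnn_condense,
    enn_edit,
    find_tomek_links,
    iht,
    ipf_filter,
    list_methods,
    nearmiss3,
    ncr,
    oss,
    random_oversample,
    random_undersample,
    renn,
    smote,
    smote_then_clean,
    tomek_undersample,
)

from _bruteforce import bf_cnn_store, bf_nearmiss3_kept_majority
from conftest import make_random_dataset, oneD


def imbalanced(rng, n_min=10, n_maj=30, spread=2.0):
    return make_random_dataset(rng, n_min=n_min, n_maj=n_maj, spread=spread)


class TestRandomOversample:
    def test_balanced_input_noop(self, rng):
        d = make_random_dataset(rng, n_min=15, n_maj=15)
        r = random_oversample(d, seed=0)
        assert r.n_added == 0 and r.dataset.n == d.n

    def test_count_arithmetic(self, rng):
        d = imbalanced(rng, n_min=10, n_maj=156)
        r = random_oversample(d, seed=0)
        assert r.added[MINORITY] == 146
        assert r.dataset.minority_count == r.dataset.majority_count == 156

    def test_added_rows_are_copies(self, rng):
        d = imbalanced(rng)
        r = random_oversample(d, seed=1)
        originals = d.X[d.y == MINORITY]
        new = r.dataset.X[r.dataset.provenance == SYNTHETIC]
        for row in new:
            assert (np.abs(originals - row).sum(axis=1) == 0).any()

    def test_empty_class_rejected(self):
        d = LabeledDataset(X=np.zeros((4, 2)), y=[0, 0, 0, 0])
        with pytest.raises(ValueError):
            random_oversample(d, seed=0)


class TestSmote:
    def test_duplicate_minority_points_give_copies(self):
        X = np.vstack([np.zeros((3, 2)) + 7.0, np.random.default_rng(0).normal(size=(9, 2))])
        d = LabeledDataset(X=X, y=[1] * 3 + [0] * 9)
        r = smote(d, k=2, seed=4)
        synth = r.dataset.X[r.dataset.provenance == SYNTHETIC]
        assert np.allclose(synth, 7.0)

    def test_synthetic_on_segment(self):
        d = LabeledDataset(
            X=np.array([[0.0, 0.0], [1.0, 1.0], [5.0, -5.0], [6.0, -6.0], [7.0, -7.0]]),
            y=[1, 1, 0, 0, 0],
        )
        r = smote(d, k=1, seed=5)
        synth = r.dataset.X[r.dataset.provenance == SYNTHETIC]
        assert len(synth) == 1
        # parents are (0,0) and (1,1): the point must be (u, u), u in [0,1]
        assert synth[0, 0] == pytest.approx(synth[0, 1])
        assert 0.0 <= synth[0, 0] <= 1.0

    def test_convexity_general(self, rng):
        d = imbalanced(rng, n_min=12, n_maj=25)
        r = smote(d, seed=6)
        X_min = d.X[d.y == MINORITY]
        lo, hi = X_min.min(axis=0), X_min.max(axis=0)
        synth = r.dataset.X[r.dataset.provenance == SYNTHETIC]
        assert (synth >= lo - 1e-9).all() and (synth <= hi + 1e-9).all()

    def test_single_minority_rejected(self):
        d = LabeledDataset(X=np.arange(10.0).reshape(-1, 1), y=[1] + [0] * 9)
        with pytest.raises(ValueError, match="SMOTE"):
            smote(d, seed=0)


class TestAdasyn:
    def test_allocation_conserved(self, rng):
        d = imbalanced(rng, n_min=9, n_maj=40, spread=1.0)
        r = adasyn(d, seed=7)
        assert r.added[MINORITY] == 40 - 9
        assert r.dataset.minority_count == 40

    def test_balanced_no_budget(self, rng):
        d = make_random_dataset(rng, n_min=12, n_maj=12)
        r = adasyn(d, seed=8)
        assert r.n_added == 0

    def test_mass_on_hard_point(self):
        # one minority point ringed by majority (hardness 1); a far minority
        # cluster whose neighborhoods are purely minority (hardness 0)
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ring = 0.2 * np.column_stack([np.cos(theta), np.sin(theta)])
        far = np.array([[100.0, 100.0 + j] for j in range(4)])
        X = np.vstack([[0.0, 0.0], far, ring])
        y = np.array([1] * 5 + [0] * 8)
        d = LabeledDataset(X=X, y=y)
        from _bruteforce import bf_adasyn_hardness

        assert bf_adasyn_hardness(X, y, k=3) == [1.0, 0.0, 0.0, 0.0, 0.0]
        r = adasyn(d, k=3, seed=9)
        synth = r.dataset.X[r.dataset.provenance == SYNTHETIC]
        assert r.n_added == 3  # the whole budget G = 8 - 5
        # every synthetic point lies on a segment from the origin point to a
        # far minority neighbor, i.e. all mass was seeded at the hard point
        for s in synth:
            ratios = np.abs(s[1] / s[0] - (100.0 + np.arange(4)) / 100.0)
            assert s[0] < 100.0 and ratios.min() < 1e-9


class TestBorderlineSmote:
    def test_far_cluster_no_danger(self, rng, separated_data):
        r = borderline_smote(separated_data, seed=10)
        assert r.n_added == 0
        assert r.dataset.n == separated_data.n

    def test_noise_point_excluded_and_danger_seeds(self):
        # minority noise point at the origin (all-majority neighborhood) plus
        # a genuine borderline minority point at (3, 0) near majority mass
        X = np.array(
            [[0.0, 0.0],  # minority noise
             [0.2, 0.0], [-0.2, 0.0], [0.0, 0.2], [0.0, -0.2], [0.1, 0.1],  # maj ring
             [3.0, 0.0], [3.2, 0.0],  # borderline minority
             [2.8, 0.0], [3.05, -0.2], [2.95, -0.25], [3.1, -0.15],  # nearby majority
             [3.1, 1.0], [2.9, 1.2], [3.0, 1.4], [3.0, 1.6]]  # safe minority
        )
        y = np.array([1, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1])
        d = LabeledDataset(X=X, y=y)
        from _bruteforce import bf_borderline_danger

        danger = bf_borderline_danger(X, y, m=5)
        assert 0 not in danger and len(danger) > 0  # noise excluded, seeds exist
        r = borderline_smote(d, m=5, k=3, seed=11)
        synth = r.dataset.X[r.dataset.provenance == SYNTHETIC]
        assert r.n_added == 2  # majority 9 - minority 7
        # no synthetic point can be seeded at (or interpolated toward) the
        # excluded noise point, so none comes near the origin
        assert np.linalg.norm(synth, axis=1).min() > 1.0


class TestRandomUndersample:
    def test_count_arithmetic(self, rng):
        d = imbalanced(rng, n_min=10, n_maj=156)
        r = random_undersample(d, seed=12)
        assert r.removed[MAJORITY] == 146
        assert r.dataset.majority_count == 10

    def test_minority_never_removed(self, rng):
        d = imbalanced(rng)
        r = random_undersample(d, seed=13)
        assert r.removed[MINORITY] == 0
        assert r.dataset.minority_count == d.minority_count

    def test_balanced_unchanged(self, rng):
        d = make_random_dataset(rng, n_min=14, n_maj=14)
        r = random_undersample(d, seed=14)
        assert r.n_removed == 0


class TestNearMiss3:
    def test_toy_1d(self):
        d = oneD([0.0, 1.0, 2.0, 9.0, 3.0], [0, 0, 0, 0, 1])
        r = nearmiss3(d, m_keep=3)
        kept_majority = sorted(r.dataset.X[r.dataset.y == MAJORITY].ravel())
        # stage 1 retains {0,1,2}; stage 2 keeps n_min=1 closest on average
        assert set(kept_majority).issubset({0.0, 1.0, 2.0})
        assert r.dataset.minority_count == 1

    def test_matches_bruteforce(self, rng):
        for trial in range(5):
            d = imbalanced(np.random.default_rng(trial), n_min=6, n_maj=20)
            r = nearmiss3(d)
            expected = bf_nearmiss3_kept_majority(d.X, d.y)
            kept = sorted(
                i for i in range(d.n)
                if d.y[i] == MAJORITY
                and (np.abs(r.dataset.X - d.X[i]).sum(axis=1) == 0).any()
            )
            assert kept == expected

    def test_output_not_larger(self, rng):
        d = imbalanced(rng)
        r = nearmiss3(d)
        assert r.dataset.majority_count <= d.majority_count


class TestTomek:
    def test_toy_links(self):
        d = oneD([0.0, 0.3, 1.0, 1.1], [0, 1, 0, 0])
        assert find_tomek_links(d) == [(0, 1)]

    def test_single_class_no_links(self):
        d = LabeledDataset(X=np.arange(5.0).reshape(-1, 1), y=[0] * 5)
        assert find_tomek_links(d) == []

    def test_links_are_cross_class(self, blob_data):
        for i, j in find_tomek_links(blob_data):
            assert blob_data.y[i] != blob_data.y[j]

    def test_undersample_removes_majority_member(self):
        d = oneD([0.0, 0.3, 1.0, 1.1], [0, 1, 0, 0])
        r = tomek_undersample(d)
        assert r.removed == {MAJORITY: 1, MINORITY: 0}
        assert 0.0 not in r.dataset.X.ravel()
        assert {0.3, 1.0, 1.1} <= set(r.dataset.X.ravel())

    def test_minority_count_invariant(self, blob_data):
        r = tomek_undersample(blob_data)
        assert r.dataset.minority_count == blob_data.minority_count


class TestEnnFamily:
    def test_toy_removal(self):
        d = oneD([0.0, 0.1, 0.2, 5.0, 4.9, 5.1, 5.2], [0, 0, 0, 0, 1, 1, 1])
        r = enn_edit(d, k=3)
        assert r.removed == {MAJORITY: 1, MINORITY: 0}
        assert 5.0 not in r.dataset.X.ravel()

    def test_separated_clusters_untouched(self, separated_data):
        assert enn_edit(separated_data, k=3).n_removed == 0

    def test_tie_keeps_row(self):
        # k=2: the row at 1.0 sees one neighbor of each class -> tie -> keep
        d = oneD([0.0, 1.0, 1.4, 10.0, 11.0], [0, 1, 1, 0, 0])
        r = enn_edit(d, k=2, edit_class="all")
        assert 1.0 in r.dataset.X.ravel()

    def test_renn_fixed_point_equals_enn(self, separated_data):
        assert np.array_equal(
            renn(separated_data).dataset.X, enn_edit(separated_data).dataset.X
        )

    def test_renn_chained_removal(self):
        # 5.0 falls first; 4.0 becomes isolated next pass and falls second
        d = oneD(
            [0.0, 0.1, 0.2, 0.3, 4.0, 5.0, 5.5, 5.6, 5.7, 5.8],
            [0, 0, 0, 0, 0, 0, 1, 1, 1, 1],
        )
        first = enn_edit(d, k=3)
        assert first.removed[MAJORITY] >= 1
        r = renn(d, k=3)
        assert r.removed[MAJORITY] == 2
        assert {4.0, 5.0}.isdisjoint(set(r.dataset.X.ravel()))

    def test_allknn_k1_equals_enn_k1(self, blob_data):
        assert np.array_equal(
            all_knn(blob_data, k_max=1).dataset.X,
            enn_edit(blob_data, k=1).dataset.X,
        )

    def test_allknn_monotone_in_kmax(self, rng):
        d = imbalanced(rng, n_min=10, n_maj=30, spread=1.0)
        sizes = [all_knn(d, k_max=k).dataset.n for k in (1, 2, 3)]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestCnnOss:
    def test_single_prototype_for_tight_cluster(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.01, (20, 2)) + 10.0, rng.normal(0, 0.5, (5, 2))])
        d = LabeledDataset(X=X, y=[0] * 20 + [1] * 5)
        r = cnn_condense(d, seed=1)
        assert r.dataset.majority_count == 1
        assert r.dataset.minority_count == 5

    def test_store_1nn_consistent(self, blob_data):
        r = cnn_condense(blob_data, seed=2)
        store = r.dataset
        for i in range(blob_data.n):
            dists = np.linalg.norm(store.X - blob_data.X[i], axis=1)
            assert store.y[np.argmin(dists)] == blob_data.y[i]

    def test_matches_bruteforce_store(self, rng):
        for trial in range(5):
            d = imbalanced(np.random.default_rng(100 + trial), n_min=5, n_maj=18, spread=1.0)
            r = cnn_condense(d, seed=trial)
            expected = bf_cnn_store(d.X, d.y, seed=trial)
            kept = sorted(
                i for i in range(d.n)
                if (np.abs(r.dataset.X - d.X[i]).sum(axis=1) == 0).any()
            )
            assert kept == expected

    def test_oss_composition(self, rng):
        d = imbalanced(rng, n_min=8, n_maj=25, spread=1.0)
        condensed = cnn_condense(d, seed=3).dataset
        expected = tomek_undersample(condensed).dataset
        got = oss(d, seed=3).dataset
        assert np.array_equal(got.X, expected.X)

    def test_oss_preserves_minority(self, blob_data):
        assert oss(blob_data, seed=4).dataset.minority_count == blob_data.minority_count


class TestNcr:
    def test_majority_intruder_removed(self):
        d = oneD([0.0, 0.1, 0.2, 5.0, 4.9, 5.1, 5.2], [0, 0, 0, 0, 1, 1, 1])
        r = ncr(d, k=3)
        assert 5.0 not in r.dataset.X.ravel()

    def test_rule_b_removes_neighbors(self):
        # minority point at 1.0 has neighbors 0.9, 1.1 (maj) and 0.0 far;
        # its vote is majority -> both majority neighbors are deleted
        d = oneD([0.9, 1.1, 3.0, 1.0, 3.1, 3.2, 2.9], [0, 0, 0, 1, 1, 1, 1])
        r = ncr(d, k=3)
        assert {0.9, 1.1}.isdisjoint(set(r.dataset.X.ravel()))

    def test_clean_separation_no_removal(self, separated_data):
        assert ncr(separated_data, k=3).n_removed == 0


class TestIht:
    def test_balancing_count(self, rng):
        d = imbalanced(rng, n_min=10, n_maj=40, spread=4.0)
        r = iht(d, seed=15)
        assert r.dataset.majority_count == 10
        assert r.dataset.minority_count == 10

    def test_outlier_removed_first(self):
        rng = np.random.default_rng(1)
        X_min = rng.normal(0, 0.3, (12, 2))
        X_maj = np.vstack([rng.normal(6, 0.3, (14, 2)), [[0.0, 0.0]]])
        d = LabeledDataset(X=np.vstack([X_maj, X_min]), y=[0] * 15 + [1] * 12)
        r = iht(d, target_ratio=12 / 14, seed=16)  # remove exactly 1 majority row
        assert not (np.abs(r.dataset.X - np.array([0.0, 0.0])).sum(axis=1) == 0).any()

    def test_no_removal_when_ratio_met(self, rng):
        d = make_random_dataset(rng, n_min=12, n_maj=12)
        assert iht(d, seed=17).n_removed == 0


class TestFiltering:
    def test_separated_cleaning_is_noop(self, separated_data):
        for cleaner in ("tomek", "enn"):
            r = smote_then_clean(separated_data, cleaner, seed=18)
            assert r.n_removed == 0
            assert r.dataset.minority_count == r.dataset.majority_count

    def test_tomek_variant_reaches_fixed_point(self, rng):
        d = imbalanced(rng, n_min=8, n_maj=24, spread=1.0)
        r = smote_then_clean(d, "tomek", seed=19)
        assert find_tomek_links(r.dataset) == []

    def test_enn_cleaner_edits_both_classes(self):
        # a synthetic point interpolated across majority territory gets cleaned
        rng = np.random.default_rng(2)
        X_min = np.array([[0.0, 0.0], [10.0, 0.0]])
        X_maj = np.column_stack([rng.normal(5.0, 1.2, 30), rng.normal(0.0, 0.3, 30)])
        d = LabeledDataset(X=np.vstack([X_maj, X_min]), y=[0] * 30 + [1, 1])
        r = smote_then_clean(d, "enn", smote_params={"k": 1}, seed=20)
        synth_kept = (r.dataset.provenance == SYNTHETIC).sum()
        assert r.added[MINORITY] == 28
        assert synth_kept < 28  # mid-segment synthetics were deleted

    def test_ipf_noiseless_no_removal(self, separated_data):
        r = ipf_filter(separated_data, seed=21)
        assert r.n_removed == 0

    def test_ipf_removes_planted_label_noise(self):
        rng = np.random.default_rng(3)
        n = 200
        X = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(6, 1, (n, 2))])
        y = np.array([0] * n + [1] * n)
        flip = rng.choice(2 * n, size=20, replace=False)
        y_noisy = y.copy()
        y_noisy[flip] = 1 - y_noisy[flip]
        d = LabeledDataset(X=X, y=y_noisy)
        r = ipf_filter(d, seed=22)
        removed_mask = np.ones(d.n, bool)
        for i in range(d.n):
            if (np.abs(r.dataset.X - d.X[i]).sum(axis=1) == 0).any():
                removed_mask[i] = False
        assert removed_mask[flip].mean() > 0.7  # most flipped rows caught
        assert removed_mask[~np.isin(np.arange(d.n), flip)].mean() < 0.1


class TestContracts:
    _fast_methods = [
        n for n in list_methods() if n not in ("IHT", "SMOTE-IPF")
    ]  # learner-backed methods are covered by the explicit tests above

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n_min=st.integers(2, 10),
        n_maj=st.integers(10, 30),
    )
    def test_count_accounting_on_fuzzed_inputs(self, seed, n_min, n_maj):
        d = make_random_dataset(np.random.default_rng(seed), n_min=n_min, n_maj=n_maj)
        for name in self._fast_methods:
            r = apply_method(name, d, seed=seed)
            out = r.dataset
            assert out.minority_count == n_min + r.added[MINORITY] - r.removed[MINORITY]
            assert out.majority_count == n_maj + r.added[MAJORITY] - r.removed[MAJORITY]
            fam = REGISTRY[name][1]
            if fam == "undersampling":
                assert r.n_added == 0
            if fam == "oversampling":
                assert r.n_removed == 0
            assert (r.dataset.provenance != None).all()  # noqa: E711


    @pytest.mark.parametrize("name", list_methods())
    def test_seed_reproducibility(self, name, rng):
        d = imbalanced(np.random.default_rng(42), n_min=8, n_maj=24)
        a = apply_method(name, d, seed=123)
        b = apply_method(name, d, seed=123)
        assert np.array_equal(a.dataset.X, b.dataset.X)
        assert np.array_equal(a.dataset.y, b.dataset.y)

    @pytest.mark.parametrize("name", list_methods("undersampling"))
    def test_undersampler_subset_contract(self, name):
        d = imbalanced(np.random.default_rng(7), n_min=8, n_maj=24)
        r = apply_method(name, d, seed=5)
        assert r.n_added == 0
        for row in r.dataset.X:
            assert (np.abs(d.X - row).sum(axis=1) == 0).any()

    @pytest.mark.parametrize("name", list_methods("oversampling"))
    def test_oversampler_superset_contract(self, name):
        d = imbalanced(np.random.default_rng(8), n_min=8, n_maj=24)
        r = apply_method(name, d, seed=6)
        assert r.n_removed == 0
        assert r.dataset.n == d.n + r.n_added
        assert np.array_equal(r.dataset.X[: d.n], d.X)  # originals kept first

    def test_registry_families(self):
        assert len(REGISTRY) == 17
        assert len(list_methods("oversampling")) == 4
        assert len(list_methods("undersampling")) == 10
        assert len(list_methods("filtering")) == 3

    def test_unknown_method_rejected(self, blob_data):
        with pytest.raises(KeyError):
            apply_method("SMOTE-PSO", blob_data)
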