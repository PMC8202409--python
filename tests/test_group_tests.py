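"""PERMANOVA, separating coefficients, fold changes, age-threshold scan."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from conftest import rel_from_columns
from pdacmicro.group_tests import (
    NotTestable,
    age_threshold_scan,
    fold_change,
    pairwise_permanova,
    permanova,
    separating_coefficients,
)
from pdacmicro.profiles import ProfileValidationError


def brute_force_pseudo_f(d: np.ndarray, labels) -> float:
    """Independent oracle: explicit double loops over sample pairs."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels))
    ss_t = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_t += d[i, j] ** 2
    ss_t /= n
    ss_w = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for i_pos in range(len(idx)):
            for j_pos in range(i_pos + 1, len(idx)):
                acc += d[idx[i_pos], idx[j_pos]] ** 2
        ss_w += acc / len(idx)
    a = len(groups)
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


def euclidean_1d(points):
    return squareform(pdist(np.asarray(points, dtype=float)[:, None]))


class TestPermanova:
    def test_worked_two_by_two_instance(self):
        # A={0,1}, B={10,11}: SS_T=101, SS_W=1, pseudo-F=200; the 6 label
        # assignments split into 3 distinct partitions, 2/6 as extreme.
        res = permanova(euclidean_1d([0, 1, 10, 11]), ["A", "A", "B", "B"], seed=0)
        assert res.method == "exact"
        assert res.pseudo_F == pytest.approx(200.0, abs=1e-10)
        assert res.p_value == pytest.approx(1 / 3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            x = rng.random((12, 6))
            d = squareform(pdist(x, "braycurtis"))
            labels = rng.permutation(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
            res = permanova(d, labels, n_permutations=49, seed=1)
            assert res.pseudo_F == pytest.approx(
                brute_force_pseudo_f(d, labels), abs=1e-10
            )

    def test_matches_reference_library_statistic(self):
        # skbio's PERMANOVA as an independent implementation of the same F
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(29)
        for _ in range(5):
            x = rng.random((10, 4))
            dm = DistanceMatrix(squareform(pdist(x, "braycurtis")),
                                ids=[str(i) for i in range(10)])
            labels = ["a"] * 5 + ["b"] * 5
            mine = permanova(dm, labels, n_permutations=99, seed=0)
            theirs = skbio_permanova(
                dm, pd.DataFrame({"g": labels}, index=dm.ids), column="g",
                permutations=0,
            )
            assert mine.pseudo_F == pytest.approx(
                float(theirs["test statistic"]), abs=1e-10
            )

    def test_invariant_to_group_renaming(self):
        d = euclidean_1d([0, 1, 5, 6, 10, 11])
        f1 = permanova(d, ["x", "x", "y", "y", "z", "z"], seed=0).pseudo_F
        f2 = permanova(d, ["z", "z", "x", "x", "y", "y"], seed=0).pseudo_F
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_exact_p_is_permutation_p_limit(self):
        # at N=8 all 70 assignments can be enumerated; an independent long
        # random permutation stream must converge to the same tail probability
        rng = np.random.default_rng(31)
        x = rng.random((8, 5))
        d = squareform(pdist(x, "braycurtis"))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        exact = permanova(d, labels, n_permutations=99, seed=0)
        assert exact.method == "exact"
        f_obs = brute_force_pseudo_f(d, labels)
        hits = sum(
            brute_force_pseudo_f(d, labels[rng.permutation(8)]) >= f_obs - 1e-12
            for _ in range(20000)
        )
        assert (1 + hits) / (1 + 20000) == pytest.approx(exact.p_value, abs=0.01)

    def test_p_value_floor_and_r2_range(self):
        res = permanova(euclidean_1d([0, 1, 50, 51, 100, 101]),
                        ["a", "a", "b", "b", "c", "c"], n_permutations=999, seed=0)
        assert res.p_value >= 1 / (res.n_permutations + 1)
        assert 0.0 <= res.R2 <= 1.0

    def test_group_of_one_is_an_error(self):
        with pytest.raises(ProfileValidationError):
            permanova(euclidean_1d([0, 1, 2]), ["a", "a", "b"], seed=0)

    def test_asymmetric_matrix_is_an_error(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ProfileValidationError):
            permanova(d, ["a", "b"], seed=0)


class TestPairwisePermanova:
    @pytest.fixture
    def three_group_dm(self):
        rng = np.random.default_rng(41)
        x = np.concatenate([rng.normal(mu, 1, size=(5, 4)) for mu in (0, 1, 2)])
        ids = [f"s{i}" for i in range(15)]
        return (
            DistanceMatrix(squareform(pdist(x)), ids=ids),
            pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5, index=ids),
        )

    def test_three_groups_give_three_pairs(self, three_group_dm):
        dm, labels = three_group_dm
        res = pairwise_permanova(dm, labels, n_permutations=99, seed=0)
        assert set(res) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_pair_equals_direct_two_group_call(self, three_group_dm):
        dm, labels = three_group_dm
        res = pairwise_permanova(dm, labels, n_permutations=99, seed=5)[("a", "b")]
        members = labels[labels.isin(["a", "b"])]
        sub = dm.filter(list(members.index))
        direct = permanova(sub, members.loc[list(sub.ids)].to_numpy(),
                           n_permutations=99, seed=5)
        assert res.pseudo_F == pytest.approx(direct.pseudo_F, abs=1e-12)
        assert res.p_value == direct.p_value

    def test_degenerate_pair_reported_not_testable(self, three_group_dm):
        dm, labels = three_group_dm
        labels = labels.copy()
        labels[labels == "c"] = "a"
        labels.iloc[-1] = "c"  # group c has a single sample
        res = pairwise_permanova(dm, labels, n_permutations=99, seed=0)
        assert isinstance(res[("a", "c")], NotTestable)
        assert isinstance(res[("b", "c")], NotTestable)
        assert not isinstance(res[("a", "b")], NotTestable)


class TestSeparatingCoefficients:
    def test_hand_computed_contrast(self):
        rel = rel_from_columns(
            {"s1": [0.6, 0.3, 0.1], "s2": [0.4, 0.5, 0.1],
             "s3": [0.1, 0.2, 0.7], "s4": [0.3, 0.2, 0.5]}
        )
        labels = pd.Series(["g1", "g1", "g2", "g2"], index=rel.sample_ids)
        coefs = separating_coefficients(rel, labels, reference="g1")
        # group means: g1=(0.5,0.4,0.1), g2=(0.2,0.2,0.6)
        assert coefs.coefficients["t2"] == pytest.approx(-0.5)
        assert coefs.coefficients["t0"] == pytest.approx(0.3)
        assert coefs.coefficients["t1"] == pytest.approx(0.2)
        assert list(coefs.coefficients.index) == ["t2", "t0", "t1"]
        assert len(coefs.top(2)) == 2

    def test_equal_means_give_zero_and_swap_negates(self):
        rel = rel_from_columns(
            {"s1": [0.5, 0.5], "s2": [0.3, 0.7], "s3": [0.5, 0.5], "s4": [0.3, 0.7]}
        )
        labels = pd.Series(["a", "a", "b", "b"], index=rel.sample_ids)
        forward = separating_coefficients(rel, labels, reference="a")
        assert np.allclose(forward.coefficients, 0.0)
        rel2 = rel_from_columns(
            {"s1": [0.8, 0.2], "s2": [0.1, 0.9], "s3": [0.4, 0.6], "s4": [0.2, 0.8]}
        )
        fwd = separating_coefficients(rel2, labels, reference="a")
        rev = separating_coefficients(rel2, labels, reference="b")
        assert np.allclose(fwd.coefficients, -rev.coefficients[fwd.coefficients.index])

    def test_three_groups_is_an_error(self):
        rel = rel_from_columns({"s1": [1.0], "s2": [1.0], "s3": [1.0]})
        labels = pd.Series(["a", "b", "c"], index=rel.sample_ids)
        with pytest.raises(ProfileValidationError):
            separating_coefficients(rel, labels)


class TestFoldChange:
    def test_ratio_arithmetic(self):
        rel = rel_from_columns({"s1": [0.376, 0.624], "s2": [0.001, 0.999]})
        labels = pd.Series(["g1", "g2"], index=rel.sample_ids)
        fc = fold_change(rel, labels, "t0", groups=("g1", "g2"))
        assert fc.ratio == pytest.approx(376.0)
        assert fc.pseudo_count == 0.0

    def test_equal_means_give_one_and_reciprocal_property(self):
        rel = rel_from_columns(
            {"s1": [0.2, 0.8], "s2": [0.4, 0.6], "s3": [0.3, 0.7], "s4": [0.3, 0.7]}
        )
        labels = pd.Series(["a", "a", "b", "b"], index=rel.sample_ids)
        assert fold_change(rel, labels, "t0", ("a", "b")).ratio == pytest.approx(1.0)
        fwd = fold_change(rel, labels, "t1", ("a", "b"))
        rev = fold_change(rel, labels, "t1", ("b", "a"))
        assert fwd.ratio == pytest.approx(1 / rev.ratio)

    def test_zero_denominator_uses_flagged_pseudo_count(self):
        rel = rel_from_columns({"s1": [0.5, 0.5], "s2": [0.0, 1.0]})
        labels = pd.Series(["a", "b"], index=rel.sample_ids)
        fc = fold_change(rel, labels, "t0", ("a", "b"))
        assert fc.pseudo_count == pytest.approx(0.25)  # half the smallest nonzero
        assert np.isfinite(fc.ratio)

    def test_unknown_taxon_is_an_error(self):
        rel = rel_from_columns({"s1": [1.0], "s2": [1.0]})
        labels = pd.Series(["a", "b"], index=rel.sample_ids)
        with pytest.raises(ProfileValidationError):
            fold_change(rel, labels, "missing", ("a", "b"))


class TestAgeThresholdScan:
    def test_partition_logic(self):
        dm = DistanceMatrix(euclidean_1d([0, 1, 2, 3]), ids=list("wxyz"))
        ages = pd.Series([40, 50, 60, 70], index=list("wxyz"))
        res = age_threshold_scan(dm, ages, thresholds=[55], n_permutations=99, seed=0)
        out = res[55.0]
        assert out.group_sizes == {"young": 2, "old": 2}

    def test_threshold_below_minimum_age_not_testable(self):
        dm = DistanceMatrix(euclidean_1d([0, 1, 2, 3]), ids=list("wxyz"))
        ages = pd.Series([60, 61, 62, 63], index=list("wxyz"))
        res = age_threshold_scan(dm, ages, thresholds=[30, 61], n_permutations=99, seed=0)
        assert isinstance(res[30.0], NotTestable)
        assert not isinstance(res[61.0], NotTestable)

    def test_all_one_sided_everywhere_is_an_error(self):
        dm = DistanceMatrix(euclidean_1d([0, 1, 2, 3]), ids=list("wxyz"))
        ages = pd.Series([80, 81, 82, 83], index=list("wxyz"))
        with pytest.raises(ProfileValidationError):
            age_threshold_scan(dm, ages, thresholds=[30, 40], n_permutations=99, seed=0)
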