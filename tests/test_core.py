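"""Unit and property tests for the exceedance / GRP / aGRP statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regprob import core
from regprob.core import (
    agrp_statistic,
    compute_statistics,
    exceedance_proportions,
    grp_statistic,
    regulation_status_profile,
    statistics_frame,
)

from conftest import brute_force_pair_count, make_dataset


class TestExceedanceProportions:
    @pytest.mark.parametrize(
        "tumor,normal,l_exp,k_exp",
        [
            ([3, 1], [2, 4], [0.5, 0.0], [0.5, 0.0]),
            ([5, 3], [1, 2], [1.0, 1.0], [1.0, 1.0]),  # complete separation
            ([7, 7], [7, 7], [1.0, 1.0], [1.0, 1.0]),  # all ties count both ways
        ],
    )
    def test_indicator_counting(self, tumor, normal, l_exp, k_exp):
        props = exceedance_proportions(tumor, normal)
        np.testing.assert_allclose(props.l, l_exp)
        np.testing.assert_allclose(props.k, k_exp)

    def test_values_are_grid_multiples(self, rng):
        t, c = rng.normal(size=7), rng.normal(size=5)
        props = exceedance_proportions(t, c)
        np.testing.assert_allclose(props.l * 5, np.round(props.l * 5))
        np.testing.assert_allclose(props.k * 7, np.round(props.k * 7))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            exceedance_proportions([1.0], [])


class TestRegulationProfile:
    def test_tau_07_zeros_middling_samples(self):
        props = exceedance_proportions([3, 1], [2, 4])
        r = regulation_status_profile(props, tau=0.7).r
        np.testing.assert_array_equal(r, [0, -1, 0, -1])

    def test_tau_05_has_no_zeros(self):
        props = exceedance_proportions([3, 1], [2, 4])
        r = regulation_status_profile(props, tau=0.5).r
        np.testing.assert_array_equal(r, [1, -1, 1, -1])
        assert (r != 0).all()

    def test_complete_separation_all_up(self):
        props = exceedance_proportions([5, 3], [1, 2])
        r = regulation_status_profile(props, tau=0.9).r
        np.testing.assert_array_equal(r, [1, 1, 1, 1])

    @pytest.mark.parametrize("tau", [0.4, 1.1, -1])
    def test_tau_out_of_range(self, tau):
        props = exceedance_proportions([3, 1], [2, 4])
        with pytest.raises(ValueError, match="tau"):
            regulation_status_profile(props, tau)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_tau_half_never_zero(self, seed):
        g = np.random.default_rng(seed)
        props = exceedance_proportions(g.normal(size=6), g.normal(size=4))
        assert (regulation_status_profile(props, tau=0.5).r != 0).all()


class TestGrpStatistic:
    def test_mixed_gene_leans_down(self):
        # tumor [3,1] vs normal [2,4]: two -1 votes at tau=0.7, no +1 votes,
        # agreeing in sign and magnitude with the cutoff-free estimate (-0.5)
        props = exceedance_proportions([3, 1], [2, 4])
        rp = grp_statistic(regulation_status_profile(props, 0.7), 2, 2)
        assert (rp.p_up, rp.p_down, rp.T) == (0.0, 0.5, -0.5)
        assert rp.p_up + rp.p_down == 0.5  # S < 1 at tau > 0.5

    def test_tau_half_sums_to_one(self):
        props = exceedance_proportions([3, 1], [2, 4])
        rp = grp_statistic(regulation_status_profile(props, 0.5), 2, 2)
        assert rp.p_up + rp.p_down == 1.0  # S = 1 at tau = 0.5
        assert rp.T == 0.0

    def test_complete_separation_is_maximal(self):
        props = exceedance_proportions([5, 3], [1, 2])
        rp = grp_statistic(regulation_status_profile(props, 0.5), 2, 2)
        assert rp.T == 1.0

    def test_profile_length_checked(self):
        props = exceedance_proportions([3, 1], [2, 4])
        prof = regulation_status_profile(props, 0.5)
        with pytest.raises(ValueError, match="length"):
            grp_statistic(prof, 3, 3)


class TestAgrpStatistic:
    def test_worked_example(self):
        props = exceedance_proportions([3, 1], [2, 4])
        rp = agrp_statistic(props, 2, 2)
        assert (rp.p_up, rp.p_down, rp.T) == (0.25, 0.75, -0.5)

    def test_complete_separation(self):
        props = exceedance_proportions([5, 3], [1, 2])
        assert agrp_statistic(props, 2, 2).T == 1.0

    def test_constant_gene_pathology(self):
        # ties count as exceedance both ways, so a constant gene scores T = 1;
        # the CV filter exists to remove such genes before analysis
        props = exceedance_proportions([4.2, 4.2], [4.2, 4.2])
        assert agrp_statistic(props, 2, 2).T == 1.0

    def test_matches_pair_count_oracle_many_instances(self, rng):
        """aGRP T equals 2 U/(n m) - 1 with U counted by brute force."""
        for _ in range(1000):
            n, m = rng.integers(1, 9, size=2)
            t, c = rng.normal(size=n), rng.normal(size=m)
            U = brute_force_pair_count(t, c)
            rp = agrp_statistic(exceedance_proportions(t, c), n, m)
            assert rp.T == pytest.approx(2 * U / (n * m) - 1, abs=1e-12)
            assert rp.p_up + rp.p_down == pytest.approx(1.0, abs=1e-12)


class TestMatrixStatistics:
    def test_per_gene_application(self, toy_dataset):
        recs = compute_statistics(toy_dataset, method="agrp")
        assert [r.T for r in recs] == [-0.5, 1.0]

    def test_grp_requires_tau(self, toy_dataset):
        with pytest.raises(ValueError, match="tau"):
            statistics_frame(toy_dataset, method="grp")

    def test_unknown_method(self, toy_dataset):
        with pytest.raises(ValueError, match="method"):
            statistics_frame(toy_dataset, method="wilcoxon")

    def test_antisymmetry_under_label_swap(self, rng):
        ds = make_dataset(rng.normal(size=(40, 6)), rng.normal(size=(40, 8)))
        T = statistics_frame(ds, "agrp")["T"].to_numpy()
        T_sw = statistics_frame(ds.with_classes_swapped(), "agrp")["T"].to_numpy()
        np.testing.assert_allclose(T, -T_sw, atol=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3, lambda x: 5 * x - 2])
    def test_monotone_invariance(self, rng, transform):
        X = rng.normal(size=(30, 12))
        ds = make_dataset(X[:, :5], X[:, 5:])
        ds2 = make_dataset(transform(X[:, :5]), transform(X[:, 5:]))
        for method, tau in [("agrp", None), ("grp", 0.7)]:
            np.testing.assert_allclose(
                statistics_frame(ds, method, tau)["T"],
                statistics_frame(ds2, method, tau)["T"],
                atol=1e-12,
            )

    def test_ranges_and_complementarity(self, rng):
        ds = make_dataset(rng.normal(size=(50, 7)), rng.normal(size=(50, 5)))
        fa = statistics_frame(ds, "agrp")
        assert ((fa["T"] >= -1) & (fa["T"] <= 1)).all()
        np.testing.assert_allclose(fa["p_up"] + fa["p_down"], 1.0, atol=1e-12)
        fg5 = statistics_frame(ds, "grp", 0.5)
        np.testing.assert_allclose(fg5["p_up"] + fg5["p_down"], 1.0, atol=1e-12)
        fg9 = statistics_frame(ds, "grp", 0.9)
        assert (fg9["p_up"] + fg9["p_down"] <= 1 + 1e-12).all()

    def test_grp_tau_half_is_sign_vote_of_agrp_components(self, rng):
        # at tau = 0.5 each sample votes the sign of its exceedance
        # proportion relative to 1/2, a coarsening of the adaptive average
        ds = make_dataset(rng.normal(size=(20, 9)), rng.normal(size=(20, 9)))
        Tg = statistics_frame(ds, "grp", 0.5)["T"]
        Ta = statistics_frame(ds, "agrp")["T"]
        # same sign where the vote is decisive
        decisive = Tg.abs() > 0.5
        assert (np.sign(Tg[decisive]) == np.sign(Ta[decisive])).all()
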