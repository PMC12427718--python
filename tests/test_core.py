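"""Unit and property tests for the i2SFCA-TH accessibility equations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teleaccess import (
    AccessProfile,
    CostMatrix,
    DecaySpec,
    DemandDivision,
    ModelParams,
    SupplySite,
    Tier,
    assign_online_preference,
    combined_accessibility,
    compute_profile,
    decay_weight,
    demand_vector,
    offline_accessibility,
    online_accessibility,
    referral_accessibility,
    supply_ratio,
)
from conftest import random_instance


class TestDecayWeight:
    @pytest.mark.parametrize(
        "d, spec, expected",
        [
            (1.0, DecaySpec(beta=2.0), 1.0),
            (2.0, DecaySpec(beta=2.0), 0.25),
            (5.0, DecaySpec(beta=2.0, d0=3.0), 0.0),  # beyond catchment
            (3.0, DecaySpec(beta=2.0, d0=3.0), 1.0 / 9.0),  # at the cutoff, inside
            (7.0, DecaySpec(beta=0.0), 1.0),  # no decay
            (0.0, DecaySpec(beta=2.0, d_floor=0.1), 100.0),  # floored
        ],
    )
    def test_values(self, d, spec, expected):
        assert decay_weight(d, spec) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            decay_weight(-1.0, DecaySpec())

    def test_vectorized(self):
        w = decay_weight(np.array([1.0, 2.0, 4.0]), DecaySpec(beta=2.0))
        assert np.allclose(w, [1.0, 0.25, 0.0625])


class TestSupplyRatio:
    def _divisions(self, pops):
        return [
            DemandDivision(id=f"k{i}", pop_total=p, pop_elderly=p, pop_chronic=p)
            for i, p in enumerate(pops)
        ]

    def _costs(self, dists):
        import pandas as pd

        return CostMatrix(
            pd.DataFrame([dists], index=["s"], columns=[f"k{i}" for i in range(len(dists))])
        )

    def test_basic_ratio(self):
        site = SupplySite(id="s", tier=Tier.community, resource_offline=10.0)
        r = supply_ratio(site, self._divisions([100, 100]), self._costs([1.0, 2.0]), d0=5.0)
        assert r == pytest.approx(0.05)

    def test_zero_supply(self):
        site = SupplySite(id="s", tier=Tier.community, resource_offline=0.0)
        assert supply_ratio(site, self._divisions([100]), self._costs([1.0]), d0=5.0) == 0.0

    def test_three_divisions_within_threshold(self):
        site = SupplySite(id="s", tier=Tier.community, resource_offline=12.0)
        r = supply_ratio(
            site, self._divisions([100, 200, 300]), self._costs([1.0, 2.0, 3.0]), d0=10.0
        )
        assert r == pytest.approx(12 / 600)

    def test_empty_catchment_warns_and_zero(self):
        site = SupplySite(id="s", tier=Tier.community, resource_offline=5.0)
        with pytest.warns(UserWarning, match="no demand within catchment"):
            r = supply_ratio(site, self._divisions([100]), self._costs([9.0]), d0=1.0)
        assert r == 0.0


class TestOfflineAccessibility:
    def test_two_division_toy(self, toy):
        a = offline_accessibility(toy.community_sites, toy.divisions, toy.costs, DecaySpec(beta=2.0))
        assert np.allclose(a, [0.08, 0.02])
        # gravity conservation: weighted demand recovers the supply
        m = demand_vector(toy.divisions, "chronic")
        assert m @ a == pytest.approx(12.0)

    def test_beta_zero_uniform(self, lubei_like):
        inst = lubei_like
        a = offline_accessibility(inst.sites, inst.divisions, inst.costs, DecaySpec(beta=0.0))
        m = demand_vector(inst.divisions, "chronic")
        total_s = sum(s.resource_offline for s in inst.sites)
        assert np.allclose(a, total_s / m.sum())

    def test_symmetric_instance_equal(self, uniform):
        a = offline_accessibility(
            uniform.community_sites, uniform.divisions, uniform.costs, DecaySpec()
        )
        assert np.allclose(a, a[0])

    def test_threshold_consistency_with_summed_ratios(self, lubei_like):
        """With d0 = inf and beta = 0 the summed catchment ratios equal the
        gravity formula on the same instance."""
        inst = lubei_like
        spec = DecaySpec(beta=0.0, d0=None)
        a = offline_accessibility(inst.sites, inst.divisions, inst.costs, spec)
        summed = sum(
            supply_ratio(s, inst.divisions, inst.costs, d0=np.inf) for s in inst.sites
        )
        assert np.allclose(a, summed)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_conservation_and_homogeneity(self, seed):
        """sum_k M_k a_k = sum_j S_j, and scaling supply scales accessibility."""
        rng = np.random.default_rng(seed)
        inst = random_instance(rng)
        spec = DecaySpec(beta=2.0)
        a = offline_accessibility(inst.community_sites, inst.divisions, inst.costs, spec)
        m = demand_vector(inst.divisions, "chronic")
        total_s = sum(s.resource_offline for s in inst.community_sites)
        assert m @ a == pytest.approx(total_s, rel=1e-9)
        c = 3.7
        scaled = offline_accessibility(
            inst.community_sites,
            inst.divisions,
            inst.costs,
            spec,
            resources=[c * s.resource_offline for s in inst.community_sites],
        )
        assert np.allclose(scaled, c * a, rtol=1e-12)


class TestReferral:
    def test_endpoints(self):
        a_c, a_t = np.array([0.08, 0.3]), np.array([0.02, 0.5])
        assert np.array_equal(referral_accessibility(a_c, a_t, 0.0), a_c)
        assert np.array_equal(referral_accessibility(a_c, a_t, 1.0), a_t)

    def test_midpoint(self):
        out = referral_accessibility(np.array([0.08]), np.array([0.02]), 0.5)
        assert out[0] == pytest.approx(0.05)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            referral_accessibility(np.zeros(2), np.zeros(3), 0.2)

    def test_referral_conservation(self):
        """Demand-weighted referral index recovers (1-r) S_total + r T_total."""
        rng = np.random.default_rng(42)
        inst = random_instance(rng)
        spec = DecaySpec()
        a_c = offline_accessibility(inst.community_sites, inst.divisions, inst.costs, spec)
        a_t = offline_accessibility(inst.tertiary_sites, inst.divisions, inst.costs, spec)
        r = 0.3
        m = demand_vector(inst.divisions, "chronic")
        total = m @ referral_accessibility(a_c, a_t, r)
        s_tot = sum(s.resource_offline for s in inst.community_sites)
        t_tot = sum(s.resource_offline for s in inst.tertiary_sites)
        assert total == pytest.approx((1 - r) * s_tot + r * t_tot, rel=1e-9)


class TestOnlineAccessibility:
    def _divs(self):
        return [
            DemandDivision(id="k1", pop_total=1, pop_elderly=1, pop_chronic=100, q_online=0.35),
            DemandDivision(id="k2", pop_total=1, pop_elderly=1, pop_chronic=200, q_online=0.1),
        ]

    def test_as_printed_hand_value(self):
        # sum QM = 0.35*100 + 0.1*200 = 55
        a = online_accessibility([6.0], self._divs(), mode="as_printed")
        assert np.allclose(a, [6 * 0.35 / 55, 6 * 0.1 / 55])

    def test_equal_q_cancels(self):
        divs = [
            DemandDivision(id=f"k{i}", pop_total=1, pop_elderly=1, pop_chronic=m, q_online=0.25)
            for i, m in enumerate([100, 300, 600])
        ]
        a = online_accessibility([5.0, 5.0], divs, mode="as_printed")
        assert np.allclose(a, 10.0 / 1000.0)

    def test_zero_pool_and_zero_demand(self):
        assert np.all(online_accessibility([0.0], self._divs()) == 0.0)
        divs0 = [
            DemandDivision(id="k1", pop_total=1, pop_elderly=1, pop_chronic=100, q_online=0.0)
        ]
        assert np.all(online_accessibility([9.0], divs0) == 0.0)

    def test_conserving_mode_conserves(self):
        divs = self._divs()
        a = online_accessibility([6.0], divs, mode="conserving")
        m = demand_vector(divs, "chronic")
        q = np.array([d.q_online for d in divs])
        assert (m * q) @ a == pytest.approx(6.0, rel=1e-9)

    def test_monotone_in_allocation(self):
        """Raising any V_i weakly increases a_k^v, strictly where Q_k > 0."""
        divs = self._divs()
        q = np.array([d.q_online for d in divs])
        a1 = online_accessibility([2.0], divs, mode="as_printed")
        a2 = online_accessibility([3.0], divs, mode="as_printed")
        assert np.all(a2 >= a1)
        assert np.all(a2[q > 0] > a1[q > 0])


class TestCombined:
    def _components(self):
        a_c = np.array([0.08, 0.02])
        a_t = np.array([0.02, 0.08])
        return a_c, a_t

    def test_offline_limit(self):
        """Q = 0 collapses the combination to the referral index."""
        a_c, a_t = self._components()
        divs = [
            DemandDivision(id=f"k{i}", pop_total=1, pop_elderly=1, pop_chronic=100, q_online=0.0)
            for i in range(2)
        ]
        params = ModelParams(referral_rate=0.3)
        prof = combined_accessibility(a_c, a_t, np.zeros(2), divs, params)
        assert np.allclose(prof.a_total, referral_accessibility(a_c, a_t, 0.3))

    def test_online_limit(self):
        """Q = 1 returns the online component regardless of r."""
        a_c, a_t = self._components()
        divs = [
            DemandDivision(id=f"k{i}", pop_total=1, pop_elderly=1, pop_chronic=100, q_online=1.0)
            for i in range(2)
        ]
        a_v = np.array([0.4, 0.4])
        prof = combined_accessibility(a_c, a_t, a_v, divs, ModelParams(referral_rate=0.7))
        assert np.allclose(prof.a_total, a_v)

    def test_two_division_hand_value(self):
        """0.65*0.05 + 0.35*0.03818... for the worked toy at r=0.5."""
        divs = [
            DemandDivision(id="k1", pop_total=1, pop_elderly=1, pop_chronic=100, q_online=0.35),
            DemandDivision(id="k2", pop_total=1, pop_elderly=1, pop_chronic=200, q_online=0.1),
        ]
        a_c = np.array([0.08, 0.02])
        a_t = np.array([0.02, 0.08])
        a_v = online_accessibility([6.0], divs, mode="as_printed")
        prof = combined_accessibility(a_c, a_t, a_v, divs, ModelParams(referral_rate=0.5))
        assert prof.a_total[0] == pytest.approx(0.65 * 0.05 + 0.35 * (6 * 0.35 / 55), rel=1e-12)
        assert prof.mean == pytest.approx(np.mean(prof.a_total))

    def test_invalid_q_rejected(self):
        a_c, a_t = self._components()
        divs = [
            DemandDivision(id=f"k{i}", pop_total=1, pop_elderly=1, pop_chronic=100)
            for i in range(2)
        ]
        with pytest.raises(ValueError):
            combined_accessibility(a_c, a_t, np.zeros(2), divs, q=[0.5, 1.5])


class TestAssignOnlinePreference:
    def test_below_mean_gets_poor(self):
        prof = AccessProfile.from_totals(["a", "b", "c"], [0.1, 0.5, 1.5])
        q = assign_online_preference(prof, ModelParams(q_poor=0.35, q_good=0.1))
        assert np.allclose(q, [0.35, 0.35, 0.1])

    def test_all_equal_all_good(self):
        prof = AccessProfile.from_totals(["a", "b"], [0.7, 0.7])
        q = assign_online_preference(prof, ModelParams())
        assert np.allclose(q, 0.1)

    def test_equal_levels_uniform(self):
        prof = AccessProfile.from_totals(["a", "b"], [0.1, 2.0])
        q = assign_online_preference(prof, ModelParams(q_poor=0.2, q_good=0.2))
        assert np.allclose(q, 0.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_online_preference(AccessProfile.from_totals([], []), ModelParams())


class TestComputeProfile:
    def test_resource_shift_conserves_total(self, lubei_like):
        """Shifting online time must not change total system resource."""
        inst = lubei_like
        params = ModelParams(online_mode="conserving", offline_mode="resource_shift")
        t = np.array([s.resource_offline for s in inst.tertiary_sites])
        v = 0.3 * t
        q = np.full(len(inst.divisions), 0.2)
        prof = compute_profile(inst.with_q(q), DecaySpec(), params, v_online=v)
        m = demand_vector(inst.divisions, "chronic")
        s_tot = sum(s.resource_offline for s in inst.community_sites)
        # weighted offline + online books balance: community + (T - V) + V
        offline_weighted = m @ (
            (1 - q) * ((1 - params.referral_rate) * prof.a_comm + params.referral_rate * prof.a_tert)
        )
        online_weighted = m @ (q * prof.a_online)
        assert online_weighted == pytest.approx(v.sum(), rel=1e-9)
        assert prof.a_total == pytest.approx(
            (1 - q) * ((1 - 0.2) * prof.a_comm + 0.2 * prof.a_tert) + q * prof.a_online
        )

    def test_overallocation_rejected(self, lubei_like):
        t = np.array([s.resource_offline for s in lubei_like.tertiary_sites])
        with pytest.raises(ValueError):
            compute_profile(lubei_like, v_online=1.5 * t)
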