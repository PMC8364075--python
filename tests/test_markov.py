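import numpy as np
import pytest

from petcea.life_tables import LifeTable
from petcea.markov import (
    build_transition_matrix,
    conversion_probability_ap,
    detection_probability,
    initial_distribution,
    mortality_probability,
    run_cohort,
    treated_probability,
)
from petcea.states import Tier, state_space
from petcea.strategies import current_practice, pet_strategy


def flat_lifetable(qx_value, lo=60, hi=120):
    qx = np.full(hi - lo + 1, float(qx_value))
    qx[-1] = 1.0
    return LifeTable(np.arange(lo, hi + 1), qx, source="flat")


class TestInitialDistribution:
    def test_pet_splits_by_sensitivity(self, params):
        ss = state_space(params.detection_cap_cycles)
        occ = initial_distribution(params, use_pet=True)
        assert occ[ss.index[ss.MCI_AP_KNOWN]] == pytest.approx(0.391 * 0.92)
        assert occ[ss.index[ss.MCI_AP_UNKNOWN]] == pytest.approx(0.391 * 0.08)
        assert occ[ss.index[ss.MCI_AN]] == pytest.approx(0.609)
        assert occ.sum() == pytest.approx(1.0)

    def test_no_pet_splits_by_prevalence(self, params):
        ss = state_space(params.detection_cap_cycles)
        occ = initial_distribution(params, use_pet=False)
        assert occ[ss.index[ss.MCI_AP_UNKNOWN]] == pytest.approx(0.391)
        assert occ[ss.index[ss.MCI_AN]] == pytest.approx(0.609)

    def test_perfect_test_leaves_no_unknown_positives(self, params):
        ss = state_space(params.detection_cap_cycles)
        occ = initial_distribution(params.replace(pet_sensitivity=1.0), use_pet=True)
        assert occ[ss.index[ss.MCI_AP_UNKNOWN]] == 0.0


class TestConversionProbability:
    def test_base_case(self, params):
        assert conversion_probability_ap(params) == pytest.approx(0.0211 * 7.95)

    def test_intervention_effect_applies_to_identified_only(self, params):
        p = params.replace(intervention_effect=0.95)
        assert conversion_probability_ap(p, identified=True) == pytest.approx(
            0.0211 * 7.95 * 0.95
        )
        assert conversion_probability_ap(p, identified=False) == pytest.approx(
            0.0211 * 7.95
        )

    def test_unit_relative_risk_recovers_negative_rate(self, params):
        p = params.replace(rr_ap_conversion=1.0)
        assert conversion_probability_ap(p) == pytest.approx(p.p_anmci_to_mild)

    def test_clamped_at_one(self, params):
        p = params.replace(rr_ap_conversion=100.0)
        assert conversion_probability_ap(p) == 1.0


class TestDetectionProbability:
    def test_annual_schedule(self, params, strat_current):
        ss = state_space(params.detection_cap_cycles)
        assert detection_probability(ss.tunnel_annual[0], params, strat_current) == 0.25

    def test_quarterly_schedule_detects_next_cycle(self, params, strat_pet):
        ss = state_space(params.detection_cap_cycles)
        assert detection_probability(ss.tunnel_quarterly[0], params, strat_pet) == 1.0

    def test_cap_forces_detection(self, params, strat_current):
        ss = state_space(params.detection_cap_cycles)
        assert detection_probability(ss.tunnel_annual[-1], params, strat_current) == 1.0

    def test_non_tunnel_state_rejected(self, params, strat_current):
        ss = state_space(params.detection_cap_cycles)
        with pytest.raises(ValueError):
            detection_probability(ss.MCI_AN, params, strat_current)


class TestTreatedProbability:
    def test_scales_annual_probability(self):
        assert treated_probability(0.3220, 0.85) == pytest.approx(0.2737)

    def test_identity_at_unit_rr(self):
        assert treated_probability(0.5, 1.0) == 0.5

    def test_clamps_above_one(self):
        assert treated_probability(0.9, 1.2) == 1.0


class TestMortalityProbability:
    def test_background_closed_form(self, params):
        lt = flat_lifetable(0.02)
        ss = state_space(params.detection_cap_cycles)
        got = mortality_probability(lt, 60, ss.CN_AN, params)
        assert got == pytest.approx(1 - 0.98**0.25, rel=1e-12)

    def test_severe_excess_multiplier(self, params):
        lt = flat_lifetable(0.02)
        ss = state_space(params.detection_cap_cycles)
        got = mortality_probability(lt, 60, ss.SEV_TREATED, params)
        assert got == pytest.approx(1 - 0.98 ** (7.82 / 4), rel=1e-12)

    def test_unit_multiplier_matches_background(self, params):
        lt = flat_lifetable(0.02)
        p = params.replace(excess_mort_moderate=1.0)
        ss = state_space(p.detection_cap_cycles)
        assert mortality_probability(lt, 60, ss.MOD_TREATED, p) == mortality_probability(
            lt, 60, ss.CN_AN, p
        )

    def test_age_beyond_table_is_lethal(self, params):
        lt = flat_lifetable(0.02, 60, 80)
        ss = state_space(params.detection_cap_cycles)
        assert mortality_probability(lt, 95, ss.MCI_AN, params) == 1.0


class TestTransitionMatrix:
    def test_zero_inputs_give_identity(self, params):
        p = params.replace(
            p_cn_to_mci=0.0,
            p_mci_to_cn=0.0,
            p_anmci_to_mild=0.0,
            p_mci_to_nonad=0.0,
            p_mild_to_mod=0.0,
            p_mild_to_sev=0.0,
            p_mod_to_mild=0.0,
            p_mod_to_sev=0.0,
        )
        lt = flat_lifetable(0.0)
        mat = build_transition_matrix(p, lt, current_practice(p), 60)
        # detection still moves tunnel mass; zero out by comparing non-tunnel rows
        ss = state_space(p.detection_cap_cycles)
        for label in ss:
            if not ss.is_tunnel(label):
                i = ss.index[label]
                expected = np.zeros(len(ss))
                expected[i] = 1.0
                np.testing.assert_allclose(mat[i], expected, atol=1e-15)

    @pytest.mark.parametrize("make_strategy", [current_practice, pet_strategy])
    @pytest.mark.parametrize("age", [60, 75, 100])
    def test_rows_are_stochastic(self, params, lifetable, make_strategy, age):
        mat = build_transition_matrix(params, lifetable, make_strategy(params), age)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(mat >= 0) and np.all(mat <= 1)

    def test_absorbing_rows_are_unit_vectors(self, params, lifetable, strat_pet):
        ss = state_space(params.detection_cap_cycles)
        mat = build_transition_matrix(params, lifetable, strat_pet, 60)
        for label in (ss.NONAD_EXIT, ss.DEATH):
            i = ss.index[label]
            assert mat[i, i] == 1.0
            assert mat[i].sum() == 1.0

    def test_tunnel_cap_has_no_successor_mass(self, params, lifetable, strat_current):
        """Mild AD is always detected by the end of the 3-year tunnel."""
        ss = state_space(params.detection_cap_cycles)
        mat = build_transition_matrix(params, lifetable, strat_current, 60)
        cap = ss.index[ss.tunnel_annual[-1]]
        tunnel_cols = [ss.index[s] for s in ss.tunnel_annual + ss.tunnel_quarterly]
        assert mat[cap, tunnel_cols].sum() == 0.0


class TestRunCohort:
    def test_lethal_table_kills_in_one_cycle(self, params):
        lt = flat_lifetable(1.0)
        trace = run_cohort(params, lt, current_practice(params))
        ss = trace.space
        assert trace.occupancy[1, ss.index[ss.DEATH]] == pytest.approx(1.0)

    def test_occupancy_conservation(self, params, lifetable, strat_pet):
        trace = run_cohort(params, lifetable, strat_pet)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_absorbing_occupancy_monotone(self, params, lifetable, strat_current):
        trace = run_cohort(params, lifetable, strat_current)
        ss = trace.space
        absorbed = trace.state(ss.DEATH) + trace.state(ss.NONAD_EXIT)
        assert np.all(np.diff(absorbed) >= -1e-12)

    def test_cohort_extinct_by_max_age(self, params, lifetable, strat_current):
        trace = run_cohort(params, lifetable, strat_current)
        ss = trace.space
        final = trace.occupancy[-1]
        living = 1 - final[ss.index[ss.DEATH]] - final[ss.index[ss.NONAD_EXIT]]
        assert living < 1e-9

    def test_null_treatment_makes_strategies_clinically_identical(
        self, params, lifetable
    ):
        """With no treatment effect and no intervention, detection timing
        cannot change clinical-tier occupancy."""
        p = params.replace(treatment_rr=1.0, intervention_effect=1.0)
        tr_cur = run_cohort(p, lifetable, current_practice(p))
        tr_pet = run_cohort(p, lifetable, pet_strategy(p))
        n = min(tr_cur.occupancy.shape[0], tr_pet.occupancy.shape[0])
        for tier in (Tier.CN, Tier.MCI, Tier.MILD, Tier.MOD, Tier.SEV):
            np.testing.assert_allclose(
                tr_cur.tier_occupancy(tier)[:n],
                tr_pet.tier_occupancy(tier)[:n],
                atol=1e-12,
            )

    def test_unit_conversion_rr_collapses_amyloid_asymmetry(self, params, lifetable):
        """With rr_ap_conversion = 1, AP and AN MCI evolve identically,
        so occupancy stays proportional to prevalence."""
        p = params.replace(rr_ap_conversion=1.0)
        trace = run_cohort(p, lifetable, current_practice(p))
        ss = trace.space
        ratio = p.ap_prevalence / (1 - p.ap_prevalence)
        np.testing.assert_allclose(
            trace.state(ss.MCI_AP_UNKNOWN),
            ratio * trace.state(ss.MCI_AN),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            trace.state(ss.CN_AP_UNKNOWN),
            ratio * trace.state(ss.CN_AN),
            atol=1e-12,
        )

    def test_life_table_must_cover_start_age(self, params, strat_current):
        lt = flat_lifetable(0.01, 70, 120)
        with pytest.raises(ValueError, match="start age"):
            run_cohort(params, lt, strat_current)
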