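"""Discounting, accrual, incremental comparison and calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shpt_cea import (
    ArmCosts,
    CalibrationTargets,
    ScenarioSpec,
    SharedCostValues,
    ValidationError,
    accrue,
    apply_calibration,
    calibrate_initial_split,
    compare,
    cycle_cost,
    discount_factor,
    random_scenario,
    run_arm,
    run_base_case,
)
from shpt_cea.cohort import CohortTrace
from shpt_cea.parameters import ModelSettings


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate, cycle, convention, expected",
        [
            (0.05, 1, "first_cycle_undiscounted", 1.0),
            (0.05, 2, "first_cycle_undiscounted", 1 / 1.05),
            (0.05, 1, "all_cycles_discounted", 1 / 1.05),
            (0.0, 7, "all_cycles_discounted", 1.0),
            (0.0, 7, "first_cycle_undiscounted", 1.0),
        ],
    )
    def test_conventions(self, rate, cycle, convention, expected):
        assert discount_factor(rate, cycle, convention) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(-0.01, 1)


class TestCycleCost:
    ARM = ArmCosts(drug_annual_year1=21766.86, drug_annual_later=18562.86,
                   inpatient_cost_per_stay=19557.85, hospitalizations_per_year=2.40)
    COMP = ArmCosts(drug_annual_year1=3942.0 + 27740.0, drug_annual_later=3942.0 + 27740.0,
                    inpatient_cost_per_stay=19375.57, hospitalizations_per_year=2.61)
    SHARED = SharedCostValues(hd_annual=67200.0, pd_annual=51600.0,
                              tx_year1=188697.90, tx_later_annual=99228.25)

    def test_hd_cycle1_per_stay_mode(self):
        cost = cycle_cost("HD", 1, self.ARM, self.SHARED, inpatient_is_annual=False)
        assert cost == pytest.approx(67200 + 21766.86 + 19557.85 * 2.40)
        assert cost == pytest.approx(135905.70)

    def test_hd_later_cycle_comparator_per_stay_mode(self):
        cost = cycle_cost("HD", 2, self.COMP, self.SHARED, inpatient_is_annual=False)
        assert cost == pytest.approx(67200 + 3942 + 27740 + 19375.57 * 2.61)
        assert cost == pytest.approx(149452.24, abs=5e-3)

    def test_annual_mode_skips_frequency(self):
        cost = cycle_cost("HD", 1, self.ARM, self.SHARED, inpatient_is_annual=True)
        assert cost == pytest.approx(67200 + 21766.86 + 19557.85)

    def test_transplant_states_accrue_only_transplant_costs(self):
        assert cycle_cost("TX_Y1", 1, self.ARM, self.SHARED) == 188697.90
        assert cycle_cost("TX_EST", 5, self.ARM, self.SHARED) == 99228.25

    def test_dead_accrues_nothing(self):
        assert cycle_cost("DEAD", 3, self.ARM, self.SHARED) == 0.0


class TestAccrue:
    def _alive_trace(self, horizon):
        occ = np.zeros((horizon + 1, 5))
        occ[:, 0] = 1.0
        return CohortTrace(occ)

    def test_undiscounted_life_years_cap(self):
        settings = ModelSettings(horizon_cycles=10, discount_rate=0.0)
        total = accrue(self._alive_trace(10), np.array([1.0, 1, 1, 1, 0]), settings)
        assert total == pytest.approx(10.0)

    def test_unit_utilities_equal_life_years(self, fixture_config):
        config = fixture_config.replace_settings(discount_rate=0.0)
        out = run_arm(config, "paricalcitol")
        life_years = accrue(out.trace, np.array([1.0, 1, 1, 1, 0]), config.settings)
        utilities = np.array([0.6, 0.6, 0.84, 0.84, 0.0])
        qalys = accrue(out.trace, utilities, config.settings)
        assert qalys <= life_years

    def test_discounting_never_increases_totals(self, fixture_config):
        discounted = run_arm(fixture_config, "paricalcitol")
        undiscounted = run_arm(
            fixture_config.replace_settings(discount_rate=0.0), "paricalcitol"
        )
        assert discounted.cost < undiscounted.cost
        assert discounted.qalys < undiscounted.qalys

    @given(seed=st.integers(0, 2_000), bump=st.floats(0.01, 0.2))
    def test_raising_death_probability_lowers_qalys(self, seed, bump):
        config = random_scenario(ScenarioSpec(seed=seed, death_prob_range=(0.02, 0.2)))
        base = run_arm(config, "arm_a").qalys
        raw = config.arms[0].transitions
        m1, m2 = raw.matrix_cycle1.copy(), raw.matrix_later.copy()
        for m in (m1, m2):
            for i in range(3):
                shift = min(bump, m[i, i])
                m[i, i] -= shift
                m[i, 3] += shift
        from shpt_cea.parameters import TransitionModel
        from dataclasses import replace
        deadlier = replace(config.arms[0],
                           transitions=TransitionModel("arm_a", m1, m2))
        bumped = run_arm(config, deadlier).qalys
        assert bumped < base + 1e-12


class TestCompare:
    def test_published_increments_classify_as_dominant(self):
        res = compare((472596.007, 2.855), (479521.619, 2.672), wtp=217113.0)
        assert res.dominance == "dominant"
        assert np.isnan(res.icer)
        assert res.delta_cost == pytest.approx(-6925.612)
        assert res.delta_qalys == pytest.approx(0.183)
        assert res.inmb == pytest.approx(217113 * 0.183 + 6925.612)
        assert res.inmb == pytest.approx(46657.29, abs=5e-3)

    def test_equal_arms_undefined(self):
        res = compare((100.0, 1.0), (100.0, 1.0), wtp=50000.0)
        assert res.dominance == "undefined"
        assert np.isnan(res.icer)

    @given(dc=st.floats(-1e5, 1e5), dq=st.floats(-1.0, 1.0))
    def test_quadrant_classification_matches_sign_oracle(self, dc, dq):
        res = compare((dc, dq), (0.0, 0.0), wtp=1e5)
        if dq == 0:
            expected = "undefined"
        elif dc <= 0 and dq > 0:
            expected = "dominant"
        elif dc >= 0 and dq < 0:
            expected = "dominated"
        else:
            expected = "icer"
        assert res.dominance == expected
        if expected == "icer":
            assert res.icer == pytest.approx(dc / dq, rel=1e-6)


class TestCalibration:
    def test_planted_split_recovered_within_one_grid_step(self, scenario_config):
        planted = 0.9
        config = scenario_config.replace_settings(initial_hd_fraction=planted)
        truth = run_base_case(config)
        targets = CalibrationTargets(
            cost_intervention=truth.cost_intervention,
            cost_comparator=truth.cost_comparator,
            qalys_intervention=truth.qalys_intervention,
            qalys_comparator=truth.qalys_comparator,
        )
        result = calibrate_initial_split(scenario_config, targets)
        assert result.initial_hd_fraction == pytest.approx(planted, abs=0.0005 + 1e-12)
        assert result.warning is None

    def test_symmetric_model_is_non_identifiable(self, scenario_config):
        """If HD and PD are indistinguishable (same rows, costs, utilities)
        the objective is flat and the lower grid edge is returned with a
        warning."""
        import yaml
        from shpt_cea.parameters import config_from_dict, config_to_dict

        raw = config_to_dict(scenario_config)
        for arm in raw["arms"]:
            for period in ("cycle1", "later"):
                m = np.asarray(arm["transitions"][period])
                m[1] = [0.0, m[0, 0], m[0, 2], m[0, 3]]  # PD mirrors HD
                arm["transitions"][period] = m.tolist()
        raw["parameters"]["cost_pd"] = dict(raw["parameters"]["cost_hd"])
        raw["parameters"]["utility_pd"] = dict(raw["parameters"]["utility_hd"])
        config = config_from_dict(raw)
        truth = run_base_case(config)
        targets = CalibrationTargets(truth.cost_intervention, truth.cost_comparator,
                                     truth.qalys_intervention, truth.qalys_comparator)
        result = calibrate_initial_split(config, targets)
        assert result.warning is not None
        assert result.initial_hd_fraction == 0.5

    def test_fixture_calibration_reproduces_stored_settings(self, fixture_config):
        result = calibrate_initial_split(fixture_config, search_conventions=True)
        assert result.initial_hd_fraction == pytest.approx(0.794, abs=1e-12)
        assert result.discount_convention == "all_cycles_discounted"
        assert result.accrual == "end_of_cycle"
        assert result.inpatient_is_annual is True
        calibrated = apply_calibration(fixture_config, result)
        assert calibrated.settings.initial_hd_fraction == result.initial_hd_fraction

    def test_basis_linearity_matches_direct_grid(self, fixture_config):
        """The linear-basis grid evaluation equals brute-force engine runs."""
        targets = CalibrationTargets(472596.007, 479521.619, 2.855, 2.672)
        result = calibrate_initial_split(fixture_config, targets)
        direct = run_base_case(fixture_config.replace_settings(
            initial_hd_fraction=result.initial_hd_fraction))
        assert result.achieved["cost_intervention"] == pytest.approx(
            direct.cost_intervention, rel=1e-12)
        assert result.achieved["qalys_comparator"] == pytest.approx(
            direct.qalys_comparator, rel=1e-12)
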