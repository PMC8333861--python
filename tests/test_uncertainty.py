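"""One-way and probabilistic sensitivity analysis, CEAC and EVPI."""

import numpy as np
import pytest

from shpt_cea import (
    PsaOutput,
    ScenarioSpec,
    ValidationError,
    ceac,
    ceac_point,
    default_wtp_grid,
    evpi,
    random_scenario,
    rng_stream,
    run_base_case,
    run_owsa,
    run_psa,
    sample_draw,
    sample_draws,
    tornado_frame,
)
from shpt_cea.parameters import config_from_dict, config_to_dict


def _fix_all_distributions(config):
    """Replace every distribution by a point mass at the base value."""
    raw = config_to_dict(config)
    for pid, p in raw["parameters"].items():
        if "distribution" in p:
            p["distribution"] = {"family": "fixed", "p1": p["value"]}
    return config_from_dict(raw)


class TestOwsa:
    def test_cinacalcet_price_tops_the_tornado(self, fixture_config):
        entries = run_owsa(fixture_config, outcome="inmb")
        assert entries[0].parameter_id == "drug_cinacalcet"
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)

    def test_degenerate_range_has_zero_spread(self, scenario_config):
        raw = config_to_dict(scenario_config)
        base = raw["parameters"]["cost_hd"]["value"]
        raw["parameters"]["cost_hd"]["owsa"] = {"low": base, "high": base,
                                                "rule": "none"}
        entries = run_owsa(config_from_dict(raw))
        by_id = {e.parameter_id: e for e in entries}
        assert by_id["cost_hd"].spread == pytest.approx(0.0, abs=1e-9)

    def test_single_ranged_parameter_yields_single_nonzero_bar(self, scenario_config):
        raw = config_to_dict(scenario_config)
        for pid, p in raw["parameters"].items():
            if pid == "drug_b":
                continue
            base = p["value"]
            if "owsa" in p:
                p["owsa"] = {"low": base, "high": base, "rule": "none"}
        entries = run_owsa(config_from_dict(raw))
        nonzero = [e for e in entries if e.spread > 1e-9]
        assert [e.parameter_id for e in nonzero] == ["drug_b"]

    def test_discount_rate_is_a_tornado_parameter(self, fixture_config):
        ids = {e.parameter_id for e in run_owsa(fixture_config)}
        assert "discount_rate" in ids

    def test_icer_outcome_carries_dominance_flags(self, fixture_config):
        entries = run_owsa(fixture_config, outcome="icer")
        flags = {e.flag_low for e in entries} | {e.flag_high for e in entries}
        assert "dominant" in flags

    def test_tornado_frame_columns(self, fixture_config):
        df = tornado_frame(run_owsa(fixture_config))
        assert {"parameter_id", "outcome_at_low", "outcome_at_high",
                "spread"} <= set(df.columns)


class TestSampling:
    def test_draw_covers_every_distributed_parameter(self, fixture_config):
        rng = rng_stream(1, "psa")
        draw = sample_draw(fixture_config, rng)
        assert set(draw) == {
            pid for pid, p in fixture_config.parameters.items()
            if p.distribution is not None
        }

    def test_fixed_distributions_return_base_values(self, fixture_config):
        config = _fix_all_distributions(fixture_config)
        draw = sample_draw(config, rng_stream(1, "psa"))
        for pid, v in draw.items():
            assert v == config.parameters[pid].value

    @pytest.mark.parametrize(
        "pid, family",
        [("cost_hd", "gamma_scale"), ("utility_tx", "beta")],
    )
    def test_sample_moments_match_analytic(self, fixture_config, pid, family):
        """Empirical mean and variance at 10^5 draws within 4 SE of the
        analytic gamma/beta moments."""
        n = 100_000
        d = fixture_config.parameters[pid].distribution
        draws = sample_draws(fixture_config, n, rng_stream(7, "psa"))[pid]
        if family == "gamma_scale":
            mean, var = d.p1 * d.p2, d.p1 * d.p2 ** 2
        else:
            mean = d.p1 / (d.p1 + d.p2)
            var = d.p1 * d.p2 / ((d.p1 + d.p2) ** 2 * (d.p1 + d.p2 + 1))
        assert abs(draws.mean() - mean) < 4 * np.sqrt(var / n)
        assert abs(draws.var() - var) < 4 * var * np.sqrt(2.0 / n)


class TestPsa:
    def test_same_seed_bitwise_identical(self, fixture_config):
        a = run_psa(fixture_config, iterations=50, seed=11)
        b = run_psa(fixture_config, iterations=50, seed=11)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)
        c = run_psa(fixture_config, iterations=50, seed=12)
        assert not np.array_equal(a.costs, c.costs)

    def test_degenerate_distributions_reproduce_base_case(self, fixture_config):
        config = _fix_all_distributions(fixture_config)
        base = run_base_case(config)
        psa = run_psa(config, iterations=1, seed=5)
        assert psa.costs[0, 0] == pytest.approx(base.cost_intervention, rel=1e-12)
        assert psa.costs[0, 1] == pytest.approx(base.cost_comparator, rel=1e-12)
        assert psa.qalys[0, 0] == pytest.approx(base.qalys_intervention, rel=1e-12)

    def test_psa_frames_shapes(self, fixture_config):
        psa = run_psa(fixture_config, iterations=20, seed=1)
        assert len(psa.to_frame()) == 40   # both arms stacked
        assert len(psa.plane_frame()) == 20


class TestCeac:
    def _toy(self, dc, dq):
        n = len(dc)
        costs = np.column_stack([np.asarray(dc, float), np.zeros(n)])
        qalys = np.column_stack([np.asarray(dq, float), np.zeros(n)])
        return PsaOutput(labels=("a", "b"), costs=costs, qalys=qalys, seed=0)

    def test_probability_at_zero_wtp_is_fraction_of_savings(self):
        toy = self._toy(dc=[-1.0, -2.0, 3.0, 4.0], dq=[0.1, -0.1, 0.1, -0.1])
        df = ceac(toy, [0.0])
        assert df["probability"].iloc[0] == 0.5

    def test_always_dominant_draws_give_probability_one(self):
        toy = self._toy(dc=[-1.0] * 8, dq=[0.2] * 8)
        df = ceac(toy, [0.0, 1e4, 4e5])
        assert (df["probability"] == 1.0).all()

    def test_boundary_ties_count_as_not_cost_effective(self):
        toy = self._toy(dc=[10.0], dq=[0.001])  # iNMB = 0 exactly at wtp 1e4
        df = ceac(toy, [1e4])
        assert df["probability"].iloc[0] == 0.0

    def test_probabilities_within_unit_interval_on_fixture(self, fixture_config):
        psa = run_psa(fixture_config, iterations=200, seed=3)
        df = ceac(psa, default_wtp_grid())
        assert df["probability"].between(0, 1).all()

    def test_default_grid_includes_the_operative_threshold(self):
        grid = default_wtp_grid()
        assert 217113.0 in grid
        assert grid.min() == 0.0 and grid.max() == 400000.0

    def test_empty_grid_rejected(self, fixture_config):
        psa = run_psa(fixture_config, iterations=5, seed=1)
        with pytest.raises(ValidationError):
            ceac(psa, [])

    def test_ceac_point_interval_brackets_estimate(self, fixture_config):
        psa = run_psa(fixture_config, iterations=200, seed=3)
        p, (lo, hi) = ceac_point(psa, 217113.0)
        assert lo <= p <= hi


class TestEvpi:
    def test_two_draw_hand_enumeration(self):
        # draw 1: NMB (10, 0); draw 2: NMB (0, 10) at wtp 1 with qalys as NMB
        costs = np.array([[0.0, 0.0], [0.0, 0.0]])
        qalys = np.array([[10.0, 0.0], [0.0, 10.0]])
        toy = PsaOutput(labels=("a", "b"), costs=costs, qalys=qalys, seed=0)
        df = evpi(toy, [1.0])
        assert df["per_person"].iloc[0] == pytest.approx(5.0)

    def test_population_value_scales_with_cohort(self):
        costs = np.array([[0.0, 0.0], [0.0, 0.0]])
        qalys = np.array([[10.0, 0.0], [0.0, 10.0]])
        toy = PsaOutput(labels=("a", "b"), costs=costs, qalys=qalys, seed=0)
        df = evpi(toy, [1.0], cohort_size=10_000)
        assert df["population"].iloc[0] == pytest.approx(50_000.0)

    def test_nonnegative_across_grid(self, fixture_config):
        psa = run_psa(fixture_config, iterations=300, seed=9)
        df = evpi(psa, default_wtp_grid(), fixture_config.settings.cohort_size)
        assert (df["per_person"] >= 0).all()

    def test_zero_under_degenerate_distributions(self, fixture_config):
        config = _fix_all_distributions(fixture_config)
        psa = run_psa(config, iterations=20, seed=2)
        df = evpi(psa, default_wtp_grid())
        assert (df["per_person"] == 0.0).all()


class TestTornadoMonotonicity:
    def test_doubling_a_range_never_shrinks_its_spread(self):
        config = random_scenario(ScenarioSpec(seed=11))
        raw = config_to_dict(config)
        base = raw["parameters"]["drug_b"]["value"]
        raw["parameters"]["drug_b"]["owsa"] = {"low": base * 0.9, "high": base * 1.1,
                                               "rule": "none"}
        narrow = {e.parameter_id: e.spread
                  for e in run_owsa(config_from_dict(raw))}
        raw["parameters"]["drug_b"]["owsa"] = {"low": base * 0.8, "high": base * 1.2,
                                               "rule": "none"}
        wide = {e.parameter_id: e.spread for e in run_owsa(config_from_dict(raw))}
        assert wide["drug_b"] >= narrow["drug_b"] - 1e-9
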