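"""Deterministic sensitivity analysis: thresholds, sweeps, tornado rows."""

import numpy as np
import pytest

from biphasic_cea import (
    ValidationError,
    one_way_sweep,
    run_cohort,
    solve_threshold_numeric,
    threshold_biphasic_risk,
    threshold_hourly_cost,
    threshold_relative_risk,
    tornado,
)
from biphasic_cea.dsa import default_tornado_ranges, set_parameter


class TestClosedFormThresholds:
    def test_biphasic_risk_break_even(self, hcp_config):
        t = threshold_biphasic_risk(hcp_config)
        assert t.threshold_value == pytest.approx(0.17046)
        assert t.rounded(percent=True) == 17
        assert t.direction == "above"

    def test_biphasic_risk_societal(self, societal_config):
        t = threshold_biphasic_risk(societal_config)
        assert t.threshold_value == pytest.approx(0.027 + 1573.45 / 10_000)

    def test_biphasic_risk_free_observation_limit(self, hcp_config):
        t = threshold_biphasic_risk(hcp_config, wtp=1e15)
        assert t.threshold_value == pytest.approx(0.027, abs=1e-8)

    def test_hourly_cost_break_even(self, hcp_config):
        t = threshold_hourly_cost(hcp_config)
        assert t.threshold_value == pytest.approx(46.00)
        assert t.direction == "below"
        assert t.parameter == "direct_hourly"  # indirect excluded by default

    def test_hourly_cost_linear_in_wtp_and_effect(self, hcp_config):
        assert threshold_hourly_cost(hcp_config, wtp=0.0).threshold_value == 0.0
        doubled = set_parameter(hcp_config, "p_short", 0.073)  # delta_p = 0.046
        assert threshold_hourly_cost(doubled).threshold_value == pytest.approx(92.00)

    @pytest.mark.parametrize(
        "societal,expected_r,expected_pct",
        [(False, 0.24175, 24), (True, 0.085915, 9)],
    )
    def test_relative_risk_break_even(
        self, hcp_config, societal_config, societal, expected_r, expected_pct
    ):
        cfg = societal_config if societal else hcp_config
        t = threshold_relative_risk(cfg)
        assert t.threshold_value == pytest.approx(expected_r, rel=1e-4)
        assert t.rounded(percent=True) == expected_pct

    def test_relative_risk_free_extension_caps_at_one(self, hcp_config):
        cfg = set_parameter(hcp_config, "direct_hourly", 1e-9)
        assert threshold_relative_risk(cfg).threshold_value == pytest.approx(1.0)

    def test_relative_risk_unattainable(self, hcp_config):
        # at a tiny per-death WTP no relative risk can justify the cost
        with pytest.raises(ValidationError):
            threshold_relative_risk(hcp_config, wtp_death=1000.0)

    def test_risk_threshold_decreasing_in_wtp(self, hcp_config):
        ts = [
            threshold_biphasic_risk(hcp_config, wtp=w).threshold_value
            for w in (5_000, 10_000, 50_000, 100_000)
        ]
        assert all(a > b for a, b in zip(ts, ts[1:]))


class TestBackSubstitution:
    def test_risk_threshold_recovers_wtp(self, hcp_config, societal_config):
        for cfg in (hcp_config, societal_config):
            p_star = threshold_biphasic_risk(cfg).threshold_value
            res = run_cohort(set_parameter(cfg, "p_short", p_star))
            assert res.icer_per_biphasic == pytest.approx(
                cfg.wtp_per_biphasic, rel=1e-6
            )

    def test_cost_threshold_recovers_wtp(self, hcp_config):
        c_star = threshold_hourly_cost(hcp_config).threshold_value
        res = run_cohort(set_parameter(hcp_config, "direct_hourly", c_star))
        assert res.icer_per_biphasic == pytest.approx(
            hcp_config.wtp_per_biphasic, rel=1e-6
        )

    def test_relative_risk_threshold_recovers_wtp(self, hcp_config):
        r_star = threshold_relative_risk(hcp_config).threshold_value
        res = run_cohort(hcp_config.with_fold(1.0 / r_star))
        assert res.icer_per_death == pytest.approx(hcp_config.wtp_per_death, rel=1e-6)


class TestNumericSolver:
    def test_bisection_matches_closed_form_risk(self, hcp_config):
        objective = lambda p: run_cohort(
            set_parameter(hcp_config, "p_short", p)
        ).icer_per_biphasic
        root = solve_threshold_numeric(objective, 10_000.0, (0.05, 0.5), tol=1e-12)
        assert root == pytest.approx(0.17046, abs=1e-9)

    def test_linear_objective_exact(self):
        assert solve_threshold_numeric(lambda x: 2 * x, 10.0, (0.0, 100.0)) == (
            pytest.approx(5.0, abs=1e-9)
        )

    def test_unbracketed_target_rejected(self):
        with pytest.raises(ValidationError):
            solve_threshold_numeric(lambda x: x, 10.0, (0.0, 1.0))

    def test_randomized_configs_closed_form_vs_bisection(self, hcp_config):
        """Closed forms and the numeric route agree on 100 perturbed models."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            cfg = set_parameter(
                hcp_config, "direct_hourly", float(rng.uniform(100, 500))
            )
            cfg = set_parameter(cfg, "p_extended", float(rng.uniform(0.01, 0.027)))
            cfg = set_parameter(cfg, "extended_hours", float(rng.uniform(4, 24)))
            wtp = float(rng.uniform(5_000, 100_000))
            p_star = threshold_biphasic_risk(cfg, wtp=wtp).threshold_value
            if not 0.03 < p_star < 0.95:
                continue
            objective = lambda p: run_cohort(
                set_parameter(cfg, "p_short", p)
            ).icer_per_biphasic
            root = solve_threshold_numeric(objective, wtp, (0.03, 0.95), tol=1e-12)
            assert root == pytest.approx(p_star, abs=1e-9)


class TestSweepsAndTornado:
    def test_sweep_passes_through_base_case(self, hcp_config):
        sweep = one_way_sweep(hcp_config, "direct_hourly", 100, 500, 201)
        at_base = sweep.iloc[(sweep["direct_hourly"] - 286.92).abs().idxmin()]
        near = run_cohort(
            set_parameter(hcp_config, "direct_hourly", at_base["direct_hourly"])
        )
        assert at_base["icer_per_biphasic"] == pytest.approx(near.icer_per_biphasic)
        assert run_cohort(hcp_config).icer_per_biphasic == pytest.approx(
            62373.913, rel=1e-6
        )

    def test_sweep_hits_wtp_at_threshold(self, hcp_config):
        p_star = threshold_biphasic_risk(hcp_config).threshold_value
        sweep = one_way_sweep(hcp_config, "p_short", 0.05, 0.20, 4)
        assert sweep["icer_per_biphasic"].is_monotonic_decreasing
        res = run_cohort(set_parameter(hcp_config, "p_short", p_star))
        assert res.icer_per_biphasic == pytest.approx(10_000.0, rel=1e-9)

    def test_sweep_endpoints_only(self, hcp_config):
        sweep = one_way_sweep(hcp_config, "direct_hourly", 100, 500, 2)
        assert list(sweep["direct_hourly"]) == [100.0, 500.0]

    def test_sweep_unknown_parameter(self, hcp_config):
        with pytest.raises(ValidationError):
            one_way_sweep(hcp_config, "not_a_parameter", 0, 1, 3)

    def test_tornado_direct_cost_row(self, hcp_config):
        rows = tornado(hcp_config).set_index("parameter")
        direct = rows.loc["direct_hourly"]
        assert direct["icer_at_low"] == pytest.approx(5 * 100 / 0.023)
        assert direct["icer_at_high"] == pytest.approx(5 * 500 / 0.023)
        assert direct["span"] == pytest.approx(
            abs(direct["icer_at_high"] - direct["icer_at_low"])
        )

    def test_tornado_sorted_and_deterministic(self, hcp_config):
        rows = tornado(hcp_config)
        assert rows["span"].is_monotonic_decreasing
        assert rows.equals(tornado(hcp_config))  # no randomness
        # the fatality input does not move the per-biphasic ICER
        assert rows.set_index("parameter").loc["case_fatality", "span"] == 0.0

    def test_tornado_degenerate_range(self, hcp_config):
        rows = tornado(hcp_config, ranges={"direct_hourly": (286.92, 286.92)})
        assert rows.loc[0, "span"] == 0.0

    def test_default_ranges_drop_indirect_under_hcp(self, hcp_config, societal_config):
        assert "indirect_hourly" not in default_tornado_ranges(hcp_config)
        assert "indirect_hourly" in default_tornado_ranges(societal_config)
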