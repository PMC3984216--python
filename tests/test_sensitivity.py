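"""Best/worst-case runs, Monte Carlo ensembles and effect classification."""

import numpy as np
import pandas as pd
import pytest

from velodyn.cba import accumulate
from velodyn.config import ScenarioConfig, preset
from velodyn.engine import ConfigurationError
from velodyn.model import CommuteModel
from velodyn.sensitivity import (ParameterDistribution, best_worst_runs, classify_effect,
                                 default_distributions, ensemble_quantiles, monte_carlo,
                                 set_by_path)


def _dist(path, low, high, mode, favorable="high"):
    return ParameterDistribution(path, low, high, mode, favorable)


class TestParameterDistribution:
    def test_bounds_must_bracket_mode(self):
        with pytest.raises(ConfigurationError):
            _dist("physical_activity.relative_risk", 0.8, 0.9, 0.72)

    def test_degenerate_distribution_samples_mode(self):
        d = _dist("physical_activity.relative_risk", 0.72, 0.72, 0.72)
        assert d.sample(np.random.default_rng(0)) == 0.72

    def test_unknown_path_rejected(self):
        cfg = ScenarioConfig()
        with pytest.raises(ConfigurationError):
            set_by_path(cfg, "policy.asbl.not_a_field", 1.0)


class TestBestWorst:
    def test_point_bounds_reproduce_primary_run(self):
        cfg = preset("ser")
        rr = cfg.physical_activity.relative_risk
        dists = [_dist("physical_activity.relative_risk", rr, rr, rr)]
        best, worst = best_worst_runs(cfg, dists)
        primary = CommuteModel(cfg).run()
        assert best.equals(primary) and worst.equals(primary)

    def test_ser_worst_case_still_reduces_injury_rate(self):
        cfg = preset("ser")
        _, worst = best_worst_runs(cfg, default_distributions(cfg, include_structural=False))
        rate = worst.set_index("year")["injury_rate_per_1000"]
        assert rate.loc[2051.0] < rate.loc[2012.0]

    def test_rcn_best_case_still_increases_injury_rate(self):
        cfg = preset("rcn")
        best, _ = best_worst_runs(cfg, default_distributions(cfg, include_structural=False))
        rate = best.set_index("year")["injury_rate_per_1000"]
        assert rate.loc[2051.0] > rate.loc[2012.0]


class TestMonteCarlo:
    def test_single_degenerate_run_equals_primary(self):
        cfg = preset("rcn")
        rr = cfg.physical_activity.relative_risk
        dists = [_dist("physical_activity.relative_risk", rr, rr, rr)]
        ensemble = monte_carlo(cfg, dists, 1, seed=5)
        assert ensemble[0].equals(CommuteModel(cfg).run())

    def test_same_seed_identical_ensembles(self):
        cfg = preset("asbl")
        dists = default_distributions(cfg)
        a = monte_carlo(cfg, dists, 3, seed=11)
        b = monte_carlo(cfg, dists, 3, seed=11)
        for x, y in zip(a, b):
            assert x.equals(y)

    def test_scenario_envelopes_remain_distinguishable(self):
        """2051 bike-share ensembles of the weakest and strongest policies
        do not overlap under the shipped uncertainty set."""
        n = 40
        rcn = monte_carlo(preset("rcn"), default_distributions(preset("rcn")), n, seed=21)
        combined = monte_carlo(preset("asbl_ser"),
                               default_distributions(preset("asbl_ser")), n, seed=22)
        rcn_final = [t["share_bicycle"].iloc[-1] for t in rcn]
        combined_final = [t["share_bicycle"].iloc[-1] for t in combined]
        assert max(rcn_final) < min(combined_final)

    def test_quantiles_shape(self):
        cfg = preset("rcn")
        ensemble = monte_carlo(cfg, default_distributions(cfg), 4, seed=3)
        q = ensemble_quantiles(ensemble, "share_bicycle")
        assert len(q) == len(ensemble[0])
        assert (q["q0"] <= q["q1"]).all()


class TestClassification:
    @staticmethod
    def _traj(values):
        years = np.arange(2012.0, 2052.0)
        return pd.DataFrame({"year": years, "out": values(years)})

    def test_identical_is_within_order(self):
        ref = self._traj(lambda y: 1 + 0.01 * (y - 2012))
        assert classify_effect(ref, ref.copy(), "out") == "within_order"

    def test_opposite_terminal_trends_is_shape_change(self):
        ref = self._traj(lambda y: 1 + 0.05 * (y - 2012))
        varied = self._traj(lambda y: 3 - 0.05 * (y - 2012))
        assert classify_effect(ref, varied, "out") == "shape_change"

    def test_twelvefold_level_same_shape_is_order_of_magnitude(self):
        ref = self._traj(lambda y: 1 + 0.05 * (y - 2012))
        varied = self._traj(lambda y: 12 * (1 + 0.05 * (y - 2012)))
        assert classify_effect(ref, varied, "out") == "order_of_magnitude"

    def test_no_threshold_power_function_changes_injury_shape(self):
        """Swapping in the pure no-threshold power function alters the
        shape of injury outputs over time for the active scenarios."""
        changed = []
        for name in ("rcn", "asbl", "asbl_ser"):
            cfg = preset(name)
            reference = CommuteModel(cfg).run()
            alt = cfg.copy()
            alt.injury.sin.pure_jacobsen = True
            varied = CommuteModel(alt).run()
            cls = classify_effect(reference, varied, "injury_rate_per_1000")
            changed.append(cls == "shape_change")
        assert any(changed)

    def test_lead_time_variation_preserves_scenario_ranking(self):
        """Cumulative deaths averted still rank the weakest below the
        strongest policy for any lead time in [1, 5] years."""
        for lead in (1.0, 3.0, 5.0):
            results = {}
            base_cfg = preset("baseline")
            base_cfg.physical_activity.lead_time_years = lead
            base = CommuteModel(base_cfg).run()
            for name in ("rcn", "asbl_ser"):
                cfg = preset(name)
                cfg.physical_activity.lead_time_years = lead
                traj = CommuteModel(cfg).run()
                results[name] = accumulate(traj, base).pa_deaths_averted
            assert results["rcn"] < results["asbl_ser"]
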