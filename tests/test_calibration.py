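"""Monte Carlo calibration: sampling, screening, selection, stability."""

import numpy as np
import pandas as pd
import pytest

from mimicslite import CalibrationMultiplierSet
from mimicslite.calibrate import (
    CalibrationError,
    EvaluationRecord,
    evaluate_set,
    filter_sets,
    rmse,
    sample_parameter_sets,
    select_best,
    stability_check,
)
from mimicslite.litterbag import run_design
from mimicslite.params import MULTIPLIER_RANGES


def make_record(draw_id, sims, effects, viable=True):
    """Hand-built evaluation record (no model runs)."""
    idx = pd.MultiIndex.from_tuples(sorted(sims), names=["site", "timepoint"])
    return EvaluationRecord(
        mults=CalibrationMultiplierSet(1.0, 1.0, 1.0, 1.0, draw_id=draw_id),
        site_means=pd.Series({k: sims[k] for k in sorted(sims)}, index=idx),
        relative_effects=pd.Series(effects),
        viable=viable,
    )


def toy_envelope():
    return pd.DataFrame(
        [
            {"site": "A", "timepoint": 10, "obs_min": 20.0, "obs_mean": 30.0, "obs_max": 40.0},
            {"site": "A", "timepoint": 21, "obs_min": 40.0, "obs_mean": 50.0, "obs_max": 60.0},
            {"site": "B", "timepoint": 10, "obs_min": 25.0, "obs_mean": 35.0, "obs_max": 45.0},
            {"site": "B", "timepoint": 21, "obs_min": 45.0, "obs_mean": 55.0, "obs_max": 65.0},
        ]
    )


OBS_EFFECTS = pd.Series({"z_moisture": 40.0, "z_lignin_n": -30.0, "z_co_ratio": -30.0})
GOOD_SIMS = {("A", 10): 31.0, ("A", 21): 51.0, ("B", 10): 34.0, ("B", 21): 54.0}
GOOD_EFFECTS = {"z_moisture": 42.0, "z_lignin_n": -28.0, "z_co_ratio": -30.0}


class TestSampling:
    def test_draws_respect_ranges(self):
        draws = sample_parameter_sets(500, seed=1)
        for d in draws:
            d.validate()

    def test_same_seed_reproduces_draws(self):
        a = sample_parameter_sets(50, seed=9)
        b = sample_parameter_sets(50, seed=9)
        assert [x.as_dict() for x in a] == [y.as_dict() for y in b]

    def test_extremes_approach_range_endpoints(self):
        draws = sample_parameter_sets(5000, seed=2)
        for name, (lo, hi) in MULTIPLIER_RANGES.items():
            vals = np.array([d.as_dict()[name] for d in draws])
            width = hi - lo
            assert vals.min() <= lo + 0.01 * width
            assert vals.max() >= hi - 0.01 * width

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_parameter_sets(0)
        with pytest.raises(ValueError):
            sample_parameter_sets(5, ranges={"m_tau_r": (2.0, 1.0)})


class TestRmse:
    def test_toy_two_site_value(self):
        sim = pd.Series(
            {("A", 10): 32.0, ("A", 21): 52.0, ("B", 10): 31.0, ("B", 21): 59.0}
        )
        obs = pd.Series(
            {("A", 10): 30.0, ("A", 21): 50.0, ("B", 10): 35.0, ("B", 21): 55.0}
        )
        # sqrt(mean(2^2, 2^2, 4^2, 4^2)) = sqrt(10)
        assert rmse(sim, obs) == pytest.approx(np.sqrt(10.0))

    def test_self_rmse_is_zero(self):
        sim = pd.Series({("A", 10): 32.0, ("A", 21): 52.0})
        assert rmse(sim, sim.copy()) == 0.0


class TestFiltering:
    def test_good_record_survives(self):
        rec = make_record(0, GOOD_SIMS, GOOD_EFFECTS)
        out = filter_sets([rec], toy_envelope(), OBS_EFFECTS)
        assert bool(out.loc[0, "survives"])

    def test_high_rmse_rejected_by_criterion_three(self):
        sims = {k: v + 6.0 for k, v in GOOD_SIMS.items()}  # RMSE 6 > 5.4
        rec = make_record(0, sims, GOOD_EFFECTS)
        out = filter_sets([rec], toy_envelope(), OBS_EFFECTS)
        assert out.loc[0, "rmse"] == pytest.approx(6.0, abs=0.2)
        assert not out.loc[0, "rmse_ok"]
        assert not bool(out.loc[0, "survives"])

    def test_effect_deviation_beyond_tolerance_rejected(self):
        effects = dict(GOOD_EFFECTS, z_lignin_n=-30.0 + 12.0)
        rec = make_record(0, GOOD_SIMS, effects)
        out = filter_sets([rec], toy_envelope(), OBS_EFFECTS)
        assert not out.loc[0, "effects_close"]
        assert not bool(out.loc[0, "survives"])

    def test_extinct_microbes_rejected(self):
        rec = make_record(0, GOOD_SIMS, GOOD_EFFECTS, viable=False)
        out = filter_sets([rec], toy_envelope(), OBS_EFFECTS)
        assert not bool(out.loc[0, "survives"])

    def test_envelope_violation_rejected(self):
        sims = dict(GOOD_SIMS)
        sims[("A", 10)] = 19.0  # below obs_min
        rec = make_record(0, sims, GOOD_EFFECTS)
        out = filter_sets([rec], toy_envelope(), OBS_EFFECTS)
        assert not out.loc[0, "in_envelope"]

    def test_loosening_thresholds_never_shrinks_survivors(self, rng):
        records = []
        for i in range(40):
            sims = {k: v + rng.normal(0, 4) for k, v in GOOD_SIMS.items()}
            effects = {k: v + rng.normal(0, 8) for k, v in GOOD_EFFECTS.items()}
            records.append(make_record(i, sims, effects, viable=rng.random() > 0.2))
        tight = filter_sets(records, toy_envelope(), OBS_EFFECTS, rmse_max=3.0, effect_tol=5.0)
        loose = filter_sets(records, toy_envelope(), OBS_EFFECTS, rmse_max=6.0, effect_tol=15.0)
        assert set(tight[tight.survives]["draw_id"]) <= set(loose[loose.survives]["draw_id"])

    def test_per_driver_tolerance_vector(self):
        effects = dict(GOOD_EFFECTS, z_co_ratio=-30.0 + 14.0)
        rec = make_record(0, GOOD_SIMS, effects)
        strict = filter_sets([rec], toy_envelope(), OBS_EFFECTS)
        assert not strict.loc[0, "effects_close"]
        loose = filter_sets(
            [rec], toy_envelope(), OBS_EFFECTS,
            effect_tol={"z_moisture": 10, "z_lignin_n": 10, "z_co_ratio": 20},
        )
        assert bool(loose.loc[0, "effects_close"])


class TestSelection:
    def scored(self, rmses, devs=None):
        devs = devs or [1.0] * len(rmses)
        return pd.DataFrame(
            {
                "draw_id": range(len(rmses)),
                "rmse": rmses,
                "effect_dev": devs,
                "survives": [True] * len(rmses),
            }
        )

    def test_ranked_by_rmse(self):
        out = select_best(self.scored([5.0, 3.0, 5.3, 4.0]), k=3)
        assert out["draw_id"].tolist() == [1, 3, 0]

    def test_tie_broken_by_effect_deviation(self):
        out = select_best(self.scored([3.0, 3.0, 4.0], devs=[9.0, 2.0, 1.0]), k=2)
        assert out["draw_id"].tolist() == [1, 0]

    def test_fewer_survivors_than_k_warns(self):
        with pytest.warns(UserWarning):
            out = select_best(self.scored([3.0]), k=3)
        assert len(out) == 1

    def test_no_survivors_raises_advice(self):
        scored = self.scored([3.0])
        scored["survives"] = False
        with pytest.raises(CalibrationError, match="loosening"):
            select_best(scored)


class TestStability:
    def build_records(self, rng, n=40):
        records = []
        for i in range(n):
            # one dominant optimum at draw 0
            offset = 0.0 if i == 0 else rng.uniform(1.5, 4.0)
            sims = {k: v + offset for k, v in GOOD_SIMS.items()}
            records.append(make_record(i, sims, GOOD_EFFECTS))
        return records

    def test_zero_holdout_always_matches(self, rng):
        records = self.build_records(rng)
        out = stability_check(
            records, toy_envelope(), OBS_EFFECTS, holdout=0.0, replicates=10, seed=1
        )
        assert out["exact_match_fraction"] == 1.0

    def test_dominant_optimum_is_always_recovered(self, rng):
        records = self.build_records(rng)
        out = stability_check(
            records, toy_envelope(), OBS_EFFECTS, holdout=0.10, replicates=100,
            seed=2, k=1,
        )
        # draw 0 survives every 90% subsample with probability 0.9; when
        # present it always wins
        assert out["mean_overlap_fraction"] >= 0.85

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            stability_check([], toy_envelope(), OBS_EFFECTS)


class TestEvaluate:
    def test_identity_multipliers_match_default_design(
        self, calibration_sites, daily, params, default_design
    ):
        sub = calibration_sites[:2]
        rec = evaluate_set(CalibrationMultiplierSet.identity(), sub, daily, params)
        assert not rec.failed
        base = run_design(sub, daily, params)
        expected = base.groupby(["site", "timepoint"])["mass_loss_pct"].mean()
        pd.testing.assert_series_equal(
            rec.site_means, expected, check_names=False, atol=1e-12, rtol=0
        )

    def test_record_carries_three_relative_effects(
        self, calibration_sites, daily, params
    ):
        rec = evaluate_set(
            CalibrationMultiplierSet(1.33, 0.76, 1.76, 0.93),
            calibration_sites, daily, params,
        )
        assert not rec.failed
        assert rec.relative_effects.abs().sum() == pytest.approx(100.0)
        assert rec.viable
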