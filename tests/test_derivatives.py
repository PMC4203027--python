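"""Trim points, stability slopes with 75% intervals, control effectiveness."""

import numpy as np
import pandas as pd
import pytest

import aerophylo as ap
from aerophylo.derivatives import (
    InsufficientDataError,
    control_effectiveness,
    find_equilibria,
    stability_slope,
)
from aerophylo.synthetic import CONTROL_CHARACTERS, STABILITY_CHARACTERS
from conftest import reduce_taxon


class TestFindEquilibria:
    def test_linear_series_crossing(self):
        alpha = np.arange(0.0, 95.0, 5.0)
        cm = 0.2 - 0.01 * alpha
        crossings = find_equilibria(alpha, cm)
        assert len(crossings) == 1
        assert crossings[0][0] == pytest.approx(20.0)

    def test_strictly_positive_series_has_no_trim_point(self):
        alpha = np.arange(0.0, 95.0, 5.0)
        assert find_equilibria(alpha, 0.1 + 0.001 * alpha) == []

    def test_humped_curve_recovers_both_crossings(self):
        """Known crossings at 5 and 60 degrees located within 0.5 on a 5-degree grid."""
        truth = ap.truth_from_knots(
            "humped",
            [(0.0, -0.05, 0.5), (10.0, 0.05, 0.5), (30.0, 0.2, 0.0),
             (55.0, 0.05, -0.5), (65.0, -0.05, -0.5), (90.0, -0.2, -0.3)],
            {"low": 0, "high": 0}, {"low": 0, "high": 0},
            equilibrium_angle_deg=None,
        )
        alpha = np.arange(0.0, 95.0, 5.0)
        cm = truth.pitch_curve(np.deg2rad(alpha))
        crossings = [a for a, _ in find_equilibria(alpha, cm)]
        assert len(crossings) == 2
        assert crossings[0] == pytest.approx(5.0, abs=0.5)
        assert crossings[1] == pytest.approx(60.0, abs=0.5)

    def test_unsorted_series_rejected(self):
        with pytest.raises(ValueError):
            find_equilibria([10.0, 5.0], [0.1, -0.1])


class TestStabilitySlope:
    def test_noise_free_linear_data_exact_slope_zero_width(self):
        angles = np.repeat(np.arange(5.0, 30.0, 5.0), 3)
        c = -0.5 * np.deg2rad(angles) + 0.02
        est = stability_slope(angles, c, 15.0)
        assert est.slope == pytest.approx(-0.5, abs=1e-12)
        assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            stability_slope([14.0, 16.0], [0.0, 0.1], 15.0)

    def test_interval_coverage_is_calibrated(self):
        """Empirical 75% coverage over 2000 linear series with Gaussian noise."""
        rng = np.random.default_rng(31)
        angles = np.repeat(np.arange(5.0, 30.0, 5.0), 5)
        x = np.deg2rad(angles)
        true = -0.5
        hits = 0
        n = 2000
        for _ in range(n):
            est = stability_slope(angles, true * x + rng.normal(0, 0.015, x.size), 15.0)
            hits += est.ci_low <= true <= est.ci_high
        assert hits / n == pytest.approx(0.75, abs=0.03)

    def test_zero_truth_straddles_zero_at_the_nominal_rate(self):
        """For a truly marginal body the interval contains 0 in ~75% of runs.

        This is the defining property of a calibrated two-sided interval at
        a true slope of zero, whatever the noise scale.
        """
        rng = np.random.default_rng(32)
        angles = np.repeat(np.arange(5.0, 30.0, 5.0), 5)
        hits = 0
        n = 2000
        for _ in range(n):
            est = stability_slope(angles, rng.normal(0, 0.015, angles.size), 15.0)
            hits += est.ci_low <= 0.0 <= est.ci_high
        assert hits / n == pytest.approx(0.75, abs=0.03)

    def test_unbiased_on_linear_truth(self):
        rng = np.random.default_rng(33)
        angles = np.repeat(np.arange(5.0, 30.0, 5.0), 5)
        x = np.deg2rad(angles)
        true = -0.5
        slopes = [
            stability_slope(angles, true * x + rng.normal(0, 0.015, x.size), 15.0).slope
            for _ in range(3000)
        ]
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - true) < 3 * se


def _series(angles, values, replicate=1):
    return pd.DataFrame({"angle_deg": angles, "replicate": replicate, "C_m": values})


class TestControlEffectiveness:
    def test_central_difference_arithmetic(self):
        angles = [5.0, 10.0, 15.0, 20.0, 25.0]
        plus = _series(angles, [0.13, 0.12, 0.11, 0.10, 0.09])
        minus = _series(angles, [0.07, 0.06, 0.05, 0.04, 0.03])
        est = control_effectiveness(None, plus, minus, np.deg2rad(15.0), 15.0)
        assert est.slope == pytest.approx(0.06 / (2 * 0.2617993878), rel=1e-9)
        assert est.slope == pytest.approx(0.1146, abs=2e-4)

    def test_identical_series_give_zero(self):
        angles = [10.0, 15.0, 20.0]
        base = _series(angles, [0.1, 0.1, 0.1])
        est = control_effectiveness(base, base.copy(), None, np.deg2rad(15.0), 15.0)
        assert est.slope == 0.0

    def test_swapping_signs_negates_exactly(self):
        rng = np.random.default_rng(3)
        angles = [5.0, 10.0, 15.0, 20.0, 25.0]
        plus = _series(angles, rng.normal(0.1, 0.01, 5))
        minus = _series(angles, rng.normal(0.0, 0.01, 5))
        a = control_effectiveness(None, plus, minus, np.deg2rad(15.0), 15.0)
        b = control_effectiveness(None, minus, plus, np.deg2rad(15.0), 15.0)
        assert a.slope == pytest.approx(-b.slope, rel=1e-12)

    def test_one_sided_requires_baseline(self):
        plus = _series([10.0, 15.0, 20.0], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            control_effectiveness(None, plus, None, np.deg2rad(45.0), 15.0)

    def test_recovers_generator_truth_within_tolerance(self, design, geometry):
        """True dC/ddelta = 0.2: estimate within +/-0.02 in >=95% of runs."""
        control = {("pitch", "tail_dorsiflexion", "low"): 0.2,
                   ("pitch", "tail_dorsiflexion", "high"): 0.2}
        truth = ap.truth_from_knots("t", [(0.0, 0.0, 0.0), (90.0, 0.0, 0.0)],
                                    {"low": 0, "high": 0}, {"low": 0, "high": 0},
                                    control=control, equilibrium_angle_deg=None)
        hits = 0
        runs = 60
        for s in range(runs):
            est = ap.estimate_taxon(reduce_taxon(truth, design, geometry, 500 + s))
            hits += abs(est["ctrl_pitch_tail_dorsiflexion_15"].slope - 0.2) <= 0.02
        assert hits / runs >= 0.95


class TestEstimateTaxon:
    def test_produces_exactly_8_stability_and_12_control(self, noisefree_estimates):
        est = noisefree_estimates["long_tailed"]
        stab = [l for l in est if l.startswith("stab_")]
        ctrl = [l for l in est if l.startswith("ctrl_")]
        assert sorted(stab) == sorted(STABILITY_CHARACTERS)
        assert len(ctrl) == len(CONTROL_CHARACTERS) == 12
        assert all(est[l] is not None for l in stab + ctrl)

    def test_stability_evaluation_points(self, noisefree_estimates):
        est = noisefree_estimates["weathervane"]
        points = {(est[l].axis, est[l].evaluation_point) for l in STABILITY_CHARACTERS}
        assert points == {("pitch", "0"), ("pitch", "15"), ("pitch", "75"), ("pitch", "eq"),
                          ("roll", "15"), ("roll", "75"), ("yaw", "15"), ("yaw", "75")}

    def test_no_trim_point_leaves_equilibrium_character_missing(self, design, geometry):
        truth = ap.truth_from_knots("t", [(0.0, 0.2, 0.0), (90.0, 0.2, 0.0)],
                                    {"low": 0, "high": 0}, {"low": 0, "high": 0},
                                    equilibrium_angle_deg=None,
                                    noise_sd_force=0.0, noise_sd_torque=0.0)
        est = ap.estimate_taxon(reduce_taxon(truth, design, geometry, 1))
        assert est["equilibria_deg"] == []
        assert est["stab_pitch_eq"] is None

    def test_full_pipeline_ci_covers_truth_at_nominal_rate(self, design, geometry):
        """Known slope -0.5 at 15 deg lies in its own 75% interval ~75% of runs."""
        truth = ap.truth_from_knots("t", [(0.0, 0.5 * np.deg2rad(15), -0.5),
                                          (90.0, -0.5 * np.deg2rad(75), -0.5)],
                                    {"low": 0, "high": 0}, {"low": 0, "high": 0},
                                    equilibrium_angle_deg=15.0)
        hits = 0
        runs = 400
        d = ap.build_test_design({"movements": [], "series": ["pitch"]})
        for s in range(runs):
            est = ap.estimate_taxon(reduce_taxon(truth, d, geometry, 9000 + s))
            e = est["stab_pitch_15"]
            hits += e.ci_low <= -0.5 <= e.ci_high
        assert hits / runs == pytest.approx(0.75, abs=0.06)
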