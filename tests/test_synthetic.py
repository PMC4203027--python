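"""Virtual wind tunnel: design enumeration, determinism, ground-truth fidelity."""

from itertools import product

import numpy as np
import pytest

import aerophylo as ap
from aerophylo.coefficients import coefficients_from_moments
from aerophylo.frames import transform_records
from aerophylo.synthetic import (
    CHARACTER_LABELS,
    CONTROL_CHARACTERS,
    MOVEMENTS,
    STABILITY_CHARACTERS,
    DesignPoint,
    control_label,
    random_truth,
)
from conftest import reduce_taxon


def brute_force_position_count(design):
    """Independent enumeration of the design size, written longhand."""
    count = 0
    for series, grid, n_aoa in (("pitch", design.pitch_grid, 1),
                                ("roll", design.roll_grid, len(design.aoa_values)),
                                ("yaw", design.yaw_grid, len(design.aoa_values))):
        if series not in design.series:
            continue
        n_states = 1  # baseline
        for mv in design.movements.values():
            if series in mv.series:
                n_states += 2 if mv.symmetric else 1
        count += n_aoa * n_states * len(grid)
    return count


def test_design_count_matches_independent_enumeration(design):
    assert len(design.positions()) == brute_force_position_count(design)


def test_default_pitch_series_includes_both_regimes(design):
    alphas = {p.theta_deg for p in design.positions() if p.series == "pitch"}
    assert {15.0, 75.0} <= alphas


def test_minimal_design_has_one_position():
    d = ap.build_test_design({
        "pitch_grid": [15.0], "series": ["pitch"], "movements": [], "replicates": 1,
    })
    assert len(d.positions()) == 1


def test_empty_grid_is_a_configuration_error():
    with pytest.raises(ValueError):
        ap.build_test_design({"pitch_grid": []})


def test_movement_extents_match_declared_set(design):
    extents = {(m.name, m.extent_deg, m.symmetric) for m in design.movements.values()}
    assert extents == {
        ("sym_protraction", 45.0, True),
        ("tail_dorsiflexion", 15.0, True),
        ("wing_tuck", 45.0, False),
        ("tail_lateral", 30.0, True),
        ("asym_pronation", 15.0, True),
    }


def test_identical_seed_gives_identical_records(design, geometry, noisy_suite):
    a = ap.simulate_taxon(noisy_suite["long_tailed"], design, geometry, 7)
    b = ap.simulate_taxon(noisy_suite["long_tailed"], design, geometry, 7)
    assert a.equals(b)
    c = ap.simulate_taxon(noisy_suite["long_tailed"], design, geometry, 8)
    assert not a.equals(c)


def test_single_record_round_trips_known_coefficient(geometry):
    """Zero noise, zero angles: the reduction chain returns C_m exactly."""
    truth = ap.truth_from_knots("t", [(0.0, 0.37, 0.0), (90.0, 0.37, 0.0)],
                                {"low": 0.0, "high": 0.0}, {"low": 0.0, "high": 0.0},
                                equilibrium_angle_deg=None,
                                noise_sd_force=0.0, noise_sd_torque=0.0)
    point = DesignPoint("pitch", 0.0, 0.0, 0.0, "baseline", 0.0)
    rec = ap.simulate_record(truth, point, geometry, seed=0)
    out = ap.to_com_frame(rec)
    C = ap.moment_coefficient(out.moment_com[1], rec.rho, rec.U,
                              geometry.snout_vent, geometry.planform_area)
    assert C == pytest.approx(0.37, rel=1e-12)


def test_sphere_zero_noise_records_are_identically_zero(design, geometry, noisefree_suite):
    records = ap.simulate_taxon(noisefree_suite["sphere"], design, geometry, 3)
    assert (records[["fx", "fy", "fz", "tx", "ty", "tz"]].to_numpy() == 0.0).all()


def test_coefficients_invariant_across_reynolds_sweep(geometry, noisefree_suite):
    """Quasi-static generator: Re 30k and 70k reduce to equal coefficients."""
    truth = noisefree_suite["long_tailed"]
    results = []
    for Re in (30000.0, 70000.0):
        U = Re * 1.5e-5 / geometry.snout_vent
        d = ap.build_test_design({"U": U})
        coeffs = reduce_taxon(truth, d, geometry, seed=4)
        results.append(coeffs.sort_values(
            ["series", "movement", "delta_deg", "phi_deg", "theta_deg", "psi_deg", "replicate"]
        )[["C_r", "C_m", "C_y"]].to_numpy())
    assert np.max(np.abs(results[0] - results[1])) < 1e-12


def test_noise_free_pipeline_recovers_analytic_slopes(noisefree_suite, noisefree_estimates):
    """End-to-end slope estimates equal the analytic derivatives (grid-exact)."""
    for name in ("long_tailed", "short_tailed", "weathervane"):
        truth = noisefree_suite[name]
        est = noisefree_estimates[name]
        for label, s_true in truth.slope_at.items():
            if s_true is None:
                continue
            assert est[label].slope == pytest.approx(s_true, abs=1e-9), (name, label)
        for key, k_true in truth.control.items():
            assert est[control_label(*key)].slope == pytest.approx(k_true, abs=1e-9), (name, key)


def test_long_tailed_equilibrium_in_expected_band(noisefree_estimates):
    eqs = noisefree_estimates["long_tailed"]["equilibria_deg"]
    assert len(eqs) == 1 and 10.0 <= eqs[0] <= 25.0


def test_short_tailed_has_single_low_unstable_equilibrium(noisefree_estimates):
    est = noisefree_estimates["short_tailed"]
    assert est["equilibria_deg"] == pytest.approx([4.0], abs=1e-6)
    assert est["stab_pitch_eq"].slope > 0


def test_fixture_suite_declared_truth_states(noisy_suite):
    sphere = noisy_suite["sphere"].character_states()
    assert all(sphere[l] == "marginal" for l in STABILITY_CHARACTERS)
    vane = noisy_suite["weathervane"].character_states()
    assert vane["stab_pitch_15"] == vane["stab_yaw_75"] == "stable"
    assert vane["stab_roll_15"] == "marginal"
    lt = noisy_suite["long_tailed"].character_states()
    st_ = noisy_suite["short_tailed"].character_states()
    assert lt["stab_pitch_eq"] == "stable"
    assert lt["ctrl_pitch_tail_dorsiflexion_15"] == "effective"
    assert st_["stab_pitch_15"] == "unstable"
    assert st_["ctrl_pitch_tail_dorsiflexion_15"] == "ineffective"
    assert st_["ctrl_pitch_sym_protraction_15"] == "effective"


def test_equilibrium_must_lie_on_the_curve():
    with pytest.raises(ValueError):
        ap.truth_from_knots("bad", [(0.0, 0.5, 0.0), (90.0, 0.5, 0.0)],
                            {"low": 0, "high": 0}, {"low": 0, "high": 0},
                            equilibrium_angle_deg=20.0)


def test_out_of_domain_angle_is_a_domain_error(noisy_suite, geometry):
    point = DesignPoint("pitch", 0.0, 140.0, 0.0, "baseline", 0.0)
    with pytest.raises(ValueError):
        ap.simulate_record(noisy_suite["sphere"], point, geometry, seed=0)


@pytest.mark.parametrize("s15,seq,s75", list(product(["stable", "marginal", "unstable"],
                                                     repeat=3)))
def test_random_truth_pitch_curves_have_intended_crossing_structure(s15, seq, s75):
    """Every stability-state combination yields exactly the designed trim point."""
    states = {"stab_pitch_15": s15, "stab_pitch_eq": seq, "stab_pitch_75": s75}
    truth, got = random_truth("t", np.random.default_rng(0), states)
    assert got["stab_pitch_0"] == s15
    xs = np.deg2rad(np.arange(0.0, 90.25, 0.25))
    y = truth.pitch_curve(xs)
    if seq == "marginal":
        assert np.all(y[xs < np.deg2rad(35)] > 0)
        assert np.all(y[xs > np.deg2rad(55)] < 0)
    else:
        sign_changes = int(np.sum(np.sign(y[:-1]) * np.sign(y[1:]) < 0))
        assert sign_changes == 1
        assert abs(float(truth.pitch_curve(np.deg2rad(45.0)))) < 1e-12


def test_random_truth_reports_all_twenty_states(rng):
    _, states = random_truth("t", rng)
    assert set(states) == set(CHARACTER_LABELS)
    assert len(CHARACTER_LABELS) == 20
    assert len(STABILITY_CHARACTERS) == 8 and len(CONTROL_CHARACTERS) == 12


def test_records_csv_round_trip(tmp_path, design, geometry, noisy_suite):
    from aerophylo.synthetic import read_records, write_records

    df = ap.simulate_taxon(noisy_suite["sphere"], design, geometry, 5)
    path = tmp_path / "records.csv"
    write_records(df, path)
    back = read_records(path)
    assert len(back) == len(df)
    assert np.allclose(back["ty"], df["ty"])
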