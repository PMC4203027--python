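"""Virtual wind tunnel: raw six-axis records for taxa with known aerodynamics.

The generator is the inverse of the data-reduction chain.  Each virtual
taxon carries analytic moment-coefficient curves; a test design enumerates
sting positions (series, orientation, appendage movement, deflection); for
every position the true coefficients are dimensionalized into tunnel-frame
moments, expressed at the sensor location, rotated into the sensor frame,
and corrupted with averaged Gaussian sensor noise.  Because the truth is
analytic, every downstream stage can be checked against exact ground truth.

Truth curves are piecewise cubic Hermite segments specified by
(angle, C, slope) knots, so target slopes at the evaluation points (0, 15,
75 degrees and the pitching equilibrium) are exact by construction; where
a slope is to be recovered by a windowed fit, the segment spanning that
window is linear.  Appendage control enters as an additive
``delta * dC/ddelta`` offset on the baseline curve (a linearized control
model).  Roll and yaw baselines are linear in their own perturbation angle
with separate slopes at the low (15 deg) and high (75 deg) angle-of-attack
regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicHermiteSpline

from .coefficients import DEFAULT_AIR_DENSITY, ModelGeometry
from .frames import euler_rotation_batch

__all__ = [
    "Movement",
    "MOVEMENTS",
    "CONTROL_CHARACTERS",
    "STABILITY_CHARACTERS",
    "TestDesign",
    "DesignPoint",
    "build_test_design",
    "AeroTruth",
    "truth_from_knots",
    "MeasurementRecord",
    "simulate_record",
    "simulate_taxon",
    "make_fixture_suite",
    "random_truth",
    "RECORD_COLUMNS",
    "write_records",
    "read_records",
]

LOW, HIGH = "low", "high"
REGIME_ALPHA = {LOW: 15.0, HIGH: 75.0}


@dataclass(frozen=True)
class Movement:
    """An appendage movement tested for control effectiveness.

    ``extent_deg`` is the deflection amplitude; symmetric movements are run
    at +/- extent and reduced by central differences, one-sided movements
    (e.g. tucking one wing) at + extent against the baseline.  ``series``
    lists the sweep series in which the movement is exercised and ``axes``
    the moment axes on which it acts.
    """

    name: str
    extent_deg: float
    symmetric: bool
    series: tuple
    axes: tuple


MOVEMENTS = {
    "sym_protraction": Movement("sym_protraction", 45.0, True, ("pitch",), ("pitch",)),
    "tail_dorsiflexion": Movement("tail_dorsiflexion", 15.0, True, ("pitch",), ("pitch",)),
    "wing_tuck": Movement("wing_tuck", 45.0, False, ("roll",), ("roll",)),
    "tail_lateral": Movement("tail_lateral", 30.0, True, ("yaw",), ("yaw",)),
    "asym_pronation": Movement("asym_pronation", 15.0, True, ("roll", "yaw"), ("roll", "yaw")),
}

#: the eight stability characters, in canonical order
STABILITY_CHARACTERS = (
    "stab_pitch_0",
    "stab_pitch_15",
    "stab_pitch_75",
    "stab_pitch_eq",
    "stab_roll_15",
    "stab_roll_75",
    "stab_yaw_15",
    "stab_yaw_75",
)

#: the twelve control-effectiveness characters as (axis, movement, regime)
CONTROL_CHARACTERS = tuple(
    (axis, movement, regime)
    for axis, movements in (
        ("pitch", ("tail_dorsiflexion", "sym_protraction")),
        ("roll", ("wing_tuck", "asym_pronation")),
        ("yaw", ("tail_lateral", "asym_pronation")),
    )
    for movement in movements
    for regime in (LOW, HIGH)
)


def control_label(axis: str, movement: str, regime: str) -> str:
    return f"ctrl_{axis}_{movement}_{int(REGIME_ALPHA[regime])}"


CHARACTER_LABELS = STABILITY_CHARACTERS + tuple(control_label(*c) for c in CONTROL_CHARACTERS)


@dataclass(frozen=True)
class DesignPoint:
    """One sting position: series, orientation, movement state."""

    series: str
    phi_deg: float
    theta_deg: float
    psi_deg: float
    movement: str  # "baseline" or a Movement name
    delta_deg: float


@dataclass
class TestDesign:
    """Automated-sting test matrix.

    Pitch series sweep angle of attack over ``pitch_grid``; roll and yaw
    series sweep their own perturbation angle over ``roll_grid``/``yaw_grid``
    at each angle of attack in ``aoa_values``.  Every series is repeated for
    the baseline posture and for each movement deflection state.
    """

    pitch_grid: tuple = tuple(float(a) for a in range(0, 95, 5))
    roll_grid: tuple = tuple(float(a) for a in range(-15, 20, 5))
    yaw_grid: tuple = tuple(float(a) for a in range(-15, 20, 5))
    aoa_values: tuple = (15.0, 75.0)
    series: tuple = ("pitch", "roll", "yaw")
    movements: dict = field(default_factory=lambda: dict(MOVEMENTS))
    replicates: int = 5
    U: float = 6.0  # m s^-1
    rho: float = DEFAULT_AIR_DENSITY  # kg m^-3

    def __post_init__(self) -> None:
        unknown = set(self.series) - {"pitch", "roll", "yaw"}
        if unknown or not self.series:
            raise ValueError(f"series must be a non-empty subset of pitch/roll/yaw: {self.series}")
        grids = {"pitch": ("pitch_grid", self.pitch_grid),
                 "roll": ("roll_grid", self.roll_grid),
                 "yaw": ("yaw_grid", self.yaw_grid)}
        for s in self.series:
            name, grid = grids[s]
            if len(grid) == 0:
                raise ValueError(f"{name} is empty")
        if len(self.aoa_values) == 0:
            raise ValueError("aoa_values is empty")
        if any(not (0.0 <= a <= 90.0) for a in self.pitch_grid):
            raise ValueError("pitch grid angles must lie in [0, 90] degrees")
        for grid in (self.roll_grid, self.yaw_grid):
            if any(not (-90.0 <= a <= 90.0) for a in grid):
                raise ValueError("deflection angles must lie in [-90, 90] degrees")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.U <= 0 or self.rho <= 0:
            raise ValueError("tunnel speed and air density must be positive")

    def _movement_states(self, series: str):
        """Deflection states run in one series: baseline plus movements."""
        states = [("baseline", 0.0)]
        for mv in self.movements.values():
            if series in mv.series:
                states.append((mv.name, mv.extent_deg))
                if mv.symmetric:
                    states.append((mv.name, -mv.extent_deg))
        return states

    def positions(self):
        """Deterministic enumeration of all test positions."""
        points = []
        if "pitch" in self.series:
            for movement, delta in self._movement_states("pitch"):
                for alpha in self.pitch_grid:
                    points.append(DesignPoint("pitch", 0.0, float(alpha), 0.0, movement, delta))
        if "roll" in self.series:
            for aoa in self.aoa_values:
                for movement, delta in self._movement_states("roll"):
                    for ang in self.roll_grid:
                        points.append(
                            DesignPoint("roll", float(ang), float(aoa), 0.0, movement, delta)
                        )
        if "yaw" in self.series:
            for aoa in self.aoa_values:
                for movement, delta in self._movement_states("yaw"):
                    for ang in self.yaw_grid:
                        points.append(
                            DesignPoint("yaw", 0.0, float(aoa), float(ang), movement, delta)
                        )
        return points


def build_test_design(config: dict | None = None) -> TestDesign:
    """Build a :class:`TestDesign` from a flat config mapping (or defaults)."""
    config = dict(config or {})
    kwargs = {}
    for key in ("pitch_grid", "roll_grid", "yaw_grid", "aoa_values"):
        if key in config:
            kwargs[key] = tuple(float(a) for a in config.pop(key))
    if "series" in config:
        kwargs["series"] = tuple(config.pop("series"))
    for key in ("replicates", "U", "rho"):
        if key in config:
            kwargs[key] = config.pop(key)
    if "movements" in config:
        requested = config.pop("movements")
        kwargs["movements"] = {name: MOVEMENTS[name] for name in requested}
    if config:
        raise ValueError(f"unknown design keys: {sorted(config)}")
    return TestDesign(**kwargs)


def _regime(alpha_deg: float) -> str:
    return LOW if alpha_deg < 45.0 else HIGH


@dataclass
class AeroTruth:
    """Ground-truth aerodynamics of one virtual taxon.

    ``pitch_curve`` is C_m(alpha) (alpha in radians); roll/yaw baselines are
    ``slope * angle`` with per-regime slopes.  ``control`` maps
    (axis, movement, regime) to the true dC/ddelta (per radian).
    ``slope_at`` stores the analytic stability derivatives at the canonical
    evaluation points, keyed by the stability character labels.
    """

    taxon_id: str
    pitch_curve: CubicHermiteSpline
    roll_slopes: dict
    yaw_slopes: dict
    control: dict
    equilibrium_angle_deg: float | None
    slope_at: dict
    noise_sd_force: float = 0.05  # N per raw sample
    noise_sd_torque: float = 0.012  # N m per raw sample
    n_samples: int = 600  # raw samples averaged into one recording

    def __post_init__(self) -> None:
        if self.noise_sd_force < 0 or self.noise_sd_torque < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.equilibrium_angle_deg is not None:
            c_eq = float(self.pitch_curve(np.deg2rad(self.equilibrium_angle_deg)))
            if abs(c_eq) > 1e-9:
                raise ValueError(
                    f"C_m({self.equilibrium_angle_deg} deg) = {c_eq}; equilibrium must sit on the curve"
                )

    def coefficients(self, point: DesignPoint) -> np.ndarray:
        """True (C_r, C_m, C_y) at a design point."""
        alpha = point.theta_deg
        lo, hi = np.deg2rad(-1.0), np.deg2rad(91.0)
        a_rad = np.deg2rad(alpha)
        if not (lo <= a_rad <= hi):
            raise ValueError(f"angle of attack {alpha} deg outside the defined curve domain")
        regime = _regime(alpha)
        C = np.array([
            self.roll_slopes[regime] * np.deg2rad(point.phi_deg),
            float(self.pitch_curve(a_rad)),
            self.yaw_slopes[regime] * np.deg2rad(point.psi_deg),
        ])
        if point.movement != "baseline":
            d_rad = np.deg2rad(point.delta_deg)
            for i, axis in enumerate(("roll", "pitch", "yaw")):
                C[i] += d_rad * self.control.get((axis, point.movement, regime), 0.0)
        return C

    def character_states(self, threshold: float = 0.09) -> dict:
        """Discretized states implied by the analytic truth (no noise)."""
        states = {}
        for label in STABILITY_CHARACTERS:
            s = self.slope_at.get(label)
            if s is None:
                states[label] = "?"
            else:
                states[label] = "marginal" if s == 0 else ("stable" if s < 0 else "unstable")
        for axis, movement, regime in CONTROL_CHARACTERS:
            k = self.control.get((axis, movement, regime), 0.0)
            states[control_label(axis, movement, regime)] = (
                "effective" if abs(k) > threshold else "ineffective"
            )
        return states


def truth_from_knots(
    taxon_id: str,
    pitch_knots,
    roll_slopes,
    yaw_slopes,
    control=None,
    equilibrium_angle_deg: float | None = None,
    **kwargs,
) -> AeroTruth:
    """Assemble an :class:`AeroTruth` from (angle_deg, C, slope_per_rad) knots.

    The pitch curve interpolates the knots with a cubic Hermite spline whose
    derivative at each knot equals the given slope exactly; the domain is
    padded to [-1, 91] degrees by linear extension so window fits at the
    grid edges stay inside the domain.
    """
    knots = sorted((float(a), float(c), float(s)) for a, c, s in pitch_knots)
    a0, c0, s0 = knots[0]
    a1, c1, s1 = knots[-1]
    pad = 1.0
    if a0 > -pad:
        knots.insert(0, (a0 - pad, c0 - s0 * np.deg2rad(pad), s0))
    if a1 < 90.0 + pad:
        knots.append((a1 + pad + (90.0 - a1), c1 + s1 * np.deg2rad(pad + 90.0 - a1), s1))
    x = np.deg2rad([k[0] for k in knots])
    y = np.array([k[1] for k in knots])
    dydx = np.array([k[2] for k in knots])
    curve = CubicHermiteSpline(x, y, dydx)
    dcurve = curve.derivative()

    slope_at = {
        "stab_pitch_0": float(dcurve(0.0)),
        "stab_pitch_15": float(dcurve(np.deg2rad(15.0))),
        "stab_pitch_75": float(dcurve(np.deg2rad(75.0))),
        "stab_roll_15": float(roll_slopes[LOW]),
        "stab_roll_75": float(roll_slopes[HIGH]),
        "stab_yaw_15": float(yaw_slopes[LOW]),
        "stab_yaw_75": float(yaw_slopes[HIGH]),
    }
    if equilibrium_angle_deg is not None:
        slope_at["stab_pitch_eq"] = float(dcurve(np.deg2rad(equilibrium_angle_deg)))
    else:
        slope_at["stab_pitch_eq"] = None
    return AeroTruth(
        taxon_id=taxon_id,
        pitch_curve=curve,
        roll_slopes=dict(roll_slopes),
        yaw_slopes=dict(yaw_slopes),
        control=dict(control or {}),
        equilibrium_angle_deg=equilibrium_angle_deg,
        slope_at=slope_at,
        **kwargs,
    )


RECORD_COLUMNS = [
    "taxon", "series", "phi_deg", "theta_deg", "psi_deg", "movement", "delta_deg",
    "U", "rho", "fx", "fy", "fz", "tx", "ty", "tz", "rx", "ry", "rz", "replicate",
]


@dataclass
class MeasurementRecord:
    """One raw recording: sensor-frame force/torque at a sting position."""

    taxon_id: str
    series: str
    phi_deg: float
    theta_deg: float
    psi_deg: float
    movement: str
    delta_deg: float
    U: float
    rho: float
    force_sensor: np.ndarray
    torque_sensor: np.ndarray
    sensor_offset: np.ndarray
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.U <= 0:
            raise ValueError("tunnel speed must be positive")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        self.force_sensor = np.asarray(self.force_sensor, dtype=float)
        self.torque_sensor = np.asarray(self.torque_sensor, dtype=float)
        self.sensor_offset = np.asarray(self.sensor_offset, dtype=float)
        if not (np.all(np.isfinite(self.force_sensor)) and np.all(np.isfinite(self.torque_sensor))):
            raise ValueError("force/torque readings must be finite")

    def to_row(self) -> dict:
        return {
            "taxon": self.taxon_id, "series": self.series,
            "phi_deg": self.phi_deg, "theta_deg": self.theta_deg, "psi_deg": self.psi_deg,
            "movement": self.movement, "delta_deg": self.delta_deg,
            "U": self.U, "rho": self.rho,
            "fx": self.force_sensor[0], "fy": self.force_sensor[1], "fz": self.force_sensor[2],
            "tx": self.torque_sensor[0], "ty": self.torque_sensor[1], "tz": self.torque_sensor[2],
            "rx": self.sensor_offset[0], "ry": self.sensor_offset[1], "rz": self.sensor_offset[2],
            "replicate": self.replicate,
        }


def simulate_record(truth: AeroTruth, point: DesignPoint, geometry: ModelGeometry,
                    seed, U: float = 6.0, rho: float = DEFAULT_AIR_DENSITY,
                    replicate: int = 1) -> MeasurementRecord:
    """Simulate a single recording at one design point.

    ``seed`` may be an int or a numpy Generator.  The recording is the mean
    of ``truth.n_samples`` noisy samples, drawn directly from the sampling
    distribution of the mean (sd / sqrt(n) per channel).  Identical
    (truth, point, geometry, seed) give an identical record.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = truth.coefficients(point)
    q = 0.5 * rho * U**2 * geometry.dynamic_scale
    M_com = C * q
    R = euler_rotation_batch(
        np.deg2rad([point.phi_deg]), np.deg2rad([point.theta_deg]), np.deg2rad([point.psi_deg])
    )[0]
    # no mean aerodynamic force is modeled (lift/drag are out of scope), so
    # the sensor-frame truth is F = 0 and M_sensor = R^T M_com
    root_n = np.sqrt(truth.n_samples)
    F_sensor = rng.normal(0.0, truth.noise_sd_force / root_n, 3)
    M_sensor = R.T @ M_com + rng.normal(0.0, truth.noise_sd_torque / root_n, 3)
    return MeasurementRecord(
        taxon_id=truth.taxon_id, series=point.series,
        phi_deg=point.phi_deg, theta_deg=point.theta_deg, psi_deg=point.psi_deg,
        movement=point.movement, delta_deg=point.delta_deg,
        U=U, rho=rho,
        force_sensor=F_sensor, torque_sensor=M_sensor,
        sensor_offset=geometry.sensor_offset, replicate=replicate,
    )


def simulate_taxon(truth: AeroTruth, design: TestDesign, geometry: ModelGeometry,
                   seed: int) -> pd.DataFrame:
    """Simulate the full test design for one taxon (vectorized).

    Identical (truth, design, seed) yield an identical table.
    """
    rng = np.random.default_rng(seed)
    points = design.positions()
    n_pos = len(points)
    reps = design.replicates
    phi = np.repeat([p.phi_deg for p in points], reps)
    theta = np.repeat([p.theta_deg for p in points], reps)
    psi = np.repeat([p.psi_deg for p in points], reps)
    C = np.repeat(np.array([truth.coefficients(p) for p in points]), reps, axis=0)
    q = 0.5 * design.rho * design.U**2 * geometry.dynamic_scale
    M_com = C * q
    R = euler_rotation_batch(np.deg2rad(phi), np.deg2rad(theta), np.deg2rad(psi))
    M_sensor = np.einsum("nji,nj->ni", R, M_com)  # R^T @ M
    n = n_pos * reps
    root_n = np.sqrt(truth.n_samples)
    F_sensor = rng.normal(0.0, truth.noise_sd_force / root_n, (n, 3))
    M_sensor = M_sensor + rng.normal(0.0, truth.noise_sd_torque / root_n, (n, 3))
    df = pd.DataFrame({
        "taxon": truth.taxon_id,
        "series": np.repeat([p.series for p in points], reps),
        "phi_deg": phi, "theta_deg": theta, "psi_deg": psi,
        "movement": np.repeat([p.movement for p in points], reps),
        "delta_deg": np.repeat([p.delta_deg for p in points], reps),
        "U": design.U, "rho": design.rho,
        "fx": F_sensor[:, 0], "fy": F_sensor[:, 1], "fz": F_sensor[:, 2],
        "tx": M_sensor[:, 0], "ty": M_sensor[:, 1], "tz": M_sensor[:, 2],
        "rx": geometry.sensor_offset[0], "ry": geometry.sensor_offset[1],
        "rz": geometry.sensor_offset[2],
        "replicate": np.tile(np.arange(1, reps + 1), n_pos),
    })
    return df[RECORD_COLUMNS]


def _zero_noise(truth: AeroTruth) -> AeroTruth:
    return replace(truth, noise_sd_force=0.0, noise_sd_torque=0.0)


def make_fixture_suite(noise: bool = True) -> dict:
    """Calibration and archetype taxa with known qualitative behavior.

    * ``sphere`` -- all coefficients identically zero: every stability slope
      is truly zero (marginal) and nothing is controllable.
    * ``weathervane`` -- strongly restoring in pitch and yaw (slope -0.9 per
      radian, the reference against which the 0.09 effectiveness threshold
      is one tenth); marginal in roll; no control surfaces.
    * ``long_tailed`` -- archetype of a long-tailed glider: stable pitching
      equilibrium at 17.5 deg (inside 10-25), stable slopes everywhere in
      pitch, highly effective tail.
    * ``short_tailed`` -- archetype of a short-tailed form: unstable
      equilibrium at 4 deg, unstable at low angle of attack, tail nearly
      ineffective, wings effective.
    """
    deg = np.deg2rad

    def lin(a0, a1, c_at, a_at, slope):
        """Knots for a linear segment through (a_at, c_at) with given slope."""
        return [(a0, c_at + slope * deg(a0 - a_at), slope),
                (a1, c_at + slope * deg(a1 - a_at), slope)]

    suite = {}
    # the sphere's curve is identically zero, so every angle is an
    # equilibrium with zero slope; 45 deg is declared as its representative
    suite["sphere"] = truth_from_knots(
        "sphere", [(0.0, 0.0, 0.0), (90.0, 0.0, 0.0)],
        {LOW: 0.0, HIGH: 0.0}, {LOW: 0.0, HIGH: 0.0}, {}, 45.0,
    )
    suite["weathervane"] = truth_from_knots(
        "weathervane", lin(0.0, 90.0, 0.0, 17.5, -0.9),
        {LOW: 0.0, HIGH: 0.0}, {LOW: -0.9, HIGH: -0.9}, {}, 17.5,
    )
    lt_ctrl = {
        ("pitch", "tail_dorsiflexion", LOW): 0.40, ("pitch", "tail_dorsiflexion", HIGH): 0.35,
        ("pitch", "sym_protraction", LOW): 0.15, ("pitch", "sym_protraction", HIGH): 0.12,
        ("roll", "wing_tuck", LOW): 0.40, ("roll", "wing_tuck", HIGH): 0.40,
        ("roll", "asym_pronation", LOW): 0.35, ("roll", "asym_pronation", HIGH): 0.30,
        ("yaw", "tail_lateral", LOW): 0.35, ("yaw", "tail_lateral", HIGH): 0.12,
        ("yaw", "asym_pronation", LOW): 0.30, ("yaw", "asym_pronation", HIGH): 0.30,
    }
    suite["long_tailed"] = truth_from_knots(
        "long_tailed",
        lin(0.0, 25.0, 0.0, 17.5, -0.6) + lin(65.0, 90.0, -0.35, 65.0, -0.25),
        {LOW: 0.3, HIGH: -0.4}, {LOW: -0.5, HIGH: 0.0}, lt_ctrl, 17.5,
    )
    st_ctrl = {
        ("pitch", "tail_dorsiflexion", LOW): 0.03, ("pitch", "tail_dorsiflexion", HIGH): 0.03,
        ("pitch", "sym_protraction", LOW): 0.30, ("pitch", "sym_protraction", HIGH): 0.25,
        ("roll", "wing_tuck", LOW): 0.45, ("roll", "wing_tuck", HIGH): 0.45,
        ("roll", "asym_pronation", LOW): 0.35, ("roll", "asym_pronation", HIGH): 0.30,
        ("yaw", "tail_lateral", LOW): 0.04, ("yaw", "tail_lateral", HIGH): 0.04,
        ("yaw", "asym_pronation", LOW): 0.30, ("yaw", "asym_pronation", HIGH): 0.30,
    }
    suite["short_tailed"] = truth_from_knots(
        "short_tailed",
        lin(0.0, 25.0, 0.0, 4.0, 0.5) + lin(65.0, 90.0, 0.35, 65.0, -0.25),
        {LOW: 0.3, HIGH: -0.4}, {LOW: 0.0, HIGH: 0.0}, st_ctrl, 4.0,
    )
    if not noise:
        suite = {name: _zero_noise(t) for name, t in suite.items()}
    return suite


#: fixed slope magnitudes used when drawing random ground truths
_STAB_SLOPE = {"stable": -0.4, "marginal": 0.0, "unstable": 0.4}
_CTRL_SLOPE = {"effective": 0.30, "ineffective": 0.02}


def random_truth(taxon_id: str, rng: np.random.Generator, states: dict | None = None):
    """A virtual taxon with per-character ground-truth states drawn at random.

    Returns ``(AeroTruth, states)`` where ``states`` maps every character
    label to its true discretized state.  Because the 0 and 15 degree pitch
    evaluation windows overlap on a 5 degree grid, those two characters
    share one low-angle slope (their states are identical by construction);
    all other characters are drawn independently.  The pitching equilibrium
    is placed at 45 degrees, between the two evaluation regimes.
    """
    states = dict(states) if states else {}

    def stab_state(label):
        if label not in states:
            states[label] = str(rng.choice(["stable", "marginal", "unstable"]))
        return states[label]

    low_state = stab_state("stab_pitch_15")
    states["stab_pitch_0"] = low_state
    s_low = _STAB_SLOPE[low_state]
    s_eq = _STAB_SLOPE[stab_state("stab_pitch_eq")]
    s_hi = _STAB_SLOPE[stab_state("stab_pitch_75")]
    roll_slopes = {LOW: _STAB_SLOPE[stab_state("stab_roll_15")],
                   HIGH: _STAB_SLOPE[stab_state("stab_roll_75")]}
    yaw_slopes = {LOW: _STAB_SLOPE[stab_state("stab_yaw_15")],
                  HIGH: _STAB_SLOPE[stab_state("stab_yaw_75")]}

    deg = np.deg2rad
    # sign layout guaranteeing a single (noise-free) crossing at 45 degrees:
    # the low-angle branch sits on the opposite side of zero from the sign
    # of the equilibrium slope, the high-angle branch on the same side
    lowsign = 1.0 if s_eq <= 0 else -1.0
    highsign = -lowsign
    c0 = lowsign * 0.35
    knots = [
        (0.0, c0, s_low), (25.0, c0 + s_low * deg(25.0), s_low),
        (35.0, s_eq * deg(-10.0), s_eq), (55.0, s_eq * deg(10.0), s_eq),
        (65.0, highsign * 0.35, s_hi), (90.0, highsign * 0.35 + s_hi * deg(25.0), s_hi),
    ]

    control = {}
    for axis, movement, regime in CONTROL_CHARACTERS:
        label = control_label(axis, movement, regime)
        if label not in states:
            states[label] = str(rng.choice(["effective", "ineffective"]))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        control[(axis, movement, regime)] = sign * _CTRL_SLOPE[states[label]]

    truth = truth_from_knots(taxon_id, knots, roll_slopes, yaw_slopes, control, 45.0)
    return truth, states


def write_records(records: pd.DataFrame, path) -> None:
    """Write a raw measurement table with the documented CSV header."""
    records[RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    return df


def load_sim_config(path) -> dict:
    """Flat key-value simulation config (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("simulation config must be a flat mapping")
    return cfg
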