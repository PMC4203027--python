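"""Static-stability and control-effectiveness derivatives with 75% intervals.

Static stability at an evaluation point is the slope of the moment
coefficient against the perturbation angle (in radians), estimated by
ordinary least squares over all replicate points whose angle lies within a
window (default +/-10 degrees, i.e. up to five points of a 5-degree grid)
around the evaluation point, with a two-sided Student-t confidence interval
(default level 0.75).  Control effectiveness is the paired difference
between deflected and baseline series: a central difference
``(C+ - C-) / (2 delta)`` when the movement was run at both signs, else a
one-sided difference against the baseline, averaged over the window, with a
t-interval over the paired per-point differences.

Pitching equilibria (trim points, C_m = 0) are located by linear
interpolation between adjacent grid points of the replicate-averaged pitch
series wherever the mean coefficient changes sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import (
    CONTROL_CHARACTERS,
    MOVEMENTS,
    REGIME_ALPHA,
    STABILITY_CHARACTERS,
    control_label,
)

__all__ = [
    "DerivativeEstimate",
    "InsufficientDataError",
    "find_equilibria",
    "stability_slope",
    "control_effectiveness",
    "estimate_taxon",
    "estimate_all",
    "estimates_to_frame",
    "frame_to_estimates",
]

AXIS_COEFF = {"pitch": "C_m", "roll": "C_r", "yaw": "C_y"}
DEFAULT_WINDOW_DEG = 10.0
DEFAULT_CI_LEVEL = 0.75


class InsufficientDataError(ValueError):
    """Raised when too few points fall in the estimation window."""


@dataclass
class DerivativeEstimate:
    """A slope (per radian) with a two-sided confidence interval."""

    taxon_id: str
    axis: str  # pitch | roll | yaw
    kind: str  # stability | control
    evaluation_point: str  # "0" | "15" | "75" | "eq" or "<movement>@<aoa>"
    slope: float
    ci_low: float
    ci_high: float
    n_points: int
    ci_level: float = DEFAULT_CI_LEVEL
    movement: str | None = None
    equilibrium_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("confidence interval must bracket the slope")


def find_equilibria(alpha_deg, c_m):
    """Zero crossings of a mean coefficient series, sorted by angle.

    Returns ``[(alpha_eq_deg, (i, j)), ...]`` where ``i, j`` bracket the
    crossing.  A run of exact zeros counts as a single crossing at its
    midpoint.  An empty list means no trim point in the tested range.
    """
    alpha = np.asarray(alpha_deg, dtype=float)
    c = np.asarray(c_m, dtype=float)
    if alpha.ndim != 1 or alpha.size != c.size or alpha.size < 2:
        raise ValueError("need matching 1-d series with at least two points")
    if np.any(np.diff(alpha) <= 0):
        raise ValueError("series must be sorted by strictly increasing angle")
    crossings = []
    i = 0
    n = alpha.size
    while i < n:
        if c[i] == 0.0:
            j = i
            while j + 1 < n and c[j + 1] == 0.0:
                j += 1
            crossings.append((float(0.5 * (alpha[i] + alpha[j])), (i, j)))
            i = j + 1
            continue
        if i + 1 < n and c[i] * c[i + 1] < 0.0:
            a_eq = alpha[i] - c[i] * (alpha[i + 1] - alpha[i]) / (c[i + 1] - c[i])
            crossings.append((float(a_eq), (i, i + 1)))
        i += 1
    return crossings


def _t_interval(estimate: float, se: float, df: int, ci_level: float):
    if df <= 0:
        return -np.inf, np.inf
    half = stats.t.ppf(0.5 + ci_level / 2.0, df) * se
    return estimate - half, estimate + half


def stability_slope(
    angles_deg,
    coeffs,
    center_deg: float,
    *,
    window_deg: float = DEFAULT_WINDOW_DEG,
    ci_level: float = DEFAULT_CI_LEVEL,
    taxon_id: str = "",
    axis: str = "pitch",
    evaluation_point: str | None = None,
) -> DerivativeEstimate:
    """OLS slope of coefficient on angle (radians) within a window.

    All replicate points with ``|angle - center| <= window`` enter one
    pooled fit; the interval is ``slope +/- t_{1-(1-ci)/2, n-2} * se``.
    """
    angles = np.asarray(angles_deg, dtype=float)
    c = np.asarray(coeffs, dtype=float)
    mask = np.abs(angles - center_deg) <= window_deg + 1e-9
    x = np.deg2rad(angles[mask])
    y = c[mask]
    if x.size < 3 or np.unique(x).size < 2:
        raise InsufficientDataError(
            f"{x.size} points within {window_deg} deg of {center_deg} deg (need >= 3)"
        )
    fit = stats.linregress(x, y)
    se = fit.stderr
    if not np.isfinite(se):  # constant y: perfect zero-slope fit
        se = 0.0
    lo, hi = _t_interval(fit.slope, se, x.size - 2, ci_level)
    return DerivativeEstimate(
        taxon_id=taxon_id, axis=axis, kind="stability",
        evaluation_point=evaluation_point or f"{center_deg:g}",
        slope=float(fit.slope), ci_low=float(lo), ci_high=float(hi),
        n_points=int(x.size), ci_level=ci_level,
    )


def _paired(series: pd.DataFrame, value_col: str) -> pd.Series:
    return series.set_index(["angle_deg", "replicate"])[value_col]


def control_effectiveness(
    baseline: pd.DataFrame | None,
    deflected_plus: pd.DataFrame,
    deflected_minus: pd.DataFrame | None,
    delta_extent_rad: float,
    center_deg: float,
    *,
    value_col: str = "C_m",
    window_deg: float = DEFAULT_WINDOW_DEG,
    ci_level: float = DEFAULT_CI_LEVEL,
    taxon_id: str = "",
    axis: str = "pitch",
    evaluation_point: str = "",
    movement: str | None = None,
) -> DerivativeEstimate:
    """dC/ddelta from paired deflected/baseline series near an evaluation point.

    Series are frames with ``angle_deg``, ``replicate`` and the coefficient
    column; points are paired on (angle, replicate).  With both deflection
    signs the estimate is the central difference ``(C+ - C-)/(2 delta)``,
    otherwise ``(C+ - C0)/delta`` against the baseline.
    """
    if delta_extent_rad <= 0:
        raise ValueError("deflection extent must be positive")
    plus = _paired(deflected_plus, value_col)
    if deflected_minus is not None and len(deflected_minus):
        ref = _paired(deflected_minus, value_col)
        denom = 2.0 * delta_extent_rad
    else:
        if baseline is None or not len(baseline):
            raise ValueError("one-sided control effectiveness requires a baseline series")
        ref = _paired(baseline, value_col)
        denom = delta_extent_rad
    diffs = (plus - ref).dropna() / denom
    angles = diffs.index.get_level_values("angle_deg").to_numpy(dtype=float)
    d = diffs.to_numpy()[np.abs(angles - center_deg) <= window_deg + 1e-9]
    if d.size == 0:
        raise InsufficientDataError("no paired points within the window")
    est = float(np.mean(d))
    if d.size > 1:
        se = float(np.std(d, ddof=1) / np.sqrt(d.size))
        lo, hi = _t_interval(est, se, d.size - 1, ci_level)
    else:
        lo = hi = est
    return DerivativeEstimate(
        taxon_id=taxon_id, axis=axis, kind="control",
        evaluation_point=evaluation_point or f"{movement}@{center_deg:g}",
        slope=est, ci_low=float(lo), ci_high=float(hi),
        n_points=int(d.size), ci_level=ci_level, movement=movement,
    )


def _select_equilibrium(crossings, slopes):
    """Trim point used for the equilibrium character.

    Prefer the lowest-angle crossing with a locally negative slope (a stable
    trim point); fall back to the lowest-angle crossing.
    """
    for (a_eq, _), s in zip(crossings, slopes):
        if s is not None and s < 0:
            return a_eq
    return crossings[0][0]


def estimate_taxon(
    coeffs: pd.DataFrame,
    *,
    window_deg: float = DEFAULT_WINDOW_DEG,
    ci_level: float = DEFAULT_CI_LEVEL,
    movements=None,
) -> dict:
    """All 8 stability and 12 control estimates for one taxon's coefficients.

    ``coeffs`` is the replicate-level coefficient table of a single taxon.
    Returns a mapping from character label to :class:`DerivativeEstimate`
    (or ``None`` where the data do not define the character, e.g. no trim
    point in range), plus the list of all trim points under
    ``"equilibria_deg"``.
    """
    movements = movements or MOVEMENTS
    taxon = str(coeffs["taxon"].iloc[0])
    out: dict = {}

    base_pitch = coeffs[(coeffs["series"] == "pitch") & (coeffs["movement"] == "baseline")]

    def stab(frame, center, axis, eval_pt):
        col = AXIS_COEFF[axis]
        try:
            return stability_slope(
                frame["angle_deg"], frame[col], center,
                window_deg=window_deg, ci_level=ci_level,
                taxon_id=taxon, axis=axis, evaluation_point=eval_pt,
            )
        except InsufficientDataError:
            return None

    out["stab_pitch_0"] = stab(base_pitch, 0.0, "pitch", "0")
    out["stab_pitch_15"] = stab(base_pitch, 15.0, "pitch", "15")
    out["stab_pitch_75"] = stab(base_pitch, 75.0, "pitch", "75")

    mean_series = (
        base_pitch.groupby("angle_deg", as_index=False)["C_m"].mean().sort_values("angle_deg")
    )
    crossings = find_equilibria(mean_series["angle_deg"], mean_series["C_m"])
    out["equilibria_deg"] = [a for a, _ in crossings]
    if crossings:
        local = [
            (e.slope if e is not None else None)
            for e in (stab(base_pitch, a, "pitch", "eq") for a, _ in crossings)
        ]
        a_eq = _select_equilibrium(crossings, local)
        est = stab(base_pitch, a_eq, "pitch", "eq")
        if est is not None:
            est.equilibrium_angle_deg = float(a_eq)
        out["stab_pitch_eq"] = est
    else:
        out["stab_pitch_eq"] = None

    for axis, series in (("roll", "roll"), ("yaw", "yaw")):
        for aoa in (15.0, 75.0):
            sub = coeffs[
                (coeffs["series"] == series)
                & (coeffs["movement"] == "baseline")
                & (coeffs["alpha_deg"] == aoa)
            ]
            out[f"stab_{axis}_{int(aoa)}"] = stab(sub, 0.0, axis, f"{int(aoa)}")

    for axis, mv_name, regime in CONTROL_CHARACTERS:
        label = control_label(axis, mv_name, regime)
        mv = movements.get(mv_name)
        if mv is None:
            out[label] = None
            continue
        aoa = REGIME_ALPHA[regime]
        # pitch movements ride the pitch sweep (window around the regime
        # angle of attack); roll/yaw movements ride their own series at the
        # regime angle of attack (window around zero perturbation)
        if axis == "pitch":
            sel = coeffs[coeffs["series"] == "pitch"]
            center = aoa
        else:
            sel = coeffs[(coeffs["series"] == axis) & (coeffs["alpha_deg"] == aoa)]
            center = 0.0
        base = sel[sel["movement"] == "baseline"]
        plus = sel[(sel["movement"] == mv_name) & (sel["delta_deg"] > 0)]
        minus = sel[(sel["movement"] == mv_name) & (sel["delta_deg"] < 0)] if mv.symmetric else None
        if not len(plus):
            out[label] = None
            continue
        try:
            out[label] = control_effectiveness(
                base, plus, minus, np.deg2rad(mv.extent_deg), center,
                value_col=AXIS_COEFF[axis], window_deg=window_deg, ci_level=ci_level,
                taxon_id=taxon, axis=axis, evaluation_point=f"{mv_name}@{int(aoa)}",
                movement=mv_name,
            )
        except InsufficientDataError:
            out[label] = None
    return out


def estimate_all(coeffs: pd.DataFrame, **kwargs) -> dict:
    """Per-taxon estimate maps for a multi-taxon coefficient table."""
    return {
        str(taxon): estimate_taxon(sub, **kwargs)
        for taxon, sub in coeffs.groupby("taxon", sort=True)
    }


_FRAME_COLUMNS = [
    "taxon", "character", "axis", "kind", "evaluation_point", "movement",
    "slope", "ci_low", "ci_high", "n_points", "ci_level", "equilibrium_angle_deg",
]


def estimates_to_frame(estimates: dict) -> pd.DataFrame:
    """Flatten ``estimate_all`` output into a tidy table (CSV-friendly)."""
    rows = []
    for taxon, per_char in estimates.items():
        for label, est in per_char.items():
            if label == "equilibria_deg" or est is None:
                continue
            rows.append({
                "taxon": taxon, "character": label, "axis": est.axis, "kind": est.kind,
                "evaluation_point": est.evaluation_point, "movement": est.movement,
                "slope": est.slope, "ci_low": est.ci_low, "ci_high": est.ci_high,
                "n_points": est.n_points, "ci_level": est.ci_level,
                "equilibrium_angle_deg": est.equilibrium_angle_deg,
            })
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def frame_to_estimates(frame: pd.DataFrame) -> dict:
    """Inverse of :func:`estimates_to_frame` (missing cells stay absent)."""
    out: dict = {}
    for _, row in frame.iterrows():
        est = DerivativeEstimate(
            taxon_id=row["taxon"], axis=row["axis"], kind=row["kind"],
            evaluation_point=str(row["evaluation_point"]),
            slope=float(row["slope"]), ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]), n_points=int(row["n_points"]),
            ci_level=float(row["ci_level"]),
            movement=None if pd.isna(row["movement"]) else row["movement"],
            equilibrium_angle_deg=(
                None if pd.isna(row["equilibrium_angle_deg"]) else float(row["equilibrium_angle_deg"])
            ),
        )
        out.setdefault(str(row["taxon"]), {})[row["character"]] = est
    return out
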