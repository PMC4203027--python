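"""Sensor-to-tunnel frame transformation of six-axis load-cell measurements.

A model on a sting is oriented by roll/pitch/yaw angles; the load cell
reads forces and torques in its own (body-fixed) frame.  Reduction rotates
the readings into the tunnel-aligned frame and moves the moment reference
from the sensor mount to the model's center of mass (COM).

Conventions (fixed here and used consistently by the synthetic generator):

* tunnel frame: x downstream along the flow, y starboard, z completing a
  right-handed triad;
* Euler sequence: ``R = R_yaw(psi) @ R_pitch(theta) @ R_roll(phi)`` acting
  on column vectors (intrinsic z-y'-x'' / standard aerospace order);
* moment components are ordered (roll, pitch, yaw) about (x, y, z), with
  nose-up pitch, right-wing-down roll and nose-right yaw positive, so a
  negative d(coefficient)/d(angle) is restoring (statically stable);
* angles are degrees at all I/O boundaries and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BodyFrameMoment",
    "euler_rotation",
    "euler_rotation_batch",
    "to_com_frame",
    "average_replicates",
    "transform_records",
]


def euler_rotation(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rotation matrix from sensor/body frame to the tunnel frame.

    Parameters are roll ``phi``, pitch ``theta`` and yaw ``psi`` in radians.
    Returns the 3x3 proper rotation ``R_z(psi) R_y(theta) R_x(phi)``.
    """
    angles = np.array([phi, theta, psi], dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError(f"non-finite Euler angles: {angles}")
    return euler_rotation_batch(angles[:1], angles[1:2], angles[2:3])[0]


def euler_rotation_batch(phi: np.ndarray, theta: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Vectorized :func:`euler_rotation`; inputs in radians, output (n, 3, 3)."""
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    psi = np.asarray(psi, dtype=float)
    cf, sf = np.cos(phi), np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(psi), np.sin(psi)
    R = np.empty(phi.shape + (3, 3), dtype=float)
    # R_z(psi) @ R_y(theta) @ R_x(phi), expanded
    R[..., 0, 0] = cp * ct
    R[..., 0, 1] = cp * st * sf - sp * cf
    R[..., 0, 2] = cp * st * cf + sp * sf
    R[..., 1, 0] = sp * ct
    R[..., 1, 1] = sp * st * sf + cp * cf
    R[..., 1, 2] = sp * st * cf - cp * sf
    R[..., 2, 0] = -st
    R[..., 2, 1] = ct * sf
    R[..., 2, 2] = ct * cf
    return R


@dataclass
class BodyFrameMoment:
    """One transformed recording: tunnel-frame force, COM-referenced moment.

    ``moment_com`` components are ordered (roll, pitch, yaw).  ``alpha_deg``
    is the angle of attack (the pitch angle of the mount) and
    ``angle_deg`` the angle swept by the series this record belongs to
    (alpha for pitch series, roll/yaw angle otherwise).
    """

    taxon_id: str
    series: str
    movement: str
    delta_deg: float
    alpha_deg: float
    angle_deg: float
    replicate: int
    force_tunnel: np.ndarray = field(default_factory=lambda: np.zeros(3))
    moment_com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_replicates: int = 1


def _series_angle(series: str, phi: float, theta: float, psi: float) -> float:
    if series == "pitch":
        return theta
    if series == "roll":
        return phi
    if series == "yaw":
        return psi
    raise ValueError(f"unknown series {series!r}")


def to_com_frame(record) -> BodyFrameMoment:
    """Transform one raw measurement into a :class:`BodyFrameMoment`.

    ``F_tunnel = R F_sensor`` and ``M_com = R M_sensor + (R r) x F_tunnel``
    where ``r`` is the COM-to-sensor offset expressed in body coordinates.
    """
    phi, theta, psi = (
        np.deg2rad(record.phi_deg),
        np.deg2rad(record.theta_deg),
        np.deg2rad(record.psi_deg),
    )
    R = euler_rotation(phi, theta, psi)
    F_sensor = np.asarray(record.force_sensor, dtype=float)
    M_sensor = np.asarray(record.torque_sensor, dtype=float)
    r = np.asarray(record.sensor_offset, dtype=float)
    if not (np.all(np.isfinite(F_sensor)) and np.all(np.isfinite(M_sensor))):
        raise ValueError("non-finite force/torque reading")
    F_tunnel = R @ F_sensor
    M_com = R @ M_sensor + np.cross(R @ r, F_tunnel)
    return BodyFrameMoment(
        taxon_id=record.taxon_id,
        series=record.series,
        movement=record.movement,
        delta_deg=record.delta_deg,
        alpha_deg=record.theta_deg,
        angle_deg=_series_angle(record.series, record.phi_deg, record.theta_deg, record.psi_deg),
        replicate=record.replicate,
        force_tunnel=F_tunnel,
        moment_com=M_com,
    )


#: columns identifying one physical test position (everything but replicate)
POSITION_KEYS = [
    "taxon",
    "series",
    "movement",
    "delta_deg",
    "phi_deg",
    "theta_deg",
    "psi_deg",
]


def transform_records(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized frame transformation of a raw measurement table.

    Expects the documented CSV layout (``fx..tz`` sensor readings and
    ``rx, ry, rz`` COM-to-sensor offsets) and returns one row per recording
    with tunnel-frame forces ``Fx,Fy,Fz``, COM moments ``Mx,My,Mz`` (roll,
    pitch, yaw), plus ``alpha_deg`` and the series sweep angle ``angle_deg``.
    """
    phi = np.deg2rad(records["phi_deg"].to_numpy())
    theta = np.deg2rad(records["theta_deg"].to_numpy())
    psi = np.deg2rad(records["psi_deg"].to_numpy())
    R = euler_rotation_batch(phi, theta, psi)
    F = records[["fx", "fy", "fz"]].to_numpy()
    M = records[["tx", "ty", "tz"]].to_numpy()
    r = records[["rx", "ry", "rz"]].to_numpy()
    F_t = np.einsum("nij,nj->ni", R, F)
    M_com = np.einsum("nij,nj->ni", R, M) + np.cross(np.einsum("nij,nj->ni", R, r), F_t)

    out = records[POSITION_KEYS + ["replicate", "U", "rho"]].copy()
    out[["Fx", "Fy", "Fz"]] = F_t
    out[["Mx", "My", "Mz"]] = M_com
    out["alpha_deg"] = records["theta_deg"]
    angle = np.where(
        records["series"] == "pitch",
        records["theta_deg"],
        np.where(records["series"] == "roll", records["phi_deg"], records["psi_deg"]),
    )
    out["angle_deg"] = angle
    return out


def average_replicates(moments, keys=None) -> pd.DataFrame:
    """Arithmetic mean of force/moment components over replicates per position.

    Accepts a transformed-moment DataFrame or a list of
    :class:`BodyFrameMoment`.  The replicate count is kept as
    ``n_replicates`` so confidence intervals can still be formed downstream.
    """
    if not isinstance(moments, pd.DataFrame):
        moments = pd.DataFrame([
            {
                "taxon": m.taxon_id, "series": m.series, "movement": m.movement,
                "delta_deg": m.delta_deg, "alpha_deg": m.alpha_deg,
                "angle_deg": m.angle_deg,
                "Fx": m.force_tunnel[0], "Fy": m.force_tunnel[1], "Fz": m.force_tunnel[2],
                "Mx": m.moment_com[0], "My": m.moment_com[1], "Mz": m.moment_com[2],
            }
            for m in moments
        ])
        keys = keys or ["taxon", "series", "movement", "delta_deg", "angle_deg"]
    if len(moments) == 0:
        raise ValueError("no records to average")
    keys = list(keys) if keys is not None else [k for k in POSITION_KEYS if k in moments.columns]
    value_cols = [
        c for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz", "C_r", "C_m", "C_y",
                    "alpha_deg", "angle_deg", "U", "rho")
        if c in moments.columns
    ]
    grouped = moments.groupby(keys, sort=False, as_index=False)
    out = grouped[value_cols].mean()
    out["n_replicates"] = grouped.size()["size"].to_numpy()
    return out
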