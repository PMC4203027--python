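"""Nondimensionalization of body-frame moments and Reynolds number.

A moment ``M`` about any axis is reduced to a dimensionless coefficient by

    C = M / (0.5 rho U^2 lambda S)

with ``lambda`` the snout-vent length (the moment reference length) and
``S`` the planform area.  The same snout-vent length serves as the length
scale in ``Re = U L / nu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelGeometry",
    "moment_coefficient",
    "reynolds",
    "coefficients_from_moments",
    "DEFAULT_AIR_DENSITY",
    "DEFAULT_KINEMATIC_VISCOSITY",
]

#: air at roughly 20 C, sea level
DEFAULT_AIR_DENSITY = 1.204  # kg m^-3
DEFAULT_KINEMATIC_VISCOSITY = 1.5e-5  # m^2 s^-1


@dataclass
class ModelGeometry:
    """Per-taxon reference geometry used for nondimensionalization.

    ``sensor_offset`` is the COM-to-sensor vector in body coordinates (m),
    e.g. a sting exiting downwind behind the COM.
    """

    taxon_id: str
    snout_vent: float = 0.08  # m; also the Reynolds length scale
    planform_area: float = 0.02  # m^2
    sensor_offset: np.ndarray = field(default_factory=lambda: np.array([-0.05, 0.0, 0.0]))

    def __post_init__(self) -> None:
        if self.snout_vent <= 0 or self.planform_area <= 0:
            raise ValueError("snout-vent length and planform area must be positive")
        self.sensor_offset = np.asarray(self.sensor_offset, dtype=float)

    @property
    def dynamic_scale(self) -> float:
        """``lambda * S`` (m^3); multiply by dynamic pressure to scale moments."""
        return self.snout_vent * self.planform_area


def moment_coefficient(M, rho: float, U: float, snout_vent: float, planform_area: float):
    """Dimensionless moment coefficient ``M / (0.5 rho U^2 lambda S)``.

    Accepts scalar or array ``M``; all reference quantities must be positive.
    """
    for name, value in (("rho", rho), ("U", U), ("snout_vent", snout_vent),
                        ("planform_area", planform_area)):
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")
    return np.asarray(M, dtype=float) / (0.5 * rho * U**2 * snout_vent * planform_area)


def reynolds(U: float, L: float, nu: float = DEFAULT_KINEMATIC_VISCOSITY) -> float:
    """Reynolds number ``U L / nu`` with L the snout-vent length."""
    for name, value in (("U", U), ("L", L), ("nu", nu)):
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")
    return U * L / nu


def coefficients_from_moments(moments: pd.DataFrame, geometries) -> pd.DataFrame:
    """Reduce a transformed-moment table to moment coefficients.

    ``geometries`` maps taxon id to :class:`ModelGeometry`.  Adds ``C_r``,
    ``C_m``, ``C_y`` columns; rows keep replicate identity so the scatter
    across replicates remains available to the derivative estimators.
    """
    lam_s = moments["taxon"].map(
        lambda t: geometries[t].dynamic_scale if not isinstance(geometries, ModelGeometry)
        else geometries.dynamic_scale
    ).to_numpy()
    q = 0.5 * moments["rho"].to_numpy() * moments["U"].to_numpy() ** 2
    denom = q * lam_s
    if np.any(denom <= 0):
        raise ValueError("non-positive dynamic scale; check rho, U and geometry")
    out = moments.copy()
    out["C_r"] = moments["Mx"].to_numpy() / denom
    out["C_m"] = moments["My"].to_numpy() / denom
    out["C_y"] = moments["Mz"].to_numpy() / denom
    return out
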