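"""Phantom material-property characterisation.

A tissue-mimicking agar/polyethylene gel phantom is characterised by its
density rho, specific heat capacity Cp, thermal diffusivity K, thermal
conductivity kappa, electrical conductivity sigma, relative permittivity
eps_r, and the heat transfer coefficient h coupling its surface to the
room.  The four thermal quantities are linked by

    kappa = K * rho * Cp        [W/m/degC]

so measuring diffusivity (laser flash), density and heat capacity fixes
the conductivity.  The heat transfer coefficient is not measured
directly: the phantom is left to cool in the scanner room for many hours
while fibre-optic probes log its temperature, and h is taken as the
value whose simulated cooling curve best matches the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .util import round_half_up
from .constants import KCAL_TO_J

__all__ = [
    "MaterialProps",
    "RecipeComponent",
    "CoolingCurve",
    "thermal_conductivity",
    "specific_heat_from_recipe",
    "percent_difference",
    "fit_heat_transfer_coefficient",
]


@dataclass
class MaterialProps:
    """Material properties of a phantom region, SI units throughout.

    Parameters
    ----------
    density : float
        rho, kg/m^3.
    specific_heat : float
        Cp, J/kg/degC.
    thermal_diffusivity : float, optional
        K, m^2/s.
    thermal_conductivity : float, optional
        kappa, W/m/degC.  If both K and kappa are given they must agree
        with ``kappa = K*rho*Cp`` to 1e-9 relative; if only one is given
        the other is derived.
    conductivity : float, optional
        Electrical conductivity sigma, S/m.
    rel_permittivity : float, optional
        Relative permittivity eps_r (dimensionless).
    heat_transfer_coeff : float, optional
        h, W/m^2/degC.
    """

    density: float
    specific_heat: float
    thermal_diffusivity: float | None = None
    thermal_conductivity: float | None = None
    conductivity: float | None = None
    rel_permittivity: float | None = None
    heat_transfer_coeff: float | None = None

    def __post_init__(self) -> None:
        for name in ("density", "specific_heat", "thermal_diffusivity",
                     "thermal_conductivity", "conductivity",
                     "rel_permittivity", "heat_transfer_coeff"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.thermal_diffusivity is None and self.thermal_conductivity is not None:
            self.thermal_diffusivity = (
                self.thermal_conductivity / (self.density * self.specific_heat))
        elif self.thermal_conductivity is None and self.thermal_diffusivity is not None:
            self.thermal_conductivity = thermal_conductivity(
                self.thermal_diffusivity, self.density, self.specific_heat)
        elif self.thermal_diffusivity is not None and self.thermal_conductivity is not None:
            implied = thermal_conductivity(
                self.thermal_diffusivity, self.density, self.specific_heat)
            if abs(implied - self.thermal_conductivity) > 1e-9 * abs(self.thermal_conductivity):
                raise ValueError(
                    "thermal_conductivity inconsistent with K*rho*Cp: "
                    f"{self.thermal_conductivity} vs implied {implied}")

    def to_json(self, path: str | Path) -> None:
        keys = {
            "density_kg_per_m3": self.density,
            "specific_heat_J_per_kg_C": self.specific_heat,
            "thermal_diffusivity_m2_per_s": self.thermal_diffusivity,
            "thermal_conductivity_W_per_m_C": self.thermal_conductivity,
            "conductivity_S_per_m": self.conductivity,
            "rel_permittivity": self.rel_permittivity,
            "heat_transfer_coeff_W_per_m2_C": self.heat_transfer_coeff,
        }
        Path(path).write_text(json.dumps(
            {k: v for k, v in keys.items() if v is not None}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaterialProps":
        d = json.loads(Path(path).read_text())
        return cls(
            density=d["density_kg_per_m3"],
            specific_heat=d["specific_heat_J_per_kg_C"],
            thermal_diffusivity=d.get("thermal_diffusivity_m2_per_s"),
            thermal_conductivity=d.get("thermal_conductivity_W_per_m_C"),
            conductivity=d.get("conductivity_S_per_m"),
            rel_permittivity=d.get("rel_permittivity"),
            heat_transfer_coeff=d.get("heat_transfer_coeff_W_per_m2_C"),
        )


@dataclass(frozen=True)
class RecipeComponent:
    """One ingredient of the gel recipe: a mass and its specific heat."""

    name: str
    mass: float            # kg
    specific_heat: float   # same unit family for all components

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"mass must be >= 0, got {self.mass}")
        if self.specific_heat <= 0:
            raise ValueError(
                f"specific_heat must be > 0, got {self.specific_heat}")


@dataclass
class CoolingCurve:
    """Probe temperature log from a passive cooling experiment."""

    times: np.ndarray          # s, strictly increasing
    temperatures: np.ndarray   # degC
    probe_location: np.ndarray = field(
        default_factory=lambda: np.zeros(3))  # mm, phantom frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.probe_location = np.asarray(self.probe_location, dtype=float)
        if self.times.shape != self.temperatures.shape:
            raise ValueError("times and temperatures must have equal length")
        if self.times.size < 2:
            raise ValueError("a cooling curve needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path: str | Path, probe: str = "probe0") -> None:
        pd.DataFrame({"time_s": self.times, "temp_C": self.temperatures,
                      "probe": probe}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, probe: str | None = None,
                 probe_location: Sequence[float] = (0.0, 0.0, 0.0)) -> "CoolingCurve":
        df = pd.read_csv(path)
        if probe is not None:
            df = df[df["probe"] == probe]
        return cls(times=df["time_s"].to_numpy(),
                   temperatures=df["temp_C"].to_numpy(),
                   probe_location=np.asarray(probe_location, dtype=float))


def thermal_conductivity(K: float, rho: float, Cp: float) -> float:
    """Thermal conductivity kappa = K * rho * Cp.

    Parameters
    ----------
    K : float
        Thermal diffusivity, m^2/s (zero permitted).
    rho : float
        Density, kg/m^3.
    Cp : float
        Specific heat, J/kg/degC.

    Returns
    -------
    float
        kappa in W/m/degC.
    """
    if K < 0 or rho <= 0 or Cp <= 0:
        raise ValueError("K must be >= 0 and rho, Cp strictly positive")
    return K * rho * Cp


def specific_heat_from_recipe(components: Sequence[RecipeComponent]) -> float:
    """Mass-weighted mean specific heat of a multi-component recipe.

    The output is in whatever specific-heat unit the components carry
    (the gel literature tabulates kcal/kg/degC; multiply by
    :data:`~prftherm.constants.KCAL_TO_J` for SI).
    """
    if not components:
        raise ValueError("recipe must contain at least one component")
    total_mass = sum(c.mass for c in components)
    if total_mass <= 0:
        raise ValueError("total recipe mass must be positive")
    return sum(c.mass * c.specific_heat for c in components) / total_mass


def percent_difference(measured: float, reference: float) -> float:
    """Signed percent difference 100*(measured - reference)/reference."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (measured - reference) / reference


def percent_difference_rounded(measured: float, reference: float,
                               ndigits: int = 1) -> float:
    """Percent difference rounded half-up for table display."""
    return round_half_up(percent_difference(measured, reference), ndigits)


def fit_heat_transfer_coefficient(curves, scenario_factory, sweep,
                                  sensors=None):
    """Estimate h by matching simulated cooling curves to probe logs.

    Sweeps candidate heat transfer coefficients, runs the transient
    thermal solver for each, and returns the candidate minimising the
    summed squared residual between simulated and observed probe
    temperatures over all provided curves.

    Parameters
    ----------
    curves : CoolingCurve or sequence of CoolingCurve
        Observed probe logs.  When several probes are given (e.g. the
        centre and edge probes) their residuals are summed, unweighted.
    scenario_factory : callable
        ``scenario_factory(h)`` -> :class:`~prftherm.thermal.ThermalScenario`
        describing the cooling set-up (geometry, material, initial and
        ambient temperatures) with heat transfer coefficient ``h``.
    sweep : dict or sequence
        Either ``{"min": .., "max": .., "step": ..}`` in W/m^2/degC or
        an explicit sequence of candidate values.
    sensors : list of SensorSpec, optional
        Sensor per curve; defaults to a sensor at each curve's
        ``probe_location``.

    Returns
    -------
    tuple
        ``(h_best, residuals)`` with ``residuals`` a dict mapping each
        candidate h to its summed squared residual in degC^2.
    """
    from .thermal import SensorSpec, simulate

    if isinstance(curves, CoolingCurve):
        curves = [curves]
    if isinstance(sweep, dict):
        candidates = np.arange(sweep["min"],
                               sweep["max"] + 0.5 * sweep["step"],
                               sweep["step"])
    else:
        candidates = np.asarray(list(sweep), dtype=float)
    if candidates.size == 0:
        raise ValueError("empty sweep")
    if sensors is None:
        sensors = [SensorSpec(location=c.probe_location, name=f"probe{i}")
                   for i, c in enumerate(curves)]

    residuals: dict[float, float] = {}
    for h in candidates:
        scenario = scenario_factory(float(h))
        result = simulate(scenario, sensors=sensors,
                          sensor_times=np.unique(np.concatenate(
                              [c.times for c in curves])))
        ssr = 0.0
        for curve, sensor in zip(curves, sensors):
            sim = np.interp(curve.times, result.sensor_times,
                            result.sensor_series[sensor.name])
            ssr += float(np.sum((sim - curve.temperatures) ** 2))
        residuals[float(h)] = ssr
    h_best = min(residuals, key=residuals.get)
    return h_best, residuals
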