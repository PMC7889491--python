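"""Sensitivity and uncertainty analysis of the thermal simulation.

For each input parameter p of the simulation, a paired run (default
value p0 vs adjusted value p1, typically a ~10% change) yields thermal
elevations T0 and T1 at the sensor, from which

    sensitivity = |dT/T0| / |dp/p0|          [% per %]

or, for probe-position rows where a relative change is meaningless,

    sensitivity = 100 * |dT/T0| / |dx|       [% per mm].

The uncertainty contributed by the parameter is the sensitivity times
the measurement standard deviation of the parameter (as % of its
default, or mm for positions); contributions combine linearly into a
group total.  Sensitivities are carried unrounded and only rounded
half-up to two decimals for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .util import round_half_up

__all__ = [
    "SensitivityRow",
    "SensitivityTable",
    "sensitivity_factor",
    "sensitivity_per_mm",
    "uncertainty_pct",
    "total_uncertainty",
    "perturbation_study",
    "Perturbation",
]


def sensitivity_factor(p0: float, p1: float, T0: float, T1: float) -> float:
    """Percent change in elevation per percent change of the parameter."""
    if p0 == 0:
        raise ValueError("default parameter value must be nonzero")
    if T0 <= 0:
        raise ValueError("default thermal elevation must be positive")
    if p1 == p0:
        raise ValueError("zero perturbation: adjusted equals default")
    return abs((T1 - T0) / T0) / abs((p1 - p0) / p0)


def sensitivity_per_mm(x0: float, x1: float, T0: float, T1: float) -> float:
    """Percent change in elevation per millimetre of displacement."""
    if x1 == x0:
        raise ValueError("zero displacement")
    if T0 <= 0:
        raise ValueError("default thermal elevation must be positive")
    return 100.0 * abs((T1 - T0) / T0) / abs(x1 - x0)


def uncertainty_pct(sensitivity: float, std: float) -> float:
    """Uncertainty contribution: sensitivity times standard deviation."""
    if sensitivity < 0 or std < 0:
        raise ValueError("sensitivity and std must be nonnegative")
    return sensitivity * std


def total_uncertainty(uncertainties: Sequence[float]) -> float:
    """Linear (simple-sum) combination of row uncertainties, in %."""
    vals = list(uncertainties)
    if not vals:
        raise ValueError("need at least one row")
    return float(sum(vals))


@dataclass
class SensitivityRow:
    """One parameter's entry of the sensitivity table.

    ``per_mm`` rows carry std in mm and sensitivity in %/mm; all others
    carry std as % of the default value and sensitivity in %/%.
    When printed reference values are stored verbatim (``sensitivity``
    / ``uncertainty`` set explicitly), ``consistency`` records whether
    they reproduce from the elevations; recomputed rows are always
    consistent.
    """

    parameter: str
    default: float
    adjusted: float
    unit: str = ""
    elevation_default: float = 1.0     # degC
    elevation_adjusted: float = 1.0    # degC
    std: float = 0.0
    per_mm: bool = False
    group: str = ""
    sensitivity: float | None = None   # verbatim printed value, if stored
    uncertainty: float | None = None
    consistency: bool = True

    def computed_sensitivity(self) -> float:
        if self.per_mm:
            return sensitivity_per_mm(self.default, self.adjusted,
                                      self.elevation_default,
                                      self.elevation_adjusted)
        if self.elevation_adjusted == self.elevation_default:
            return 0.0
        return sensitivity_factor(self.default, self.adjusted,
                                  self.elevation_default,
                                  self.elevation_adjusted)

    def computed_uncertainty(self) -> float:
        return uncertainty_pct(self.computed_sensitivity(), self.std)

    def display_sensitivity(self) -> float:
        s = self.sensitivity if self.sensitivity is not None \
            else self.computed_sensitivity()
        return round_half_up(s, 2)

    def display_uncertainty(self) -> float:
        if self.uncertainty is not None:
            return round_half_up(self.uncertainty, 2)
        return round_half_up(self.computed_uncertainty(), 2)


@dataclass
class SensitivityTable:
    """Grouped sensitivity rows with per-group linear totals."""

    rows: list[SensitivityRow] = field(default_factory=list)

    def groups(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.group not in seen:
                seen.append(r.group)
        return seen

    def group_total(self, group: str) -> float:
        vals = [r.display_uncertainty() for r in self.rows if r.group == group]
        return round_half_up(total_uncertainty(vals), 2)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            unit_suffix = "%/mm" if r.per_mm else "%/%"
            recs.append({
                "group": r.group,
                "parameter": r.parameter,
                "unit": r.unit,
                "default": r.default,
                "adjusted": r.adjusted,
                "elevation_default_C": r.elevation_default,
                "elevation_adjusted_C": r.elevation_adjusted,
                "sensitivity": r.display_sensitivity(),
                "sensitivity_unit": unit_suffix,
                "std": r.std,
                "std_unit": "mm" if r.per_mm else "%",
                "uncertainty_pct": r.display_uncertainty(),
                "consistency": r.consistency,
            })
        return pd.DataFrame(recs)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class Perturbation:
    """One parameter perturbation of a scenario."""

    path: str                  # attribute path into the scenario object
    adjusted: float
    std: float                 # % of default, or mm for positions
    per_mm: bool = False
    unit: str = ""
    group: str = ""


def _get_path(obj, path: str):
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def _with_path(obj, path: str, value):
    """Return a copy of a (nested) dataclass with one field replaced."""
    from .props import MaterialProps

    parts = path.split(".")
    if len(parts) == 1:
        if isinstance(obj, MaterialProps):
            # rho/Cp/kappa perturbations hold kappa (the solver input)
            # and re-derive diffusivity; a K perturbation re-derives kappa
            kw = dict(density=obj.density, specific_heat=obj.specific_heat,
                      thermal_diffusivity=obj.thermal_diffusivity,
                      thermal_conductivity=obj.thermal_conductivity,
                      conductivity=obj.conductivity,
                      rel_permittivity=obj.rel_permittivity,
                      heat_transfer_coeff=obj.heat_transfer_coeff)
            kw[parts[0]] = value
            if parts[0] == "thermal_diffusivity":
                kw["thermal_conductivity"] = None
            elif parts[0] in ("density", "specific_heat",
                              "thermal_conductivity"):
                kw["thermal_diffusivity"] = None
            return MaterialProps(**kw)
        return replace(obj, **{parts[0]: value})
    child = getattr(obj, parts[0])
    return replace(obj, **{parts[0]: _with_path(child, ".".join(parts[1:]),
                                                value)})


def perturbation_study(evaluator: Callable, baseline,
                       perturbations: Sequence[Perturbation]) -> SensitivityTable:
    """Build a sensitivity table by paired simulations.

    ``evaluator(scenario) -> thermal elevation (degC)`` must be
    deterministic; it is called once for the baseline and once per
    perturbation.  Dataclass scenarios are copied with the perturbed
    field replaced, so the baseline object is never mutated.
    """
    T0 = float(evaluator(baseline))
    rows = []
    for p in perturbations:
        default = float(_get_path(baseline, p.path))
        try:
            scenario = _with_path(baseline, p.path, p.adjusted)
            T1 = float(evaluator(scenario))
        except Exception as exc:
            raise RuntimeError(
                f"evaluator failed for perturbation {p.path!r} "
                f"= {p.adjusted}") from exc
        rows.append(SensitivityRow(
            parameter=p.path, default=default, adjusted=p.adjusted,
            unit=p.unit, elevation_default=T0, elevation_adjusted=T1,
            std=p.std, per_mm=p.per_mm, group=p.group))
    return SensitivityTable(rows=rows)
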