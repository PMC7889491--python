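"""Published characterisation and sensitivity tables as fixture data.

These are the printed experimental constants of the 7 T phantom study:
the dielectric characterisation of the phantom and its saline
verification sample, and the input-parameter sensitivity analysis of
the thermal simulation (default/adjusted parameter values and the
resulting sensor thermal elevations after a 1258 s heating run).

Four printed rows are not arithmetically self-consistent with their own
default/adjusted values and elevations (the permittivity uncertainty,
the S11 sensitivity factor, the heat-transfer-coefficient row and the
alpha-coefficient row).  Those rows keep their printed values verbatim
with ``consistency=False`` so that downstream totals match the printed
table, while every self-consistent row is recomputed from first
principles.
"""

from __future__ import annotations

import pandas as pd

from .sensitivity import SensitivityRow, SensitivityTable

GROUP_PHANTOM = "phantom characterisation"
GROUP_EXPERIMENT = "experimental"
GROUP_PRF = "prf calculation"

#: Dielectric characterisation: estimated vs measured, with the printed
#: percent differences (saline sample verifies the probe measurement).
TABLE1 = pd.DataFrame([
    {"material": "saline_51.3mM", "quantity": "rel_permittivity",
     "estimated": 77.98, "measured": 77.62, "printed_difference_pct": 0.4},
    {"material": "saline_51.3mM", "quantity": "conductivity_S_per_m",
     "estimated": 0.60, "measured": 0.59, "printed_difference_pct": 1.6},
    {"material": "phantom", "quantity": "rel_permittivity",
     "estimated": 51.00, "measured": 47.76, "printed_difference_pct": -6.4},
    {"material": "phantom", "quantity": "conductivity_S_per_m",
     "estimated": 0.57, "measured": 0.62, "printed_difference_pct": 8.7},
])

#: Thermal-simulation input parameters: (parameter, unit, default,
#: adjusted, T0, T1, printed sensitivity, std, printed uncertainty,
#: per_mm, group, self-consistent)
_TABLE2_ROWS = [
    ("phantom conductivity", "S/m", 0.6227, 0.6850, 0.8643, 0.8805,
     0.19, 6.42, 1.20, False, GROUP_PHANTOM, True),
    ("phantom permittivity", "", 47.76, 52.54, 0.8643, 0.8662,
     0.02, 5.86, 1.29, False, GROUP_PHANTOM, False),
    ("phantom density", "kg/m^3", 1022.22, 1124.40, 0.8643, 0.7882,
     0.88, 0.98, 0.86, False, GROUP_PHANTOM, True),
    ("phantom heat capacity", "J/kg/degC", 3776.3, 4153.9, 0.8643, 0.7882,
     0.88, 4.24, 3.73, False, GROUP_PHANTOM, True),
    ("phantom thermal conductivity", "W/m/degC", 0.4864, 0.5350,
     0.8643, 0.8618, 0.03, 4.11, 0.12, False, GROUP_PHANTOM, True),
    ("phantom heat transfer coefficient", "W/degC/m^2", 2.5, 3.0,
     0.8643, 0.8642, 0.01, 40.00, 0.58, False, GROUP_PHANTOM, False),
    ("stabilised temperature", "degC", 18.6, 22.0, 0.8643, 0.8643,
     0.00, 9.30, 0.00, False, GROUP_EXPERIMENT, True),
    ("S11 magnitude", "", 0.4124, 0.3928, 0.8643, 0.8231,
     1.06, 4.75, 5.03, False, GROUP_EXPERIMENT, False),
    ("RF exposure time", "s", 1258.0, 1263.0, 0.8643, 0.8675,
     0.93, 1.63, 1.52, False, GROUP_EXPERIMENT, True),
    ("probe x position", "mm", 0.0, 2.5, 0.8643, 0.9377,
     3.40, 2.71, 9.21, True, GROUP_EXPERIMENT, True),
    ("probe y position", "mm", 0.0, 2.5, 0.8643, 0.8515,
     0.59, 2.71, 1.61, True, GROUP_EXPERIMENT, True),
    ("probe z position", "mm", 0.0, 5.0, 0.8643, 0.8686,
     0.10, 5.77, 0.57, True, GROUP_EXPERIMENT, True),
    ("PRF alpha coefficient", "ppm/degC", 0.00988, 0.01000, 0.9491, 0.9401,
     0.14, 6.88, 0.95, False, GROUP_PRF, False),
]

#: Printed group totals (linear sums of the printed uncertainties).
TABLE2_TOTALS = {GROUP_PHANTOM: 7.78, GROUP_EXPERIMENT: 17.94}


def table2() -> SensitivityTable:
    """The published sensitivity table as a :class:`SensitivityTable`.

    Self-consistent rows are recomputed at access time from their
    default/adjusted values and elevations; flagged rows store the
    printed sensitivity and uncertainty verbatim.
    """
    rows = []
    for (name, unit, p0, p1, T0, T1, sens, std, unc, per_mm, group,
         consistent) in _TABLE2_ROWS:
        rows.append(SensitivityRow(
            parameter=name, default=p0, adjusted=p1, unit=unit,
            elevation_default=T0, elevation_adjusted=T1, std=std,
            per_mm=per_mm, group=group,
            sensitivity=None if consistent else sens,
            uncertainty=None if consistent else unc,
            consistency=consistent))
    return SensitivityTable(rows=rows)


def table2_row(parameter: str) -> SensitivityRow:
    for row in table2().rows:
        if row.parameter == parameter:
            return row
    raise KeyError(parameter)
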