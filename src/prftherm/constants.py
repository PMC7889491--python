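"""Physical constants of the PRF thermometry experiment.

The proton resonance frequency shifts by roughly -0.01 ppm per degree
Celsius; at a fixed echo time TE this makes gradient-echo image phase a
linear thermometer,

    dphi = 2*pi * gamma * alpha * B0 * dT * TE

with gamma the proton gyromagnetic ratio in Hz/T, alpha the (negative)
PRF temperature coefficient and B0 the static field.  Heating therefore
accrues *negative* phase under this sign convention.
"""

from __future__ import annotations

import math

#: Proton gyromagnetic ratio, Hz/T.
GAMMA_HZ_PER_T: float = 42.576e6

#: PRF temperature coefficient for 1-2% agar gel, ppm/degC (negative).
ALPHA_PPM_PER_C: float = -0.00988

#: Static field strength of the scanner, tesla.
B0_T: float = 7.0

#: Echo times of the multi-echo gradient-echo protocol, ms.
TE_MS_DEFAULT: tuple[float, ...] = (1.44, 3.62, 5.5, 7.38, 9.26)

#: Repetition (dynamic) interval of the thermometry time series, s.
TEMPORAL_RESOLUTION_S: float = 41.0

#: Thermochemical calorie-based conversion, J per kcal.
KCAL_TO_J: float = 4186.8


def phase_per_degC(te_s: float,
                   gamma_hz_per_t: float = GAMMA_HZ_PER_T,
                   alpha_ppm_per_c: float = ALPHA_PPM_PER_C,
                   b0_t: float = B0_T) -> float:
    """Phase accrual in radians per degC of heating at echo time ``te_s``.

    Negative for the default alpha: heating lowers the resonance
    frequency, so phase winds backwards relative to the reference.
    """
    return 2.0 * math.pi * gamma_hz_per_t * alpha_ppm_per_c * 1e-6 * b0_t * te_s
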