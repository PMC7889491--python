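"""Synthetic multi-echo, multi-coil, two-mode thermometry acquisitions.

Generates complex image series with known ground-truth heating, B0
drift and noise, emulating the 7 T two-mode (TIAMO) multi-echo
gradient-echo protocol: 8 receive/transmit channels around a cylindrical
gel phantom, two RF shim modes (45 deg and 0 deg inter-channel phase
increments), five echoes, and a 41 s dynamic interval.

The forward phase model per voxel, echo ``e`` and repetition ``r`` is

    phi = angle(mode * coil) + jitter_r
          + 2*pi*gamma*alpha*B0 * (dT_r(x) + drift_r(x)) * TE_e

with magnitude ``|mode| * |coil| * exp(-TE/T2star)``; complex Gaussian
noise is added per channel.  Because every k-space step of the
reconstruction is linear, generating directly in image space is exact.

The 45-degree shim mode cancels at the cylinder axis (the eight equal
contributions sum around the unit circle), producing the B1 void that
motivates acquiring a complementary 0-degree mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants
from .constants import phase_per_degC
from .series import MultiEchoSeries
from .util import seeded_rng

__all__ = [
    "HotspotSpec",
    "DriftSpec",
    "ScenarioConfig",
    "GroundTruth",
    "make_phantom_mask",
    "make_coil_profiles",
    "make_transmit_modes",
    "make_ground_truth",
    "render_acquisition",
]


@dataclass(frozen=True)
class HotspotSpec:
    """Gaussian heating focus mimicking a single dipole's deposition.

    The default centre sits 30 mm inside the phantom edge (the fibre
    optic probe position); amplitude ramps linearly with repetition.
    """

    centre_mm: tuple[float, float, float] = (105.0, 0.0, 0.0)
    sigma_mm: float = 25.0
    ramp_C_per_rep: float = 0.05


@dataclass(frozen=True)
class DriftSpec:
    """Apparent-temperature drift from gradient-induced B0 change.

    ``bulk_C_per_rep`` grows linearly for the whole scan (the spatially
    invariant offset keeps increasing on the real system), while the
    first-order spatial gradients settle exponentially with time
    constant ``settling_s``: coefficient(t) = rate * tau * (1 - e^-t/tau)
    in repetition units, so the initial slope is ``plane_C_per_mm_per_rep``
    and the asymptote is rate * settling_s / tr.
    """

    bulk_C_per_rep: float = 0.01
    plane_C_per_mm_per_rep: tuple[float, float, float] = (2.44e-4, 2.0e-4, 1.2e-4)
    settling_s: float | None = 840.0


@dataclass
class ScenarioConfig:
    """Acquisition scenario; defaults mirror the 7 T phantom protocol."""

    matrix: tuple[int, int, int] = (64, 64, 30)
    fov_mm: tuple[float, float, float] = (300.0, 300.0, 300.0)
    n_coils: int = 8
    mode_increments_deg: tuple[float, ...] = (45.0, 0.0)
    te_ms: tuple[float, ...] = constants.TE_MS_DEFAULT
    n_reps: int = 30
    tr_s: float = constants.TEMPORAL_RESOLUTION_S
    noise_sd: float = 0.0
    seed: int = 0
    hotspot: HotspotSpec | None = field(default_factory=HotspotSpec)
    drift: DriftSpec | None = None
    jitter_sd_rad: float = 0.0
    probe_locations_mm: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 0.0), (105.0, 0.0, 0.0))
    phantom_radius_mm: float = 135.0   # inner (gel) radius
    phantom_halfheight_mm: float = 145.0
    t2star_ms: float = 9.0
    gamma_hz_per_t: float = constants.GAMMA_HZ_PER_T
    alpha_ppm_per_c: float = constants.ALPHA_PPM_PER_C
    b0_t: float = constants.B0_T

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("need at least 2 repetitions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("TE list must be strictly increasing")

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(f / n for f, n in zip(self.fov_mm, self.matrix))

    def coordinates_mm(self):
        """Voxel-centre coordinates, origin at the phantom centre."""
        ax = [(np.arange(n) - (n - 1) / 2) * d
              for n, d in zip(self.matrix, self.voxel_size_mm)]
        return np.meshgrid(*ax, indexing="ij")


@dataclass
class GroundTruth:
    """Everything the reconstruction is supposed to estimate."""

    delta_T: np.ndarray          # [rep, x, y, z], degC relative to rep 0
    drift: np.ndarray            # [rep, x, y, z], degC-equivalent, affine
    drift_coeffs: np.ndarray     # [rep, 4]: a0, ax, ay, az
    coil_profiles: np.ndarray    # [coil, x, y, z], complex
    mode_maps: np.ndarray        # [mode, x, y, z], complex
    mask: np.ndarray             # phantom interior
    probe_delta_T: np.ndarray    # [rep, probe], degC
    jitter_rad: np.ndarray       # [rep]


def make_phantom_mask(config: ScenarioConfig) -> np.ndarray:
    X, Y, Z = config.coordinates_mm()
    return ((X ** 2 + Y ** 2 <= config.phantom_radius_mm ** 2)
            & (np.abs(Z) <= config.phantom_halfheight_mm))


def make_coil_profiles(config: ScenarioConfig) -> np.ndarray:
    """Smooth complex receive sensitivities for a circumferential array.

    Coil ``c`` sits on the phantom surface at azimuth ``2*pi*c/n``; its
    magnitude decays with distance from the element and its phase winds
    slowly with that distance, as a loop/dipole sensitivity does.
    Rotating the coil index by one step rotates the map by the same
    azimuthal increment (exactly, up to grid interpolation).
    """
    if config.n_coils < 1:
        raise ValueError("need at least one coil")
    X, Y, Z = config.coordinates_mm()
    R = config.phantom_radius_mm
    decay = 0.8 * R             # mm, sensitivity fall-off length
    phase_wind = 0.5 * np.pi / R  # rad/mm of distance
    profiles = np.empty((config.n_coils, *config.matrix), dtype=complex)
    for c in range(config.n_coils):
        th = 2 * np.pi * c / config.n_coils
        cx, cy = R * np.cos(th), R * np.sin(th)
        dist = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (0.3 * Z) ** 2)
        profiles[c] = np.exp(-dist / decay) * np.exp(-1j * phase_wind * dist)
    return profiles


def make_transmit_modes(config: ScenarioConfig,
                        coil_profiles: np.ndarray) -> np.ndarray:
    """Complex transmit maps for each RF shim mode.

    mode_m = sum_c profile_c * exp(i * c * increment_m).  With eight
    equally spaced coils the 45-degree increment cancels on the axis
    (B1 void) while the 0-degree mode peaks there: the two modes are
    complementary, which is what makes the interleaved acquisition
    cover the whole phantom.
    """
    n_coils = coil_profiles.shape[0]
    modes = np.empty((len(config.mode_increments_deg),
                      *coil_profiles.shape[1:]), dtype=complex)
    for m, inc in enumerate(config.mode_increments_deg):
        w = np.exp(1j * np.deg2rad(inc) * np.arange(n_coils))
        modes[m] = np.tensordot(w, coil_profiles, axes=(0, 0))
    return modes


def _hotspot_field(config: ScenarioConfig) -> np.ndarray:
    X, Y, Z = config.coordinates_mm()
    hs = config.hotspot
    d2 = ((X - hs.centre_mm[0]) ** 2 + (Y - hs.centre_mm[1]) ** 2
          + (Z - hs.centre_mm[2]) ** 2)
    return np.exp(-d2 / (2 * hs.sigma_mm ** 2))


def make_ground_truth(config: ScenarioConfig) -> GroundTruth:
    """Assemble the true heating, drift and sensitivity maps."""
    mask = make_phantom_mask(config)
    X, Y, Z = config.coordinates_mm()
    reps = np.arange(config.n_reps)

    delta_T = np.zeros((config.n_reps, *config.matrix))
    if config.hotspot is not None:
        shape = _hotspot_field(config) * mask
        for r in reps:
            delta_T[r] = config.hotspot.ramp_C_per_rep * r * shape

    drift_coeffs = np.zeros((config.n_reps, 4))
    drift = np.zeros_like(delta_T)
    if config.drift is not None:
        d = config.drift
        t = reps * config.tr_s
        if d.settling_s is None:
            settle = reps.astype(float)
        else:
            tau_reps = d.settling_s / config.tr_s
            settle = tau_reps * (1.0 - np.exp(-t / d.settling_s))
        drift_coeffs[:, 0] = d.bulk_C_per_rep * reps
        for a, rate in enumerate(d.plane_C_per_mm_per_rep):
            drift_coeffs[:, 1 + a] = rate * settle
        for r in reps:
            a0, ax, ay, az = drift_coeffs[r]
            drift[r] = a0 + ax * X + ay * Y + az * Z

    rng = seeded_rng(config.seed, "jitter")
    jitter = (rng.normal(0.0, config.jitter_sd_rad, size=config.n_reps)
              if config.jitter_sd_rad > 0 else np.zeros(config.n_reps))

    coil_profiles = make_coil_profiles(config)
    mode_maps = make_transmit_modes(config, coil_profiles)

    probe_idx = [_nearest_index(config, p) for p in config.probe_locations_mm]
    probe_dT = np.stack([[delta_T[r][idx] for idx in probe_idx]
                         for r in reps])

    return GroundTruth(delta_T=delta_T, drift=drift,
                       drift_coeffs=drift_coeffs,
                       coil_profiles=coil_profiles, mode_maps=mode_maps,
                       mask=mask, probe_delta_T=probe_dT, jitter_rad=jitter)


def _nearest_index(config: ScenarioConfig, loc_mm) -> tuple[int, int, int]:
    idx = []
    for i, (n, d) in enumerate(zip(config.matrix, config.voxel_size_mm)):
        idx.append(int(np.clip(round(loc_mm[i] / d + (n - 1) / 2), 0, n - 1)))
    return tuple(idx)


def render_acquisition(truth: GroundTruth, config: ScenarioConfig,
                       dtype=np.complex128) -> MultiEchoSeries:
    """Render the complex image series from ground truth.

    Identical config and seed give bit-identical output.  Noise is
    complex circular Gaussian with total standard deviation
    ``noise_sd`` per channel sample (``noise_sd/sqrt(2)`` per
    real/imaginary component).
    """
    if truth.delta_T.shape != (config.n_reps, *config.matrix):
        raise ValueError("ground truth and config shapes disagree")
    n_modes = len(config.mode_increments_deg)
    shape = (n_modes, config.n_coils, len(config.te_ms), config.n_reps,
             *config.matrix)
    data = np.empty(shape, dtype=dtype)

    te_s = np.asarray(config.te_ms) * 1e-3
    apparent = truth.delta_T + truth.drift      # degC-equivalent
    mask = truth.mask
    for e, te in enumerate(te_s):
        mag_decay = np.exp(-te * 1e3 / config.t2star_ms)
        for r in range(config.n_reps):
            thermal = np.exp(1j * (phase_per_degC(
                te, config.gamma_hz_per_t, config.alpha_ppm_per_c,
                config.b0_t) * apparent[r] + truth.jitter_rad[r]))
            for m in range(n_modes):
                base = truth.mode_maps[m] * mag_decay * thermal * mask
                for c in range(config.n_coils):
                    data[m, c, e, r] = base * truth.coil_profiles[c]

    if config.noise_sd > 0:
        rng = seeded_rng(config.seed, "noise")
        sd = config.noise_sd / np.sqrt(2.0)
        noise = rng.normal(0.0, sd, size=(*shape, 2))
        data += (noise[..., 0] + 1j * noise[..., 1]).astype(dtype)

    return MultiEchoSeries(
        data=data, te_ms=config.te_ms, tr_s=config.tr_s,
        voxel_size_mm=config.voxel_size_mm,
        mode_increments_deg=config.mode_increments_deg, seed=config.seed,
        meta={"noise_sd": config.noise_sd,
              "n_reps": config.n_reps,
              "probe_locations_mm": [list(p) for p in config.probe_locations_mm]})


def probe_log_frame(truth: GroundTruth, config: ScenarioConfig) -> pd.DataFrame:
    """Fibre-optic probe log as `time_s,temp_C,probe` rows (delta-T)."""
    t = np.arange(config.n_reps) * config.tr_s
    rows = []
    for p in range(truth.probe_delta_T.shape[1]):
        rows.append(pd.DataFrame({
            "time_s": t, "temp_C": truth.probe_delta_T[:, p],
            "probe": f"probe{p}"}))
    return pd.concat(rows, ignore_index=True)


def write_probe_log(truth: GroundTruth, config: ScenarioConfig,
                    path: str | Path) -> None:
    probe_log_frame(truth, config).to_csv(path, index=False)
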