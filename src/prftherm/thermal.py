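"""Transient heat diffusion in a voxelised gel phantom.

The phantom is an agar gel cylinder in a PMMA shell.  Without perfusion
or metabolism the bioheat equation reduces to conduction plus the RF
source term,

    rho * Cp * dT/dt = div(kappa grad T) + rho * SAR ,

with a Robin (mixed) boundary condition on the gel surface,

    -kappa dT/dn = h * (T - T_ambient) ,

i.e. each exposed face loses heat in proportion to its excess over the
room.  The solver is an explicit forward-time central-space scheme on a
regular voxel grid restricted to the gel interior (the shell is
excluded from the conductive domain); fluxes are face-based, which
makes the scheme exactly conservative when h = 0.

The time step is chosen automatically at half the explicit stability
bound dt <= min(dx^2, dy^2, dz^2) / (6 K) and rounded so that the
requested duration is an integer number of steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .props import MaterialProps

__all__ = [
    "PhantomGeometry",
    "VoxelGrid",
    "ThermalScenario",
    "SensorSpec",
    "SimulationResult",
    "voxelise_cylinder",
    "stability_dt",
    "step_heat",
    "simulate",
]

#: fraction of the explicit stability bound used for the automatic dt
DT_SAFETY = 0.5


@dataclass(frozen=True)
class PhantomGeometry:
    """Cylindrical phantom with its axis along z, dimensions in mm."""

    diameter: float = 280.0
    height: float = 300.0
    shell_thickness: float = 5.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("diameter and height must be positive")
        if not (0 <= self.shell_thickness < self.diameter / 2):
            raise ValueError("shell_thickness must be in [0, diameter/2)")


@dataclass
class VoxelGrid:
    """Regular voxel grid with an interior (gel) mask.

    ``origin`` is the position, in mm, of the centre of voxel [0,0,0];
    coordinates are phantom-frame mm with the origin at the cylinder
    centre.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]  # mm
    origin: tuple[float, float, float]      # mm, centre of voxel [0,0,0]
    mask: np.ndarray                        # bool, gel interior

    def __post_init__(self) -> None:
        if any(n < 3 for n in self.shape):
            raise ValueError("grid must be at least 3 voxels per axis")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.shape):
            raise ValueError("mask shape must match grid shape")
        if not self.mask.any():
            raise ValueError("interior mask is empty")

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinate arrays (mm), broadcastable to shape."""
        ax = [self.origin[i] + np.arange(self.shape[i]) * self.voxel_size[i]
              for i in range(3)]
        return np.meshgrid(*ax, indexing="ij")

    def index_of(self, location_mm) -> tuple[int, int, int]:
        """Nearest voxel index to a phantom-frame position in mm."""
        loc = np.asarray(location_mm, dtype=float)
        idx = np.round((loc - np.asarray(self.origin))
                       / np.asarray(self.voxel_size)).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1)
        return tuple(int(i) for i in idx)

    @property
    def voxel_volume_m3(self) -> float:
        dx, dy, dz = (v * 1e-3 for v in self.voxel_size)
        return dx * dy * dz


def voxelise_cylinder(geometry: PhantomGeometry, voxel_size: float | tuple,
                      padding_voxels: int = 1) -> VoxelGrid:
    """Voxelise the gel interior of a cylindrical phantom.

    A voxel belongs to the interior when its centre lies within radius
    ``diameter/2 - shell_thickness`` of the axis and within the axial
    extent shortened by ``shell_thickness`` at each end.

    Parameters
    ----------
    geometry : PhantomGeometry
    voxel_size : float or 3-tuple
        Isotropic or per-axis voxel edge length in mm.
    padding_voxels : int
        Layers of exterior voxels kept around the cylinder bounding box.
    """
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    voxel_size = tuple(float(v) for v in voxel_size)
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel_size must be positive")
    if geometry.diameter < 3 * min(voxel_size[0], voxel_size[1]):
        raise ValueError("grid too coarse: need >= 3 voxels across the diameter")

    half = (geometry.diameter / 2, geometry.diameter / 2, geometry.height / 2)
    shape = tuple(
        int(np.ceil(2 * half[i] / voxel_size[i])) + 2 * padding_voxels
        for i in range(3))
    origin = tuple(-(shape[i] - 1) / 2 * voxel_size[i] for i in range(3))

    ax = [origin[i] + np.arange(shape[i]) * voxel_size[i] for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r_in = geometry.diameter / 2 - geometry.shell_thickness
    z_in = geometry.height / 2 - geometry.shell_thickness
    mask = (X ** 2 + Y ** 2 <= r_in ** 2) & (np.abs(Z) <= z_in)
    if not mask.any():
        raise ValueError("grid too coarse to contain an interior voxel")
    return VoxelGrid(shape=shape, voxel_size=voxel_size, origin=origin,
                     mask=mask)


@dataclass
class ThermalScenario:
    """Complete specification of one transient thermal run."""

    grid: VoxelGrid
    material: MaterialProps
    sar: np.ndarray | float = 0.0          # W/kg, per voxel or scalar
    h: float = 2.5                         # W/m^2/degC
    T_ambient: float = 18.6                # degC
    T_initial: np.ndarray | float = 18.6   # degC
    duration: float = 1258.0               # s
    dt: float | None = None                # s; None -> automatic

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.h < 0:
            raise ValueError("heat transfer coefficient must be >= 0")
        sar = np.broadcast_to(np.asarray(self.sar, dtype=float),
                              self.grid.shape).copy()
        if np.any(sar < 0):
            raise ValueError("SAR must be nonnegative")
        sar[~self.grid.mask] = 0.0
        self.sar = sar
        bound = stability_dt(self.grid, self.material)
        if self.dt is None:
            self.dt = DT_SAFETY * bound
        elif self.dt <= 0 or self.dt > bound:
            raise ValueError(
                f"dt={self.dt} violates the explicit stability bound {bound:.4g} s")
        # shrink dt so an integer number of steps spans the duration exactly
        n = max(1, int(np.ceil(self.duration / self.dt - 1e-12)))
        self.dt = self.duration / n

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def initial_field(self) -> np.ndarray:
        T = np.broadcast_to(np.asarray(self.T_initial, dtype=float),
                            self.grid.shape).copy()
        T[~self.grid.mask] = np.nan
        return T


@dataclass(frozen=True)
class SensorSpec:
    """Point temperature sensor at a phantom-frame location in mm."""

    location: tuple[float, float, float]
    name: str = "sensor"


@dataclass
class SimulationResult:
    """Fields at requested save times plus per-sensor time series."""

    save_times: np.ndarray
    fields: list[np.ndarray]
    sensor_times: np.ndarray
    sensor_series: dict[str, np.ndarray]
    energy_in_J: float = 0.0
    energy_out_J: float = 0.0

    def sensor_frame(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"time_s": self.sensor_times,
                              "temp_C": series, "sensor": name})
                for name, series in self.sensor_series.items()]
        return pd.concat(rows, ignore_index=True)


def stability_dt(grid: VoxelGrid, material: MaterialProps) -> float:
    """Explicit-scheme stability bound min(d^2) / (6 K), in seconds."""
    K = material.thermal_diffusivity
    if K is None or K <= 0:
        return np.inf
    d2 = min((v * 1e-3) ** 2 for v in grid.voxel_size)
    return d2 / (6.0 * K)


def _neighbour_counts(mask: np.ndarray) -> np.ndarray:
    """Number of interior neighbours per voxel (6-connectivity)."""
    n = np.zeros(mask.shape, dtype=np.int8)
    for axis in range(3):
        m = mask.astype(np.int8)
        n[tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))] += \
            m[tuple(slice(1, None) if a == axis else slice(None) for a in range(3))]
        n[tuple(slice(1, None) if a == axis else slice(None) for a in range(3))] += \
            m[tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))]
    return n


def step_heat(T: np.ndarray, scenario: ThermalScenario,
              return_boundary_power: bool = False):
    """One explicit finite-difference update of the temperature field.

    Exterior voxels hold NaN and are never read; fluxes are accumulated
    per face so that with ``h = 0`` the volume integral of rho*Cp*T is
    conserved to round-off.

    Returns the updated field, and optionally the instantaneous boundary
    heat loss in watts (positive = heat leaving the phantom).
    """
    grid = scenario.grid
    mat = scenario.material
    mask = grid.mask
    kappa = mat.thermal_conductivity
    rho_cp = mat.density * mat.specific_heat
    dt = scenario.dt
    d_m = tuple(v * 1e-3 for v in grid.voxel_size)

    Tm = np.where(mask, T, 0.0)
    dTdt = np.zeros_like(Tm)
    exposed = np.zeros_like(Tm)  # per-voxel sum of exposed-face 1/dx terms

    for axis, d in enumerate(d_m):
        lo = tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))
        hi = tuple(slice(1, None) if a == axis else slice(None) for a in range(3))
        both = mask[lo] & mask[hi]
        # conductive flux between interior neighbour pairs
        flux = np.zeros(both.shape)
        flux[both] = (Tm[hi][both] - Tm[lo][both]) * (kappa / d ** 2)
        dTdt[lo] += flux
        dTdt[hi] -= flux
        # faces exposed to the surroundings (interior voxel, exterior neighbour)
        exp_lo = mask[lo] & ~mask[hi]
        exp_hi = mask[hi] & ~mask[lo]
        e = np.zeros(both.shape)
        e[exp_lo] += 1.0 / d
        exposed[lo] += e
        e = np.zeros(both.shape)
        e[exp_hi] += 1.0 / d
        exposed[hi] += e
        # domain-boundary faces of the array are exposed too
        edge_lo = tuple(slice(0, 1) if a == axis else slice(None) for a in range(3))
        edge_hi = tuple(slice(-1, None) if a == axis else slice(None) for a in range(3))
        exposed[edge_lo] += mask[edge_lo] / d
        exposed[edge_hi] += mask[edge_hi] / d

    boundary_power_density = scenario.h * exposed * (Tm - scenario.T_ambient)
    dTdt -= boundary_power_density                       # W/m^3 / (rho Cp) pending
    dTdt /= rho_cp
    dTdt += scenario.sar / mat.specific_heat             # rho*SAR/(rho*Cp)

    T_new = np.where(mask, Tm + dt * dTdt, np.nan)
    if return_boundary_power:
        # watts: h * (T - T_amb) * exposed_area; exposed holds 1/d per face,
        # and face area * (1/d) = voxel volume / d^2 * d = V / d -> V*exposed
        watts = float(np.sum(boundary_power_density[mask]) * grid.voxel_volume_m3)
        return T_new, watts
    return T_new


def simulate(scenario: ThermalScenario,
             sensors: list[SensorSpec] | None = None,
             save_times=None, sensor_times=None) -> SimulationResult:
    """Integrate a thermal scenario, recording fields and sensor series.

    Sensors are sampled by nearest-voxel lookup at every step and then
    interpolated onto ``sensor_times`` (defaults to every step).
    """
    grid = scenario.grid
    sensors = sensors or []
    idxs = []
    for s in sensors:
        idx = grid.index_of(s.location)
        if not grid.mask[idx]:
            raise ValueError(f"sensor {s.name!r} at {s.location} is outside "
                             "the interior mask")
        idxs.append(idx)

    save_times = np.atleast_1d(np.asarray(
        save_times if save_times is not None else [scenario.duration],
        dtype=float))
    T = scenario.initial_field()
    n = scenario.n_steps
    dt = scenario.dt
    times = np.arange(n + 1) * dt
    series = np.empty((len(sensors), n + 1))
    for k, idx in enumerate(idxs):
        series[k, 0] = T[idx]

    save_steps = sorted(set(min(n, int(round(t / dt))) for t in save_times))
    fields_by_step: dict[int, np.ndarray] = {}
    if 0 in save_steps:
        fields_by_step[0] = T.copy()

    mass = scenario.material.density * grid.voxel_volume_m3  # kg per voxel
    energy_in = 0.0
    energy_out = 0.0
    sar_power = float(np.sum(scenario.sar[grid.mask]) * mass)  # W

    for step in range(1, n + 1):
        T, watts_out = step_heat(T, scenario, return_boundary_power=True)
        energy_in += sar_power * dt
        energy_out += watts_out * dt
        for k, idx in enumerate(idxs):
            series[k, step] = T[idx]
        if step in save_steps:
            fields_by_step[step] = T.copy()

    if sensor_times is None:
        sensor_times = times
        sensor_series = {s.name: series[k] for k, s in enumerate(sensors)}
    else:
        sensor_times = np.asarray(sensor_times, dtype=float)
        sensor_series = {
            s.name: np.interp(sensor_times, times, series[k])
            for k, s in enumerate(sensors)}

    return SimulationResult(save_times=np.asarray(save_steps, dtype=float) * dt,
                            fields=[fields_by_step[s] for s in save_steps],
                            sensor_times=sensor_times,
                            sensor_series=sensor_series,
                            energy_in_J=energy_in,
                            energy_out_J=energy_out)
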