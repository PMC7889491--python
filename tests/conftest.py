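"""Shared fixtures: desk-scale scenarios reused across test modules."""

import numpy as np
import pytest

import prftherm as pt

#: gel material of the characterised phantom (SI units)
GEL = dict(density=1022.22, specific_heat=3776.3,
           thermal_diffusivity=1.26e-7, conductivity=0.6227,
           rel_permittivity=47.76, heat_transfer_coeff=2.5)


@pytest.fixture(scope="session")
def gel_material() -> pt.MaterialProps:
    return pt.MaterialProps(**GEL)


@pytest.fixture(scope="session")
def coarse_grid() -> pt.VoxelGrid:
    """Full-size phantom at 20 mm: fast enough for sweeps."""
    return pt.voxelise_cylinder(pt.PhantomGeometry(), 20.0)


@pytest.fixture(scope="session")
def noiseless_recon():
    """Noiseless hotspot acquisition and its reconstruction (no filter)."""
    cfg = pt.ScenarioConfig(matrix=(20, 20, 8), n_reps=4, noise_sd=0.0,
                            seed=1, hotspot=pt.HotspotSpec(ramp_C_per_rep=0.3))
    truth = pt.make_ground_truth(cfg)
    series = pt.render_acquisition(truth, cfg)
    rc = pt.ReconConfig(apodise=False, zero_pad_shape=None, reference_rep=1,
                        drift_correction="none")
    result = pt.reconstruct_temperature(series, rc)
    return cfg, truth, series, result


@pytest.fixture(scope="session")
def noisy_acquisition():
    """Seeded noisy 30-repetition two-mode acquisition (odd matrix so a
    voxel sits on the cylinder axis, inside the 45-degree-mode B1 void)."""
    cfg = pt.ScenarioConfig(matrix=(25, 25, 9), n_reps=30, noise_sd=0.02,
                            seed=7, hotspot=pt.HotspotSpec(ramp_C_per_rep=0.05))
    truth = pt.make_ground_truth(cfg)
    series = pt.render_acquisition(truth, cfg)
    return cfg, truth, series


@pytest.fixture(scope="session")
def drift_acquisition():
    """Noiseless drift-only stabilisation scan (45 reps, 14-min settling)."""
    cfg = pt.ScenarioConfig(matrix=(16, 16, 8), n_reps=45, noise_sd=0.0,
                            seed=2, hotspot=None, drift=pt.DriftSpec())
    truth = pt.make_ground_truth(cfg)
    series = pt.render_acquisition(truth, cfg)
    rc = pt.ReconConfig(apodise=False, zero_pad_shape=None, reference_rep=1,
                        drift_correction="none")
    result = pt.reconstruct_temperature(series, rc)
    return cfg, truth, result


@pytest.fixture(scope="session")
def cooling_reference(coarse_grid, gel_material):
    """Simulated 4 h cooling curve of the phantom at h = 2.5."""
    times = np.arange(0.0, 14401.0, 300.0)

    def factory(h):
        return pt.ThermalScenario(grid=coarse_grid, material=gel_material,
                                  sar=0.0, h=h, T_ambient=18.6,
                                  T_initial=23.0, duration=14400.0)

    sensor = pt.SensorSpec((105.0, 0.0, 0.0), "edge")
    sim = pt.simulate(factory(2.5), sensors=[sensor], sensor_times=times)
    return times, sim.sensor_series["edge"], factory, sensor
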