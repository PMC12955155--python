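import numpy as np
import pytest

import fvheeplan as fp


def make_water_beamlet(
    focal_length_cm: float = 15.0,
    energy_mev: float = 250.0,
    lens_to_surface_cm: float = 7.0,
    surface_y_cm: float = 10.0,
) -> fp.BeamletSpec:
    """Beamlet entering a water box anteriorly (gantry 0), lens a fixed
    distance upstream of the box surface."""
    beam = fp.BeamConfig(
        0.0, 5.0, lens_to_iso_cm=surface_y_cm + lens_to_surface_cm, energy_mev=energy_mev
    )
    spot = beam.lens_center + beam.travel_direction * focal_length_cm
    return fp.BeamletSpec(beam, tuple(spot), focal_length_cm)


@pytest.fixture(scope="session")
def water_box():
    """12 x 20 x 12 cm water box, 2.5 mm voxels (entry face at y = +10)."""
    phantom, _ = fp.make_water_box((12.0, 20.0, 12.0), 0.25)
    return phantom


@pytest.fixture(scope="session")
def coarse_water_box():
    """Small, coarse water box for cheap Monte Carlo checks."""
    phantom, _ = fp.make_water_box((8.0, 14.0, 8.0), 0.5)
    return phantom


@pytest.fixture(scope="session")
def water_run(water_box):
    """One shared 6e4-history transport of the default 250 MeV beamlet
    (focal length 15 cm, lens 7 cm before the surface)."""
    beamlet = make_water_beamlet()
    rays = fp.sample_phase_space(beamlet, 60_000, seed=11)
    dose_grid = fp.transport(water_box, rays, fp.TransportConfig(60_000, seed=12))
    return beamlet, dose_grid


def coarse_beamlet(energy_mev: float = 250.0, focal_length_cm: float = 15.0) -> fp.BeamletSpec:
    """Beamlet matched to the coarse water box (surface at y = +7)."""
    return make_water_beamlet(focal_length_cm, energy_mev, surface_y_cm=7.0)
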