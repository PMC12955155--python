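"""Fermi-Eyges analytic oracle for the lateral spread of a focused beamlet
in homogeneous water.

The lateral variance at depth is the sum of

* the geometric (vacuum) envelope of the focused bundle — entry points
  uniform on the lens disc, targets Gaussian in the focal plane — which is
  exact under linear propagation, and
* the Fermi-Eyges scattering contribution
  ``A2(z) = integral_0^z T(u) (z-u)^2 du`` with the scattering power ``T``
  taken from the same Highland parameterization (and step length) as the
  Monte Carlo engine, evaluated along the CSDA energy loss curve.
"""

from __future__ import annotations

import numpy as np

from fvheeplan.beam_model import GAUSSIAN_FWHM_TO_SIGMA, BeamletSpec
from fvheeplan.materials import MaterialTable, highland_sigma


def csda_energy_at_depth(
    depths_cm: np.ndarray,
    e0_mev: float,
    materials: MaterialTable,
    density: float = 1.0,
    step_cm: float = 0.01,
) -> np.ndarray:
    """Kinetic energy remaining after the given depths in a homogeneous
    medium, by continuous slowing down over total stopping power."""
    depths_cm = np.asarray(depths_cm, dtype=float)
    zmax = float(depths_cm.max(initial=0.0))
    n = max(int(np.ceil(zmax / step_cm)), 1)
    z_grid = np.linspace(0.0, zmax, n + 1)
    e_grid = np.empty(n + 1)
    e_grid[0] = e0_mev
    e = e0_mev
    for i in range(n):
        dz = z_grid[i + 1] - z_grid[i]
        e = max(e - float(materials.stopping_power_total(e)) * density * dz, 1e-6)
        e_grid[i + 1] = e
    return np.interp(depths_cm, z_grid, e_grid)


def geometric_sigma(beamlet: BeamletSpec, axial_from_lens_cm: np.ndarray) -> np.ndarray:
    """Vacuum lateral (1D marginal) sigma of the bundle at an axial distance
    from the lens plane.

    Entry marginal variance of a uniform disc of radius R is R^2/4; the
    target marginal variance is the focal-spot sigma^2.  Positions
    interpolate linearly between the two, so
    ``sigma^2(z) = (R^2/4)(1 - z/f)^2 + (z/f)^2 sigma_f^2``.
    """
    z = np.asarray(axial_from_lens_cm, dtype=float)
    f = beamlet.focal_length_cm
    r = beamlet.beam.lens_radius_cm
    sig_f = beamlet.focal_fwhm_cm * GAUSSIAN_FWHM_TO_SIGMA
    return np.sqrt((r**2 / 4.0) * (1.0 - z / f) ** 2 + (z / f) ** 2 * sig_f**2)


def fermi_eyges_sigma(
    depths_cm: np.ndarray,
    beamlet: BeamletSpec,
    lens_to_surface_cm: float,
    materials: MaterialTable | None = None,
    density: float = 1.0,
    step_cm: float = 0.1,
    scattering_power: float | None = None,
) -> np.ndarray:
    """Lateral sigma profile of a focused beamlet in homogeneous water.

    ``depths_cm`` are measured from the phantom surface, which sits
    ``lens_to_surface_cm`` downstream of the lens plane.  ``step_cm`` should
    match the Monte Carlo step so the Highland logarithmic factor agrees.
    ``scattering_power`` overrides T(u) with a constant (rad^2/cm), used for
    closed-form checks; 0 reduces to the vacuum envelope.
    """
    materials = materials or MaterialTable()
    depths_cm = np.asarray(depths_cm, dtype=float)
    if np.any(depths_cm < 0):
        raise ValueError("depths must be >= 0")
    sig_geom = geometric_sigma(beamlet, lens_to_surface_cm + depths_cm)

    zmax = float(depths_cm.max(initial=0.0))
    n = max(int(np.ceil(zmax / step_cm)), 1)
    u = np.linspace(0.0, zmax, n + 1)
    if scattering_power is not None:
        t_power = np.full(n + 1, float(scattering_power))
    else:
        e_u = csda_energy_at_depth(u, beamlet.beam.energy_mev, materials, density)
        t_step = density * step_cm / materials.x0_g_cm2
        theta0 = highland_sigma(e_u, np.full(n + 1, t_step))
        t_power = theta0**2 / step_cm  # rad^2 per cm
    a2 = np.array(
        [np.trapezoid(t_power * np.clip(z - u, 0.0, None) ** 2 * (u <= z), u) for z in depths_cm]
    )
    return np.sqrt(sig_geom**2 + a2)
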