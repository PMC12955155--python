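"""Geometric model of a magnetically focused electron beamlet.

A beamlet is defined by a gantry angle, a magnetic-lens aperture of radius
``lens_radius`` located ``lens_to_iso`` upstream of the isocenter on the beam
axis, and a focal point at which the beamlet converges to a Gaussian spot of
given FWHM.  Focusing is purely geometric: rays start uniformly distributed
over the lens disc and each is aimed at an independent Gaussian-distributed
target in the focal plane, so the vacuum fluence FWHM at the focus equals the
configured spot FWHM by construction.

Gantry convention (table fixed at 0 deg, rotation about z): at angle theta the
beam travels along ``(-sin theta, -cos theta, 0)``, i.e. theta = 0 enters
anteriorly (+y) and travels toward -y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class BeamConfig:
    """One beam direction with its lens geometry and energy."""

    gantry_angle_deg: float
    lens_radius_cm: float = 5.0
    lens_to_iso_cm: float = 50.0
    energy_mev: float = 250.0

    def __post_init__(self) -> None:
        if self.lens_radius_cm <= 0:
            raise ValueError("lens radius must be > 0")
        if self.lens_to_iso_cm <= 0:
            raise ValueError("lens-to-isocenter distance must be > 0")
        if self.energy_mev <= 0:
            raise ValueError("energy must be > 0")

    @property
    def travel_direction(self) -> np.ndarray:
        """Unit vector along which the beam travels (lens -> isocenter)."""
        t = np.deg2rad(self.gantry_angle_deg)
        return np.array([-np.sin(t), -np.cos(t), 0.0])

    @property
    def source_direction(self) -> np.ndarray:
        """Unit vector from the isocenter toward the lens."""
        return -self.travel_direction

    @property
    def lens_center(self) -> np.ndarray:
        """World position of the lens-plane center."""
        return self.source_direction * self.lens_to_iso_cm


def gantry_transform(gantry_angle_deg: float) -> np.ndarray:
    """Orthonormal 3x3 matrix mapping beam-frame vectors to world vectors.

    Beam frame: e_z' = travel direction, e_x' and e_y' span the transverse
    plane (e_y' is world +z; e_x' completes the right-handed triad).
    """
    t = np.deg2rad(gantry_angle_deg)
    travel = np.array([-np.sin(t), -np.cos(t), 0.0])
    ey = np.array([0.0, 0.0, 1.0])
    ex = np.cross(ey, travel)
    m = np.column_stack([ex, ey, travel])
    return m


@dataclass(frozen=True)
class BeamletSpec:
    """One focused beamlet: beam geometry plus focal point and spot width."""

    beam: BeamConfig
    spot_cm: tuple[float, float, float]
    focal_length_cm: float
    focal_fwhm_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.focal_length_cm <= 0:
            raise ValueError("focal length must be > 0")
        if self.focal_fwhm_cm <= 0:
            raise ValueError("focal-spot FWHM must be > 0")
        object.__setattr__(self, "spot_cm", tuple(float(v) for v in self.spot_cm))


@dataclass
class RaySet:
    """Sampled phase space: per-ray entry position on the lens plane,
    unit direction, kinetic energy (MeV) and statistical weight."""

    positions: np.ndarray  # (n, 3) world cm
    directions: np.ndarray  # (n, 3) unit vectors
    energies: np.ndarray  # (n,) MeV
    weights: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.directions) == len(self.energies) == len(self.weights) == n):
            raise ValueError("inconsistent ray-set array lengths")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("ray directions must be unit vectors")
        if np.any(self.weights <= 0):
            raise ValueError("ray weights must be > 0")

    def __len__(self) -> int:
        return len(self.positions)


def focal_length_for_spot(beam: BeamConfig, spot_cm) -> float:
    """Lens-plane-to-spot distance along the beam axis.

    Equals ``lens_to_iso`` plus the signed distance from the isocenter plane
    to the spot along the travel direction (positive downstream).
    """
    spot = np.asarray(spot_cm, dtype=float)
    f = beam.lens_to_iso_cm + float(spot @ beam.travel_direction)
    if f <= 0:
        raise ValueError("spot lies upstream of the lens plane")
    return f


def sample_phase_space(beamlet: BeamletSpec, n_rays: int, seed: int) -> RaySet:
    """Sample ``n_rays`` monoenergetic rays of the focused beamlet.

    Entry points are uniform over the lens disc; each ray is aimed at the
    focal point plus a 2D isotropic Gaussian offset in the focal plane with
    sigma = FWHM / sqrt(8 ln 2).  Deterministic for a fixed seed.
    """
    if n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    rng = np.random.default_rng(seed)
    beam = beamlet.beam
    frame = gantry_transform(beam.gantry_angle_deg)
    ex, ey = frame[:, 0], frame[:, 1]

    # uniform disc sampling in the lens plane
    r = beam.lens_radius_cm * np.sqrt(rng.random(n_rays))
    phi = 2.0 * np.pi * rng.random(n_rays)
    entry = (
        beam.lens_center
        + np.outer(r * np.cos(phi), ex)
        + np.outer(r * np.sin(phi), ey)
    )

    sigma = beamlet.focal_fwhm_cm * GAUSSIAN_FWHM_TO_SIGMA
    offsets = rng.normal(0.0, sigma, size=(n_rays, 2))
    targets = (
        np.asarray(beamlet.spot_cm)
        + np.outer(offsets[:, 0], ex)
        + np.outer(offsets[:, 1], ey)
    )

    directions = targets - entry
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    energies = np.full(n_rays, beam.energy_mev)
    weights = np.ones(n_rays)
    return RaySet(entry, directions, energies, weights)


def propagate_to_plane(rays: RaySet, plane_point: np.ndarray, plane_normal: np.ndarray) -> np.ndarray:
    """Intersect straight rays with a plane; returns (n, 3) positions.

    Used for vacuum checks (e.g. measuring the fluence FWHM at the focal
    plane)."""
    plane_point = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    denom = rays.directions @ n
    t = ((plane_point - rays.positions) @ n) / denom
    return rays.positions + rays.directions * t[:, None]


def fluence_fwhm(lateral: np.ndarray, n_bins: int = 101) -> float:
    """FWHM of a 1D fluence histogram with linear interpolation at the
    half-maximum crossings."""
    lateral = np.asarray(lateral, dtype=float)
    span = np.percentile(np.abs(lateral - np.median(lateral)), 99.9) * 3
    center = np.median(lateral)
    counts, edges = np.histogram(lateral, bins=n_bins, range=(center - span, center + span))
    mids = 0.5 * (edges[:-1] + edges[1:])
    peak = counts.max()
    half = peak / 2.0
    above = np.nonzero(counts >= half)[0]
    i0, i1 = above[0], above[-1]

    def _cross(i_out: int, i_in: int) -> float:
        c0, c1 = counts[i_out], counts[i_in]
        if c1 == c0:
            return mids[i_in]
        frac = (half - c0) / (c1 - c0)
        return mids[i_out] + frac * (mids[i_in] - mids[i_out])

    left = mids[i0] if i0 == 0 else _cross(i0 - 1, i0)
    right = mids[i1] if i1 == len(counts) - 1 else _cross(i1 + 1, i1)
    return float(right - left)
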