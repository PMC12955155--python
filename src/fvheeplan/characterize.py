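"""Water-box beamlet characterization: central-axis depth-dose curves and
lateral profiles at and beyond the depth of maximum dose."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from fvheeplan.beam_model import BeamletSpec, sample_phase_space
from fvheeplan.materials import MaterialTable
from fvheeplan.phantoms import Phantom
from fvheeplan.transport import DoseGrid, TransportConfig, transport


@dataclass
class CharacterizationResult:
    """Depth-dose curve (averaged over a central cylinder) plus lateral
    profiles at fixed offsets behind the dose maximum.  ``dmax_depth_cm`` is
    None when no dose was scored (e.g. vacuum phantom)."""

    depth_cm: np.ndarray
    depth_dose: np.ndarray
    depth_dose_rel_unc: np.ndarray
    dmax_depth_cm: float | None
    profiles: dict[float, pd.DataFrame]  # offset behind dmax -> (x_cm, dose)

    def depth_dose_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_cm": self.depth_cm,
                "dose_gy_per_history": self.depth_dose,
                "rel_uncertainty": self.depth_dose_rel_unc,
            }
        )

    def write_csv(self, out_dir: str | Path, stem: str) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = [out_dir / f"{stem}_depth_dose.csv"]
        self.depth_dose_frame().to_csv(paths[0], index=False)
        for off, frame in self.profiles.items():
            p = out_dir / f"{stem}_profile_dmax+{off:g}cm.csv"
            frame.to_csv(p, index=False)
            paths.append(p)
        return paths


def _beam_axis(beamlet: BeamletSpec) -> tuple[int, int]:
    """Grid axis index and sign of the beam travel direction; the beamlet
    must be axis-aligned for characterization."""
    v = beamlet.beam.travel_direction
    axis = int(np.argmax(np.abs(v)))
    if abs(abs(v[axis]) - 1.0) > 1e-9:
        raise ValueError("characterization requires an axis-aligned beamlet")
    return axis, int(np.sign(v[axis]))


def characterize(
    beamlet: BeamletSpec,
    phantom: Phantom,
    cfg: TransportConfig,
    materials: MaterialTable | None = None,
    cylinder_radius_cm: float = 0.5,
    profile_offsets_cm: tuple[float, ...] = (0.0, 5.0, 10.0),
    dose_grid: DoseGrid | None = None,
) -> CharacterizationResult:
    """Simulate (or reuse) one beamlet in a homogeneous water box and extract
    the central-axis depth-dose curve and lateral profiles along x."""
    grid = phantom.grid
    axis, sign = _beam_axis(beamlet)
    if dose_grid is None:
        rays = sample_phase_space(beamlet, cfg.n_histories, cfg.seed)
        dose_grid = transport(phantom, rays, cfg, materials)
    dose = dose_grid.dose

    # depth measured from the entry face along the travel direction
    coords = grid.voxel_centers(axis)
    entry = coords[-1] + grid.spacing[axis] / 2 if sign < 0 else coords[0] - grid.spacing[axis] / 2
    depth = (coords - entry) * sign
    order = np.argsort(depth)
    depth = depth[order]

    # central cylinder around the beam axis (through the spot)
    trans_axes = [a for a in range(3) if a != axis]
    mesh = grid.coordinate_mesh()
    r2 = sum((mesh[a] - beamlet.spot_cm[a]) ** 2 for a in trans_axes)
    in_cyl = r2 <= cylinder_radius_cm**2
    sums = np.where(in_cyl, dose, 0.0).sum(axis=tuple(trans_axes))
    counts = in_cyl.sum(axis=tuple(trans_axes))
    unc = np.where(in_cyl, dose_grid.rel_uncertainty * dose, 0.0).sum(axis=tuple(trans_axes))
    with np.errstate(invalid="ignore", divide="ignore"):
        dd = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)[order]
        dd_unc = np.where(sums > 0, unc / np.maximum(sums, 1e-300), 0.0)[order]

    if dd.max() <= 0:
        return CharacterizationResult(depth, dd, dd_unc, None, {})
    dmax_depth = float(depth[np.argmax(dd)])

    profiles: dict[float, pd.DataFrame] = {}
    for off in profile_offsets_cm:
        target = dmax_depth + off
        if target > depth[-1]:
            continue
        i_slice = order[int(np.argmin(np.abs(depth - target)))]
        sl = [slice(None)] * 3
        sl[axis] = i_slice
        plane = dose[tuple(sl)]
        # profile along x through the beamlet axis; if the beam travels
        # along x, profile along y instead
        prof_axis = 0 if axis != 0 else 1
        other = [a for a in trans_axes if a != prof_axis][0]
        j = int(
            np.clip(
                round((beamlet.spot_cm[other] - grid.origin[other]) / grid.spacing[other]),
                0,
                grid.dims[other] - 1,
            )
        )
        plane_axes = [a for a in range(3) if a != axis]
        if plane_axes.index(prof_axis) == 0:
            line = plane[:, j]
        else:
            line = plane[j, :]
        profiles[off] = pd.DataFrame(
            {"x_cm": grid.voxel_centers(prof_axis), "dose_gy_per_history": line}
        )
    return CharacterizationResult(depth, dd, dd_unc, dmax_depth, profiles)


def lateral_sigma_profile(dose_grid: DoseGrid, beamlet: BeamletSpec) -> pd.DataFrame:
    """Dose-weighted lateral standard deviation versus depth, for comparison
    with the Fermi-Eyges oracle (homogeneous water, axis-aligned beam)."""
    grid = dose_grid.grid
    axis, sign = _beam_axis(beamlet)
    trans_axes = [a for a in range(3) if a != axis]
    prof_axis = trans_axes[0]
    mesh = grid.coordinate_mesh()
    x = mesh[prof_axis] - beamlet.spot_cm[prof_axis]
    w = dose_grid.dose
    sums = w.sum(axis=tuple(trans_axes))
    m1 = (w * x).sum(axis=tuple(trans_axes))
    m2 = (w * x * x).sum(axis=tuple(trans_axes))
    coords = grid.voxel_centers(axis)
    entry = coords[-1] + grid.spacing[axis] / 2 if sign < 0 else coords[0] - grid.spacing[axis] / 2
    depth = (coords - entry) * sign
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = m1 / sums
        var = m2 / sums - mean**2
    sigma = np.sqrt(np.clip(var, 0.0, None))
    order = np.argsort(depth)
    return pd.DataFrame({"depth_cm": depth[order], "sigma_cm": sigma[order], "total_dose": sums[order]})
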