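"""Sparse dose-influence matrices: voxels x beamlets, Gy per unit weight."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import sparse

from fvheeplan.beam_model import BeamConfig, BeamletSpec, sample_phase_space
from fvheeplan.materials import MaterialTable
from fvheeplan.phantoms import Phantom, VoxelGrid
from fvheeplan.spot_grid import BeamletCatalog
from fvheeplan.transport import TransportConfig, transport


@dataclass
class DoseInfluenceMatrix:
    """Linear dose operator: ``dose(w) = A @ w`` with A in CSC form.

    Entries below ``tau`` times the per-beamlet maximum were pruned at
    assembly time.
    """

    grid: VoxelGrid
    matrix: sparse.csc_matrix  # (n_voxels, n_beamlets)
    beamlets: list[BeamletSpec]
    tau: float

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    def dose(self, weights: np.ndarray) -> np.ndarray:
        """Total dose volume for the given beamlet weights."""
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (self.n_beamlets,):
            raise ValueError(f"expected {self.n_beamlets} weights, got {weights.shape}")
        return np.asarray(self.matrix @ weights).reshape(self.grid.shape)

    def save(self, path: str | Path) -> None:
        a = self.matrix
        catalog = [
            {
                "gantry_angle_deg": b.beam.gantry_angle_deg,
                "lens_radius_cm": b.beam.lens_radius_cm,
                "lens_to_iso_cm": b.beam.lens_to_iso_cm,
                "energy_mev": b.beam.energy_mev,
                "spot_cm": list(b.spot_cm),
                "focal_length_cm": b.focal_length_cm,
                "focal_fwhm_cm": b.focal_fwhm_cm,
            }
            for b in self.beamlets
        ]
        with h5py.File(path, "w") as fh:
            fh.create_dataset("indptr", data=a.indptr)
            fh.create_dataset("indices", data=a.indices)
            fh.create_dataset("data", data=a.data)
            fh.attrs["shape"] = a.shape
            fh.attrs["tau"] = self.tau
            fh.attrs["origin"] = self.grid.origin
            fh.attrs["spacing"] = self.grid.spacing
            fh.attrs["dims"] = self.grid.dims
            fh.attrs["catalog"] = json.dumps(catalog)

    @classmethod
    def load(cls, path: str | Path) -> "DoseInfluenceMatrix":
        with h5py.File(path, "r") as fh:
            a = sparse.csc_matrix(
                (fh["data"][:], fh["indices"][:], fh["indptr"][:]),
                shape=tuple(fh.attrs["shape"]),
            )
            grid = VoxelGrid(
                tuple(fh.attrs["origin"]), tuple(fh.attrs["spacing"]), tuple(int(d) for d in fh.attrs["dims"])
            )
            tau = float(fh.attrs["tau"])
            catalog = json.loads(fh.attrs["catalog"])
        beamlets = [
            BeamletSpec(
                BeamConfig(
                    c["gantry_angle_deg"], c["lens_radius_cm"], c["lens_to_iso_cm"], c["energy_mev"]
                ),
                tuple(c["spot_cm"]),
                c["focal_length_cm"],
                c["focal_fwhm_cm"],
            )
            for c in catalog
        ]
        return cls(grid, a, beamlets, tau)


def beamlet_seed(global_seed: int, beamlet_index: int) -> np.random.SeedSequence:
    """Stable per-beamlet seed, independent of computation order."""
    return np.random.SeedSequence([int(global_seed), int(beamlet_index)])


def compute_beamlet_dose(
    phantom: Phantom,
    beamlet: BeamletSpec,
    cfg: TransportConfig,
    materials: MaterialTable | None = None,
):
    """Transport one beamlet; returns its DoseGrid (Gy per unit weight)."""
    rays = sample_phase_space(beamlet, cfg.n_histories, cfg.seed)
    return transport(phantom, rays, cfg, materials)


def compute_influence_matrix(
    phantom: Phantom,
    beamlets: BeamletCatalog | list[BeamletSpec],
    cfg: TransportConfig,
    tau: float = 1e-3,
    materials: MaterialTable | None = None,
) -> DoseInfluenceMatrix:
    """Assemble the sparse voxels-x-beamlets matrix, one transported beamlet
    per column, each normalized per history and pruned at ``tau`` of its own
    maximum."""
    if not 0 <= tau < 1:
        raise ValueError("tau must be in [0, 1)")
    blist = list(beamlets)
    if not blist:
        raise ValueError("need at least one beamlet")
    materials = materials or MaterialTable()
    n_vox = int(np.prod(phantom.grid.dims))
    cols = []
    for i, b in enumerate(blist):
        ss = beamlet_seed(cfg.seed, i)
        sub_seed = ss.generate_state(1)[0]
        sub_cfg = TransportConfig(
            cfg.n_histories, cfg.step_cm, cfg.cutoff_mev, cfg.n_batches, int(sub_seed)
        )
        rays = sample_phase_space(b, cfg.n_histories, int(sub_seed))
        dose = transport(phantom, rays, sub_cfg, materials).dose.ravel()
        if tau > 0 and dose.max() > 0:
            dose = np.where(dose >= tau * dose.max(), dose, 0.0)
        cols.append(sparse.csc_matrix(dose.reshape(-1, 1)))
    a = sparse.hstack(cols, format="csc")
    return DoseInfluenceMatrix(phantom.grid, a, blist, tau)
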