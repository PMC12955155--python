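"""3D diamond-pattern (hexagonal-close-packed) focal-spot lattice.

The lattice has nearest-neighbor distance ``k`` everywhere: hexagonal rows
in each layer (row pitch ``k*sqrt(3)/2``, alternate rows offset by ``k/2``),
layer pitch ``k*sqrt(2/3)`` with the ABAB lateral offset placing each
B-layer point over an A-layer triangle centroid.  The lattice is anchored at
the PTV centroid, defined once and shared by all beam directions; candidates
are retained iff their position falls inside the PTV expanded by the margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from fvheeplan.beam_model import BeamConfig, BeamletSpec, focal_length_for_spot
from fvheeplan.phantoms import VoxelGrid, expand_mask

ROW_PITCH = np.sqrt(3.0) / 2.0
LAYER_PITCH = np.sqrt(2.0 / 3.0)
B_LAYER_OFFSET = (0.5, np.sqrt(3.0) / 6.0)


@dataclass
class SpotLattice:
    """Retained focal-spot positions of the diamond lattice."""

    spacing_cm: float
    margin_cm: float
    anchor_cm: tuple[float, float, float]
    positions: np.ndarray  # (n, 3) world cm, deterministic order

    def __len__(self) -> int:
        return len(self.positions)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.positions, delimiter=",", header="x_cm,y_cm,z_cm", comments="")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "spacing_cm": self.spacing_cm,
                    "margin_cm": self.margin_cm,
                    "anchor_cm": list(self.anchor_cm),
                    "positions": self.positions.tolist(),
                },
                indent=2,
            )
            + "\n"
        )


def mask_centroid(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """World centroid of a voxel mask (mean of voxel centers)."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise ValueError("mask is empty")
    return grid.index_to_world(idx.mean(axis=0))


def hcp_candidates(anchor: np.ndarray, k: float, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """All HCP lattice points with NN distance ``k`` anchored at ``anchor``
    that fall inside the axis-aligned box [lo, hi].

    Enumeration order is (layer, row, column), which fixes the lattice
    ordering everywhere downstream.
    """
    if k <= 0:
        raise ValueError("spacing factor k must be > 0")
    dz = k * LAYER_PITCH
    dy = k * ROW_PITCH
    l_range = np.arange(int(np.floor((lo[2] - anchor[2]) / dz)) - 1, int(np.ceil((hi[2] - anchor[2]) / dz)) + 2)
    j_range = np.arange(int(np.floor((lo[1] - anchor[1]) / dy)) - 1, int(np.ceil((hi[1] - anchor[1]) / dy)) + 2)
    pts = []
    for l in l_range:
        z = anchor[2] + l * dz
        if z < lo[2] - 1e-9 or z > hi[2] + 1e-9:
            continue
        off_x = k * B_LAYER_OFFSET[0] * (l % 2)
        off_y = k * B_LAYER_OFFSET[1] * (l % 2)
        for j in j_range:
            y = anchor[1] + j * dy + off_y
            if y < lo[1] - 1e-9 or y > hi[1] + 1e-9:
                continue
            row_off = 0.5 * k * (j % 2)
            x0 = anchor[0] + off_x + row_off
            i_lo = int(np.ceil((lo[0] - x0) / k - 1e-9))
            i_hi = int(np.floor((hi[0] - x0) / k + 1e-9))
            if i_hi < i_lo:
                continue
            xs = x0 + np.arange(i_lo, i_hi + 1) * k
            block = np.empty((xs.size, 3))
            block[:, 0] = xs
            block[:, 1] = y
            block[:, 2] = z
            pts.append(block)
    if not pts:
        return np.empty((0, 3))
    return np.concatenate(pts, axis=0)


def generate_diamond_grid(
    ptv_mask: np.ndarray,
    grid: VoxelGrid,
    margin_cm: float,
    spacing_cm: float,
    anchor: np.ndarray | None = None,
) -> SpotLattice:
    """Diamond-pattern spot lattice covering the PTV plus margin.

    Candidates span the bounding box of the expanded PTV padded by ``k`` and
    are retained iff the voxel containing them belongs to the expanded mask.
    """
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("PTV mask is empty")
    if spacing_cm <= 0:
        raise ValueError("spacing factor k must be > 0")
    if margin_cm < 0:
        raise ValueError("margin must be >= 0")
    if anchor is None:
        anchor = mask_centroid(ptv_mask, grid)
    anchor = np.asarray(anchor, dtype=float)

    expanded = expand_mask(ptv_mask, margin_cm, grid.spacing)
    idx = np.argwhere(expanded)
    lo = grid.index_to_world(idx.min(axis=0)) - spacing_cm
    hi = grid.index_to_world(idx.max(axis=0)) + spacing_cm
    candidates = hcp_candidates(anchor, spacing_cm, lo, hi)

    keep = np.zeros(len(candidates), dtype=bool)
    if len(candidates):
        vox = np.floor(grid.world_to_index(candidates) + 0.5).astype(int)
        inside = np.all((vox >= 0) & (vox < np.asarray(grid.dims)), axis=1)
        keep[inside] = expanded[tuple(vox[inside].T)]
    return SpotLattice(spacing_cm, margin_cm, tuple(anchor), candidates[keep])


@dataclass
class BeamletCatalog:
    """Beam-major ordered list of (beam, spot) beamlets."""

    beams: list[BeamConfig]
    lattice: SpotLattice
    beamlets: list[BeamletSpec]

    def __len__(self) -> int:
        return len(self.beamlets)

    def __getitem__(self, i: int) -> BeamletSpec:
        return self.beamlets[i]

    def __iter__(self):
        return iter(self.beamlets)


def build_catalog(
    lattice: SpotLattice, beams: list[BeamConfig], focal_fwhm_cm: float = 1.0
) -> BeamletCatalog:
    """One beamlet per (beam, spot), beam-major, with per-spot focal lengths."""
    if not beams:
        raise ValueError("need at least one beam")
    if len(lattice) == 0:
        raise ValueError("need at least one spot")
    beamlets = [
        BeamletSpec(beam, tuple(spot), focal_length_for_spot(beam, spot), focal_fwhm_cm)
        for beam in beams
        for spot in lattice.positions
    ]
    return BeamletCatalog(list(beams), lattice, beamlets)
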