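"""Voxel phantoms, structure sets, case templates and synthetic planning cases.

World units are cm; a voxel's world position is its center.  Masks are full
boolean volumes on the phantom grid.  The "uniform expansion" of a mask is
realized with a Euclidean distance transform on voxel centers so that it is
correct for anisotropic spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel grid: origin/spacing in cm, 0-based indices.

    ``origin`` is the world position of the *center* of voxel (0, 0, 0).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(int(d) < 1 or int(d) != d for d in self.dims):
            raise ValueError(f"dims must be integers >= 1, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world coordinates (cm)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Map world coordinates (cm) to fractional voxel indices."""
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    def coordinate_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (X, Y, Z) of all voxel centers."""
        ax = [self.voxel_centers(i) for i in range(3)]
        return np.meshgrid(*ax, indexing="ij")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return (
            np.allclose(self.origin, other.origin, atol=1e-9)
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
            and self.dims == other.dims
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((self.origin, self.spacing, self.dims))


@dataclass
class Phantom:
    """Voxelized transport medium: grid plus per-voxel mass density (g/cm^3)."""

    grid: VoxelGrid
    density: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        if self.density.shape != self.grid.shape:
            raise ValueError(
                f"density shape {self.density.shape} != grid dims {self.grid.shape}"
            )
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    @property
    def mass(self) -> float:
        """Total phantom mass in g."""
        return float(self.density.sum() * self.grid.voxel_volume)


class StructureSet:
    """Named binary masks on a shared grid.  'PTV' and 'BODY' are required
    for planning; PTV must be contained in BODY."""

    def __init__(self, grid: VoxelGrid, masks: Mapping[str, np.ndarray]):
        self.grid = grid
        self.masks: dict[str, np.ndarray] = {}
        for name, mask in masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != grid.shape:
                raise ValueError(f"mask {name!r} shape {mask.shape} != grid {grid.shape}")
            self.masks[name] = mask

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def validate_for_planning(self) -> None:
        for required in ("PTV", "BODY"):
            if required not in self.masks:
                raise ValueError(f"structure set requires a {required!r} mask")
        ptv, body = self.masks["PTV"], self.masks["BODY"]
        if not ptv.any():
            raise ValueError("PTV mask is empty")
        if np.any(ptv & ~body):
            raise ValueError("PTV extends outside BODY")


NormalizationMode = str  # "D95" | "D50"


@dataclass(frozen=True)
class CaseTemplate:
    """Beam/beamlet setup of one planning case.

    ``prescription_gy`` is the total prescription D_pres; ``fractions`` times
    ``fraction_dose_gy`` equals it.
    """

    name: str
    beam_angles_deg: tuple[float, ...]
    energy_mev: float
    margin_cm: float
    spacing_cm: float
    prescription_gy: float
    fractions: int
    normalization: NormalizationMode

    def __post_init__(self) -> None:
        if self.margin_cm < 0:
            raise ValueError("margin must be >= 0")
        if self.spacing_cm <= 0:
            raise ValueError("spacing factor k must be > 0")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")
        if self.normalization not in ("D95", "D50"):
            raise ValueError(f"normalization must be 'D95' or 'D50', got {self.normalization!r}")

    @property
    def fraction_dose_gy(self) -> float:
        return self.prescription_gy / self.fractions

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=list) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CaseTemplate":
        d = json.loads(Path(path).read_text())
        d["beam_angles_deg"] = tuple(d["beam_angles_deg"])
        return cls(**d)


# Shipped case templates (brain, head-and-neck, two lung, two prostate,
# femoral head).  The clinical CT geometries are not available; these
# templates are applied to the synthetic scenarios below.
_TEMPLATES: dict[str, CaseTemplate] = {
    t.name: t
    for t in [
        CaseTemplate("B", (-130.0, -90.0, 130.0), 250.0, 0.5, 0.36, 12.0, 2, "D95"),
        CaseTemplate("H", (-20.0, 0.0, 30.0, 90.0), 250.0, 0.5, 0.36, 50.0, 25, "D95"),
        CaseTemplate("L1", (-150.0, -90.0, 150.0, 180.0), 250.0, 0.5, 0.36, 60.0, 30, "D50"),
        CaseTemplate("L2", (-130.0, -90.0, 130.0, 180.0), 250.0, 0.5, 0.36, 60.0, 30, "D50"),
        CaseTemplate(
            "P1", (-150.0, -110.0, -20.0, 20.0, 110.0, 150.0), 250.0, 0.5, 0.46, 60.0, 30, "D50"
        ),
        CaseTemplate(
            "P2", (-150.0, -110.0, -20.0, 20.0, 110.0, 150.0), 250.0, 0.5, 0.46, 60.0, 30, "D50"
        ),
        CaseTemplate("F", (-25.0, 0.0, 25.0, 90.0, 180.0), 250.0, 0.25, 0.46, 46.5, 10, "D50"),
    ]
}


def case_template(name: str) -> CaseTemplate:
    """Return one of the shipped case templates (B, H, L1, L2, P1, P2, F)."""
    try:
        return _TEMPLATES[name]
    except KeyError:
        raise KeyError(f"unknown case template {name!r}; have {sorted(_TEMPLATES)}") from None


def available_templates() -> list[str]:
    return sorted(_TEMPLATES)


def make_water_box(
    side_lengths_cm: tuple[float, float, float],
    voxel_size_cm: float | tuple[float, float, float],
    *,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[Phantom, StructureSet]:
    """Uniform water box (density 1.0 g/cm^3) centered at ``center``.

    The BODY mask covers the full box.  Voxel counts are the rounded ratio of
    side length to voxel size; the side length must be an integer multiple of
    the voxel size within rounding.
    """
    if np.isscalar(voxel_size_cm):
        voxel_size = (float(voxel_size_cm),) * 3
    else:
        voxel_size = tuple(float(v) for v in voxel_size_cm)  # type: ignore[arg-type]
    if any(s <= 0 for s in side_lengths_cm) or any(v <= 0 for v in voxel_size):
        raise ValueError("side lengths and voxel size must be positive")
    dims = []
    for s, v in zip(side_lengths_cm, voxel_size):
        n = round(s / v)
        if n < 1 or abs(n * v - s) > 1e-6 * max(1.0, s):
            raise ValueError(f"voxel size {v} does not divide side length {s}")
        dims.append(n)
    origin = tuple(
        c - s / 2 + v / 2 for c, s, v in zip(center, side_lengths_cm, voxel_size)
    )
    grid = VoxelGrid(origin, voxel_size, tuple(dims))
    phantom = Phantom(grid, np.ones(grid.shape))
    structures = StructureSet(grid, {"BODY": np.ones(grid.shape, dtype=bool)})
    return phantom, structures


def expand_mask(mask: np.ndarray, margin_cm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Uniform expansion of a binary mask by ``margin_cm``.

    Returns the set of voxels whose Euclidean distance (between voxel
    centers) to the input mask is <= margin; a superset of the input and
    monotone in the margin.
    """
    if margin_cm < 0:
        raise ValueError("margin must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if margin_cm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_cm + 1e-12


def _sphere_mask(grid: VoxelGrid, center: tuple[float, float, float], radius: float) -> np.ndarray:
    x, y, z = grid.coordinate_mesh()
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2


def _rod_mask(
    grid: VoxelGrid,
    center_xy: tuple[float, float],
    radius: float,
    z_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Cylindrical rod along z, optionally clipped to a z interval."""
    x, y, z = grid.coordinate_mesh()
    mask = (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2 <= radius**2
    if z_range is not None:
        mask &= (z >= z_range[0]) & (z <= z_range[1])
    return mask


def make_planning_case(
    template: CaseTemplate,
    scenario: str,
    *,
    body_radius_cm: float = 8.0,
    body_length_cm: float = 16.0,
    ptv_radius_cm: float = 1.5,
    ptv_offset_cm: float = 3.5,
    voxel_size_cm: float = 0.25,
) -> tuple[Phantom, StructureSet]:
    """Synthetic cylindrical 'patient' standing in for the clinical CTs.

    Scenarios:

    * ``lateral`` — spherical PTV offset laterally (+x) with a contralateral
      rod OAR on the opposite side, disjoint from the PTV.
    * ``central`` — PTV on the cylinder axis with an anterior rod OAR and a
      posterior ("rectum-like") rod abutting the PTV surface.
    * ``bilateral`` — two PTV subvolumes at +/- the lateral offset, with a
      central rod OAR between them.

    The body is a water cylinder (axis along z); densities are 1.0 inside
    the body, 0 outside.
    """
    if scenario not in ("lateral", "central", "bilateral"):
        raise ValueError(f"unknown scenario {scenario!r}")
    n_xy = int(round(2 * body_radius_cm / voxel_size_cm)) + 4
    n_z = int(round(body_length_cm / voxel_size_cm)) + 4
    extent_xy = n_xy * voxel_size_cm
    extent_z = n_z * voxel_size_cm
    origin = (
        -extent_xy / 2 + voxel_size_cm / 2,
        -extent_xy / 2 + voxel_size_cm / 2,
        -extent_z / 2 + voxel_size_cm / 2,
    )
    grid = VoxelGrid(origin, (voxel_size_cm,) * 3, (n_xy, n_xy, n_z))

    half_len = body_length_cm / 2
    body = _rod_mask(grid, (0.0, 0.0), body_radius_cm, (-half_len, half_len))
    density = np.where(body, 1.0, 0.0)

    oar_radius = 1.0
    masks: dict[str, np.ndarray] = {"BODY": body}
    if scenario == "lateral":
        ptv = _sphere_mask(grid, (ptv_offset_cm, 0.0, 0.0), ptv_radius_cm)
        masks["contralateral"] = body & _rod_mask(
            grid, (-ptv_offset_cm + 0.5, 0.0), oar_radius, (-half_len + 1, half_len - 1)
        )
    elif scenario == "central":
        ptv = _sphere_mask(grid, (0.0, 0.0, 0.0), ptv_radius_cm)
        # posterior is -y: a rod abutting the posterior PTV surface
        masks["rectum_like"] = body & _rod_mask(
            grid, (0.0, -(ptv_radius_cm + oar_radius)), oar_radius, (-3.0, 3.0)
        )
        masks["anterior_rod"] = body & _rod_mask(
            grid, (0.0, ptv_radius_cm + oar_radius), oar_radius, (-3.0, 3.0)
        )
    else:  # bilateral
        ptv = _sphere_mask(grid, (ptv_offset_cm, 0.0, 0.0), ptv_radius_cm) | _sphere_mask(
            grid, (-ptv_offset_cm, 0.0, 0.0), ptv_radius_cm
        )
        masks["central_rod"] = body & _rod_mask(grid, (0.0, 0.0), oar_radius, (-3.0, 3.0))

    if np.any(ptv & ~body):
        raise ValueError("constructed PTV extends outside BODY")
    masks["PTV"] = ptv
    structures = StructureSet(grid, masks)
    structures.validate_for_planning()
    if scenario != "central":
        for name, m in masks.items():
            if name not in ("PTV", "BODY") and np.any(m & ptv):
                raise ValueError(f"OAR {name!r} overlaps the PTV")
    return Phantom(grid, density), structures
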