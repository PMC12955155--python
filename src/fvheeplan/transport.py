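"""Simplified condensed-history electron transport with dose scoring.

Physics model (a documented stand-in for a full Monte Carlo code, with
testable conservation laws):

* continuous slowing down: per step of length ``ds`` in density ``rho`` the
  collisional loss ``S_col(E) * rho * ds`` is deposited in the current voxel
  and the radiative loss ``S_rad(E) * rho * ds`` is removed without local
  deposition (bremsstrahlung-escape approximation);
* multiple Coulomb scattering: after each step the direction receives two
  independent Gaussian kicks with the Highland sigma for the traversed
  thickness in radiation lengths;
* histories end when the energy falls to the cutoff (residual energy is
  deposited locally) or when the track leaves the grid.

Statistical uncertainty uses the batch method: histories are split into
``n_batches`` independent batches and the per-voxel relative uncertainty is
the standard error of the batch means.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fvheeplan.beam_model import RaySet
from fvheeplan.materials import GY_PER_MEV_PER_G, MaterialTable, highland_sigma
from fvheeplan.phantoms import Phantom, VoxelGrid

_EPS_ADVANCE = 1e-9


@dataclass(frozen=True)
class TransportConfig:
    """Transport parameters.  ``n_histories`` is the total over all batches."""

    n_histories: int
    step_cm: float = 0.1
    cutoff_mev: float = 2.0
    n_batches: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_cm <= 0:
            raise ValueError("step length must be > 0")
        if self.cutoff_mev <= 0:
            raise ValueError("energy cutoff must be > 0")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches for uncertainty estimation")
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")


@dataclass
class EnergyLedger:
    """Exact energy bookkeeping accumulated during transport (MeV, weighted)."""

    total_input: float = 0.0
    deposited: float = 0.0  # continuous collisional deposits
    cutoff_deposited: float = 0.0  # residual energy dumped at track end
    radiative: float = 0.0  # bremsstrahlung losses, removed non-locally
    escaped: float = 0.0  # kinetic energy carried out of the grid

    @property
    def total_accounted(self) -> float:
        return self.deposited + self.cutoff_deposited + self.radiative + self.escaped

    @property
    def closure(self) -> float:
        """Relative energy-conservation defect."""
        if self.total_input == 0:
            return 0.0
        return abs(self.total_accounted - self.total_input) / self.total_input


@dataclass
class DoseGrid:
    """Dose per voxel (Gy per unit beamlet weight == per history) with
    per-voxel relative statistical uncertainty."""

    grid: VoxelGrid
    dose: np.ndarray
    rel_uncertainty: np.ndarray
    ledger: EnergyLedger | None = None

    def __post_init__(self) -> None:
        if self.dose.shape != self.grid.shape or self.rel_uncertainty.shape != self.grid.shape:
            raise ValueError("dose/uncertainty shape does not match grid")

    def mean_rel_uncertainty(self, dose_fraction: float = 0.5) -> float:
        """Mean relative uncertainty over voxels above ``dose_fraction`` of
        the maximum dose."""
        dmax = self.dose.max()
        if dmax <= 0:
            return float("nan")
        sel = self.dose > dose_fraction * dmax
        return float(self.rel_uncertainty[sel].mean())


def _advance_to_box(pos: np.ndarray, dirs: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Move rays forward to their axis-aligned-box entry point (slab method).

    Returns updated positions and a boolean mask of rays that hit the box.
    Rays already inside are left in place.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t1 = (lo - pos) * inv
        t2 = (hi - pos) * inv
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hits = (tmax >= tmin) & (tmax > 0)
    tentry = np.clip(tmin, 0.0, None)
    out = pos.copy()
    out[hits] += dirs[hits] * (tentry[hits, None] + _EPS_ADVANCE)
    return out, hits


def _transverse_basis(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-ray orthonormal basis of the plane perpendicular to ``dirs``."""
    helper = np.zeros_like(dirs)
    use_x = np.abs(dirs[:, 2]) > 0.9
    helper[use_x, 0] = 1.0
    helper[~use_x, 2] = 1.0
    e1 = np.cross(dirs, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    return e1, e2


def _run_batch(
    phantom: Phantom,
    pos: np.ndarray,
    dirs: np.ndarray,
    energy: np.ndarray,
    weight: np.ndarray,
    cfg: TransportConfig,
    materials: MaterialTable,
    rng: np.random.Generator,
    ledger: EnergyLedger,
) -> np.ndarray:
    """Transport one batch; returns deposited energy (MeV, weighted) per voxel."""
    grid = phantom.grid
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    dims = np.asarray(grid.dims)
    lo = origin - spacing / 2
    hi = origin + (dims - 0.5) * spacing
    density_flat = phantom.density.ravel()
    edep = np.zeros(density_flat.size)
    ds = cfg.step_cm
    inv_x0 = 1.0 / materials.x0_g_cm2

    ledger.total_input += float(energy @ weight)
    pos, hits = _advance_to_box(pos, dirs, lo, hi)
    if not hits.all():
        miss = ~hits
        ledger.escaped += float(energy[miss] @ weight[miss])
        pos, dirs, energy, weight = pos[hits], dirs[hits], energy[hits], weight[hits]
    pos = pos.copy()
    dirs = dirs.copy()
    energy = energy.copy()

    while energy.size:
        idx = np.floor((pos - origin) / spacing + 0.5).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < dims), axis=1)
        if not inside.all():
            out = ~inside
            ledger.escaped += float(energy[out] @ weight[out])
            pos, dirs, energy, weight, idx = (
                pos[inside],
                dirs[inside],
                energy[inside],
                weight[inside],
                idx[inside],
            )
            if not energy.size:
                break
        flat = (idx[:, 0] * dims[1] + idx[:, 1]) * dims[2] + idx[:, 2]
        rho = density_flat[flat]

        de_col = materials.stopping_power_col(energy) * rho * ds
        de_rad = materials.stopping_power_rad(energy) * rho * ds
        # clamp so the energy cannot go negative within one step
        total_loss = de_col + de_rad
        over = total_loss > energy
        if np.any(over):
            scale = energy[over] / total_loss[over]
            de_col[over] *= scale
            de_rad[over] *= scale
        np.add.at(edep, flat, de_col * weight)
        ledger.deposited += float(de_col @ weight)
        ledger.radiative += float(de_rad @ weight)
        energy = energy - de_col - de_rad

        # terminate sub-cutoff histories, dumping the residual locally
        dead = energy <= cfg.cutoff_mev
        if np.any(dead):
            np.add.at(edep, flat[dead], energy[dead] * weight[dead])
            ledger.cutoff_deposited += float(energy[dead] @ weight[dead])

        # advance, then deflect survivors by two Gaussian Highland kicks
        pos = pos + dirs * ds
        alive = ~dead
        if not alive.all():
            pos, dirs, energy, weight, rho = (
                pos[alive],
                dirs[alive],
                energy[alive],
                weight[alive],
                rho[alive],
            )
        if not energy.size:
            break
        t = rho * ds * inv_x0
        scattering = t > 0
        if np.any(scattering):
            theta0 = highland_sigma(energy[scattering], t[scattering])
            kicks = rng.normal(size=(theta0.size, 2)) * theta0[:, None]
            e1, e2 = _transverse_basis(dirs[scattering])
            newd = dirs[scattering] + kicks[:, :1] * e1 + kicks[:, 1:] * e2
            newd /= np.linalg.norm(newd, axis=1, keepdims=True)
            dirs[scattering] = newd
    return edep


def transport(phantom: Phantom, rays: RaySet, cfg: TransportConfig, materials: MaterialTable | None = None) -> DoseGrid:
    """Transport a ray set through the phantom and score dose.

    ``cfg.n_histories`` rays are taken from ``rays`` (which must contain at
    least that many); they are split into ``cfg.n_batches`` near-equal
    batches for the uncertainty estimate.  Dose is returned per history
    (Gy per unit beamlet weight).
    """
    if len(rays) == 0:
        raise ValueError("empty ray set")
    if len(rays) < cfg.n_histories:
        raise ValueError(f"ray set has {len(rays)} rays < n_histories={cfg.n_histories}")
    materials = materials or MaterialTable()
    grid = phantom.grid
    n = cfg.n_histories
    nb = cfg.n_batches
    bounds = np.linspace(0, n, nb + 1).astype(int)

    voxel_mass = phantom.density * grid.voxel_volume  # g
    nonzero = voxel_mass > 0
    ledger = EnergyLedger()
    batch_dose = np.zeros((nb, *grid.shape))
    for b in range(nb):
        s = slice(bounds[b], bounds[b + 1])
        n_b = bounds[b + 1] - bounds[b]
        if n_b == 0:
            continue
        rng = np.random.default_rng([cfg.seed, b])
        edep = _run_batch(
            phantom,
            rays.positions[s],
            rays.directions[s],
            rays.energies[s].astype(float),
            rays.weights[s].astype(float),
            cfg,
            materials,
            rng,
            ledger,
        ).reshape(grid.shape)
        d = np.zeros(grid.shape)
        d[nonzero] = edep[nonzero] * GY_PER_MEV_PER_G / voxel_mass[nonzero] / n_b
        batch_dose[b] = d

    weights_b = np.diff(bounds) / n
    mean = np.einsum("b,bijk->ijk", weights_b, batch_dose)
    # standard error of the (equally-sized) batch means
    var = np.mean((batch_dose - mean) ** 2, axis=0) / max(nb - 1, 1)
    sigma = np.sqrt(var)
    rel = np.zeros(grid.shape)
    pos_mask = mean > 0
    rel[pos_mask] = sigma[pos_mask] / mean[pos_mask]
    return DoseGrid(grid, mean, rel, ledger)
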