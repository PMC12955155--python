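"""Fluence-map optimization of nonnegative beamlet weights.

The objective is a weighted sum of one-sided quadratic penalties per
structure; it is minimized by projected gradient descent with Armijo
backtracking and the projection ``w <- max(w, 0)``.  Dose-volume ("dvh_max")
objectives re-select their penalized voxels every iteration, which makes
the problem non-convex; accepted objective values are still monotone
non-increasing by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fvheeplan.influence import DoseInfluenceMatrix
from fvheeplan.phantoms import StructureSet
from fvheeplan.plan_eval import compute_dvh, dose_at_volume

OBJECTIVE_TYPES = ("uniform", "max_dose", "min_dose", "mean_dose", "dvh_max")


@dataclass(frozen=True)
class ObjectiveSpec:
    """One penalty term on one structure."""

    structure: str
    kind: str
    d_ref_gy: float
    weight: float = 1.0
    v_ref: float | None = None  # allowed volume fraction, dvh_max only

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_TYPES:
            raise ValueError(f"unknown objective type {self.kind!r}")
        if self.d_ref_gy < 0:
            raise ValueError("reference dose must be >= 0")
        if self.weight <= 0:
            raise ValueError("penalty weight must be > 0")
        if self.kind == "dvh_max":
            if self.v_ref is None or not 0 < self.v_ref < 1:
                raise ValueError("dvh_max requires v_ref in (0, 1)")


@dataclass(frozen=True)
class OptimizationConfig:
    max_iterations: int = 500
    rel_tolerance: float = 1e-5
    initial_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.rel_tolerance <= 0:
            raise ValueError("limits must be positive")


@dataclass
class Plan:
    """Optimized beamlet weights with convergence trace and the global
    normalization scale applied afterwards."""

    weights: np.ndarray
    objective_trace: list[float]
    scale: float = 1.0
    normalization: str | None = None
    prescription_gy: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.scale <= 0:
            raise ValueError("normalization scale must be > 0")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": self.weights.tolist(),
                    "objective_trace": self.objective_trace,
                    "scale": self.scale,
                    "normalization": self.normalization,
                    "prescription_gy": self.prescription_gy,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "Plan":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["weights"], dtype=float),
            list(d["objective_trace"]),
            d["scale"],
            d.get("normalization"),
            d.get("prescription_gy"),
        )


def _voxel_indices(structures: StructureSet, name: str) -> np.ndarray:
    if name not in structures:
        raise KeyError(f"unknown structure {name!r}")
    return np.flatnonzero(structures[name].ravel())


def objective_value(
    matrix,
    weights: np.ndarray,
    objectives: list[ObjectiveSpec],
    structures: StructureSet,
    return_gradient: bool = True,
):
    """Penalty value F(w) and (optionally) its analytic gradient.

    ``F(w) = sum_o p_o / |V_o| * sum_{i in V_o} e_{o,i}^2`` with the residual
    ``e`` depending on the objective type; mean_dose applies one residual to
    the structure mean.  ``matrix`` is anything with ``@`` onto weights
    (sparse influence matrix or a dense array).
    """
    a = matrix.matrix if isinstance(matrix, DoseInfluenceMatrix) else matrix
    weights = np.asarray(weights, dtype=float)
    d = np.asarray(a @ weights).ravel()
    if not np.all(np.isfinite(d)):
        raise FloatingPointError("non-finite dose in objective evaluation")
    value = 0.0
    # accumulate dF/dd sparsely, then one adjoint product
    grad_d = np.zeros_like(d) if return_gradient else None
    for obj in objectives:
        vox = _voxel_indices(structures, obj.structure)
        if vox.size == 0:
            raise ValueError(f"objective structure {obj.structure!r} has no voxels")
        dv = d[vox]
        nv = vox.size
        p = obj.weight
        if obj.kind == "uniform":
            e = dv - obj.d_ref_gy
        elif obj.kind == "max_dose":
            e = np.maximum(dv - obj.d_ref_gy, 0.0)
        elif obj.kind == "min_dose":
            e = -np.maximum(obj.d_ref_gy - dv, 0.0)
        elif obj.kind == "mean_dose":
            m = dv.mean() - obj.d_ref_gy
            value += p * m * m
            if return_gradient:
                grad_d[vox] += p * 2.0 * m / nv
            continue
        else:  # dvh_max: penalize only the excess voxels above the quota,
            # keeping the smallest-excess ones (closest to d_ref)
            over = np.flatnonzero(dv > obj.d_ref_gy)
            allowed = int(np.floor(obj.v_ref * nv))
            if over.size <= allowed:
                continue
            excess = dv[over] - obj.d_ref_gy
            n_penal = over.size - allowed
            sel = over[np.argsort(excess, kind="stable")[:n_penal]]
            e_sel = dv[sel] - obj.d_ref_gy
            value += p / nv * float(e_sel @ e_sel)
            if return_gradient:
                grad_d[vox[sel]] += p * 2.0 / nv * e_sel
            continue
        value += p / nv * float(e @ e)
        if return_gradient:
            grad_d[vox] += p * 2.0 / nv * e
    if not return_gradient:
        return value
    grad_w = np.asarray(a.T @ grad_d).ravel()
    return value, grad_w


def optimize(
    matrix,
    objectives: list[ObjectiveSpec],
    structures: StructureSet,
    cfg: OptimizationConfig = OptimizationConfig(),
    initial_weights: np.ndarray | None = None,
) -> Plan:
    """Projected-gradient descent with Armijo backtracking.

    The iterate stays nonnegative; accepted objective values are monotone
    non-increasing; stops when the relative decrease falls below the
    tolerance or at the iteration limit.
    """
    a = matrix.matrix if isinstance(matrix, DoseInfluenceMatrix) else matrix
    n_beamlets = a.shape[1]
    if n_beamlets < 1:
        raise ValueError("influence matrix has no beamlets")
    ptv_kinds = {o.kind for o in objectives if o.structure == "PTV"}
    if not ptv_kinds & {"uniform", "min_dose"}:
        raise ValueError("PTV requires at least one uniform or min_dose objective")

    if initial_weights is None:
        w = np.ones(n_beamlets)
        # scale the uniform start so the mean PTV dose hits the PTV target
        ptv_obj = next(o for o in objectives if o.structure == "PTV" and o.kind in ("uniform", "min_dose"))
        vox = _voxel_indices(structures, "PTV")
        mean_dose = float(np.asarray(a @ w).ravel()[vox].mean())
        if mean_dose > 0:
            w *= ptv_obj.d_ref_gy / mean_dose
    else:
        w = np.maximum(np.asarray(initial_weights, dtype=float), 0.0)

    f, g = objective_value(a, w, objectives, structures)
    trace = [f]
    g_norm = float(g @ g)
    # scale-aware first step: the weights can be many orders of magnitude
    # larger than the gradient when dose-per-unit-weight is small
    if g_norm > 0 and float(w @ w) > 0:
        step = cfg.initial_step * np.sqrt(float(w @ w) / g_norm)
    else:
        step = cfg.initial_step
    for _ in range(cfg.max_iterations):
        accepted = False
        for _bt in range(60):
            w_new = np.maximum(w - step * g, 0.0)
            f_new = objective_value(a, w_new, objectives, structures, return_gradient=False)
            if not np.isfinite(f_new):
                raise FloatingPointError("non-finite objective during line search")
            decrease = float(g @ (w - w_new))
            if f_new <= f - 1e-4 * decrease and f_new <= f:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        f_new_grad, g_new = objective_value(a, w_new, objectives, structures)
        s = w_new - w
        y = g_new - g
        sy = float(s @ y)
        # Barzilai-Borwein step for the next iterate, grown if curvature is flat
        step = float(s @ s) / sy if sy > 0 else step * 2.0
        w, f_old, f, g = w_new, f, f_new_grad, g_new
        trace.append(f)
        if f_old - f <= cfg.rel_tolerance * max(abs(f_old), 1e-30):
            break
    return Plan(w, trace)


def normalize_plan(
    dose: np.ndarray,
    ptv_mask: np.ndarray,
    mode: str,
    prescription_gy: float,
) -> tuple[float, np.ndarray]:
    """Global rescale so that D95% or D50% of the PTV equals the
    prescription; returns (scale, scaled dose)."""
    if mode not in ("D95", "D50"):
        raise ValueError(f"normalization mode must be 'D95' or 'D50', got {mode!r}")
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    ptv_dose = np.asarray(dose)[ptv_mask]
    if ptv_dose.size == 0 or ptv_dose.max() <= 0:
        raise ValueError("PTV dose is zero; cannot normalize")
    dvh = compute_dvh(np.asarray(dose), ptv_mask, name="PTV")
    d_mode = dose_at_volume(dvh, 95.0 if mode == "D95" else 50.0)
    if d_mode <= 0:
        raise ValueError(f"{mode} of the PTV is zero; cannot normalize")
    scale = prescription_gy / d_mode
    return scale, np.asarray(dose) * scale
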