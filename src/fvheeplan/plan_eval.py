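"""DVH computation and plan-quality metrics (Dx%, VxGy, D_mean, homogeneity
index, Paddick conformity index) with comparison reports.

DVHs are exact (sorting-based, no binning): ``v(d)`` is the fraction of
structure voxels with dose >= d.  Dx%/Vd use linear interpolation between
adjacent sorted doses.  The homogeneity index follows the ICRU-83 form
``(D2% - D98%) / D50%``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DVHCurve:
    """Cumulative DVH of one structure.

    ``doses`` are the sorted (descending) voxel doses; ``volume_fractions``
    holds the fraction of voxels receiving at least each dose, so the curve
    is non-increasing in dose, starts at 1.0 at the minimum dose and falls
    toward 0 at the maximum.
    """

    structure: str
    doses: np.ndarray  # descending
    volume_fractions: np.ndarray  # (i+1)/n for the i-th largest dose

    @property
    def n_voxels(self) -> int:
        return len(self.doses)

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(self.doses, kind="stable")
        return pd.DataFrame(
            {
                "structure": self.structure,
                "dose_gy": self.doses[order],
                "volume_fraction": self.volume_fractions[order],
            }
        )


def compute_dvh(dose: np.ndarray, mask: np.ndarray, name: str = "") -> DVHCurve:
    """Exact cumulative DVH from the sorted voxel doses of ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"mask for structure {name!r} is empty")
    vals = np.sort(np.asarray(dose)[mask].ravel())[::-1]
    n = vals.size
    fractions = np.arange(1, n + 1) / n
    return DVHCurve(name, vals, fractions)


def dose_at_volume(dvh: DVHCurve, x_percent: float) -> float:
    """Dx% — the smallest dose received by at least x% of the volume, with
    linear interpolation between adjacent sorted doses."""
    if not 0 < x_percent <= 100:
        raise ValueError("x must be in (0, 100]")
    frac = x_percent / 100.0
    # volume_fractions ascend with descending dose
    return float(np.interp(frac, dvh.volume_fractions, dvh.doses))


def volume_at_dose(dvh: DVHCurve, d_gy: float) -> float:
    """Vd — percent of the volume receiving at least ``d_gy``, by exact
    counting (voxels at exactly the threshold are included)."""
    if d_gy < 0:
        raise ValueError("dose threshold must be >= 0")
    return float(np.count_nonzero(dvh.doses >= d_gy) / dvh.n_voxels * 100.0)


def mean_dose(dvh: DVHCurve) -> float:
    return float(dvh.doses.mean())


def homogeneity_index(ptv_dvh: DVHCurve) -> float:
    """(D2% - D98%) / D50%; 0 for a perfectly uniform dose."""
    d50 = dose_at_volume(ptv_dvh, 50.0)
    if d50 == 0:
        warnings.warn("D50% of the PTV is zero; homogeneity index undefined")
        return float("nan")
    return (dose_at_volume(ptv_dvh, 2.0) - dose_at_volume(ptv_dvh, 98.0)) / d50


def paddick_ci(dose: np.ndarray, ptv_mask: np.ndarray, isodose_gy: float) -> float:
    """Paddick conformity index |TV&PIV|^2 / (|TV| |PIV|) at the given
    isodose level; 1 is perfect conformity."""
    if isodose_gy <= 0:
        raise ValueError("isodose level must be > 0")
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    piv = np.asarray(dose) >= isodose_gy
    n_tv = int(ptv_mask.sum())
    n_piv = int(piv.sum())
    if n_tv == 0:
        raise ValueError("empty target volume")
    if n_piv == 0:
        warnings.warn("prescription isodose volume is empty; CI = 0")
        return 0.0
    overlap = int((ptv_mask & piv).sum())
    return overlap**2 / (n_tv * n_piv)


@dataclass
class PlanMetrics:
    """Per-structure DVH parameters plus PTV HI/CI for one plan."""

    plan_name: str
    prescription_gy: float
    structures: dict[str, dict[str, float]] = field(default_factory=dict)
    hi: float = float("nan")
    ci: float = float("nan")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    def as_dict(self) -> dict:
        return {
            "plan_name": self.plan_name,
            "prescription_gy": self.prescription_gy,
            "structures": self.structures,
            "hi": self.hi,
            "ci": self.ci,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlanMetrics":
        return cls(d["plan_name"], d["prescription_gy"], d["structures"], d["hi"], d["ci"])


def compute_plan_metrics(
    dose: np.ndarray,
    structures,
    prescription_gy: float,
    plan_name: str = "plan",
    ci_isodose_fraction: float = 1.0,
    extra_volume_thresholds_gy: tuple[float, ...] = (20.0,),
) -> PlanMetrics:
    """Standard metric set per structure: D2%, D50%, D98%, D_mean, V95%
    (volume at 95% of prescription) and VxGy thresholds; HI and Paddick CI
    on the PTV."""
    metrics = PlanMetrics(plan_name, prescription_gy)
    dose = np.asarray(dose)
    for name, mask in structures.masks.items():
        if not mask.any():
            continue
        dvh = compute_dvh(dose, mask, name)
        entry = {
            "D2%_gy": dose_at_volume(dvh, 2.0),
            "D50%_gy": dose_at_volume(dvh, 50.0),
            "D98%_gy": dose_at_volume(dvh, 98.0),
            "Dmean_gy": mean_dose(dvh),
            "V95%_%": volume_at_dose(dvh, 0.95 * prescription_gy),
        }
        for thr in extra_volume_thresholds_gy:
            entry[f"V{thr:g}Gy_%"] = volume_at_dose(dvh, thr)
        metrics.structures[name] = entry
    ptv_dvh = compute_dvh(dose, structures["PTV"], "PTV")
    metrics.hi = homogeneity_index(ptv_dvh)
    metrics.ci = paddick_ci(dose, structures["PTV"], ci_isodose_fraction * prescription_gy)
    return metrics


def plan_report(plans: list[PlanMetrics]) -> pd.DataFrame:
    """Long-format comparison table across plans.

    One row per (structure, metric) with one column per plan, a best-plan
    flag (lower is better except coverage/conformity metrics) and, for two
    plans, the pairwise difference.
    """
    if not plans:
        raise ValueError("no plans to report")
    names = [p.plan_name for p in plans]
    if len(set(names)) != len(names):
        raise ValueError("plan names must be unique")
    rows = []
    all_structs: list[str] = []
    for p in plans:
        for s in p.structures:
            if s not in all_structs:
                all_structs.append(s)
    higher_better = ("V95%_%",)
    all_metrics: list[str] = []
    for p in plans:
        for s in p.structures.values():
            for m in s:
                if m not in all_metrics:
                    all_metrics.append(m)
    for struct in all_structs:
        for metric in all_metrics:
            vals = {p.plan_name: p.structures.get(struct, {}).get(metric) for p in plans}
            present = {k: v for k, v in vals.items() if v is not None}
            if not present:
                continue
            if metric in higher_better:
                best = max(present, key=present.get)
            else:
                best = min(present, key=present.get)
            row = {"structure": struct, "metric": metric, **vals, "best": best}
            if len(plans) == 2 and len(present) == 2:
                row["difference"] = present[names[0]] - present[names[1]]
            rows.append(row)
    for metric, attr, best_high in (("HI", "hi", False), ("CI", "ci", True)):
        vals = {p.plan_name: getattr(p, attr) for p in plans}
        best = (max if best_high else min)(vals, key=vals.get)
        row = {"structure": "PTV", "metric": metric, **vals, "best": best}
        if len(plans) == 2:
            row["difference"] = vals[names[0]] - vals[names[1]]
        rows.append(row)
    return pd.DataFrame(rows)
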