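"""Configuration-driven two-stage planning workflow.

Stage 1 computes the dose-influence matrix (phantom -> spot lattice ->
beamlet catalog -> per-beamlet transport); stage 2 optimizes beamlet
weights, normalizes the plan and evaluates DVH metrics.  Every artifact is
written with provenance (config hash, seed, package version) and each stage
can be rerun from the saved artifacts of the previous one.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from fvheeplan import __version__
from fvheeplan.beam_model import BeamConfig, BeamletSpec
from fvheeplan.characterize import characterize
from fvheeplan.influence import DoseInfluenceMatrix, compute_influence_matrix
from fvheeplan.inverse_opt import (
    ObjectiveSpec,
    OptimizationConfig,
    Plan,
    normalize_plan,
    optimize,
)
from fvheeplan.phantoms import (
    CaseTemplate,
    Phantom,
    StructureSet,
    case_template,
    make_planning_case,
    make_water_box,
)
from fvheeplan.plan_eval import compute_plan_metrics, plan_report
from fvheeplan.spot_grid import build_catalog, generate_diamond_grid
from fvheeplan.transport import TransportConfig
from fvheeplan.volume_io import write_volume

log = logging.getLogger("fvheeplan")


@dataclass
class RunConfig:
    """Validated run configuration (see ``load_config`` for the YAML schema)."""

    template: CaseTemplate
    scenario: str = "lateral"
    voxel_size_cm: float = 0.4
    beam_angles_deg: tuple[float, ...] | None = None  # override template angles
    lens_radius_cm: float = 5.0
    lens_to_iso_cm: float = 50.0
    focal_fwhm_cm: float = 1.0
    histories_per_beamlet: int = 4000
    step_cm: float = 0.1
    cutoff_mev: float = 2.0
    n_batches: int = 20
    pruning_tau: float = 1e-3
    objectives: list[ObjectiveSpec] = field(default_factory=list)
    max_iterations: int = 300
    rel_tolerance: float = 1e-6
    seed: int = 0
    output_dir: Path = Path("out")

    @property
    def angles(self) -> tuple[float, ...]:
        return self.beam_angles_deg or self.template.beam_angles_deg

    def beams(self) -> list[BeamConfig]:
        return [
            BeamConfig(a, self.lens_radius_cm, self.lens_to_iso_cm, self.template.energy_mev)
            for a in self.angles
        ]

    def transport_config(self) -> TransportConfig:
        return TransportConfig(
            self.histories_per_beamlet, self.step_cm, self.cutoff_mev, self.n_batches, self.seed
        )

    def validate(self) -> None:
        if self.scenario not in ("lateral", "central", "bilateral"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not self.objectives:
            raise ValueError("config defines no objectives")
        if not any(
            o.structure == "PTV" and o.kind in ("uniform", "min_dose") for o in self.objectives
        ):
            raise ValueError("config must include a PTV uniform or min_dose objective")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_objectives(template: CaseTemplate, structures: StructureSet) -> list[ObjectiveSpec]:
    """Template objectives: uniform PTV at prescription, max-dose penalties
    on each OAR and a low body max penalty."""
    d = template.prescription_gy
    objectives = [ObjectiveSpec("PTV", "uniform", d, 100.0)]
    for name in structures.names:
        if name in ("PTV", "BODY"):
            continue
        objectives.append(ObjectiveSpec(name, "max_dose", 0.1 * d, 20.0))
    objectives.append(ObjectiveSpec("BODY", "max_dose", 1.05 * d, 5.0))
    return objectives


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate the YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    case = raw.get("case", {})
    if "template" in case:
        template = case_template(case["template"])
    else:
        template = CaseTemplate(
            name=case.get("name", "custom"),
            beam_angles_deg=tuple(case["beam_angles_deg"]),
            energy_mev=case.get("energy_mev", 250.0),
            margin_cm=case["margin_cm"],
            spacing_cm=case["spacing_cm"],
            prescription_gy=case["prescription_gy"],
            fractions=case.get("fractions", 1),
            normalization=case.get("normalization", "D50"),
        )
    overrides = {}
    for key in ("margin_cm", "spacing_cm", "prescription_gy", "normalization"):
        if key in case and "template" in case:
            overrides[key] = case[key]
    if overrides:
        template = CaseTemplate(
            template.name,
            template.beam_angles_deg,
            template.energy_mev,
            overrides.get("margin_cm", template.margin_cm),
            overrides.get("spacing_cm", template.spacing_cm),
            overrides.get("prescription_gy", template.prescription_gy),
            template.fractions,
            overrides.get("normalization", template.normalization),
        )
    beams = raw.get("beams", {})
    transport_cfg = raw.get("transport", {})
    opt = raw.get("optimization", {})
    objectives = [
        ObjectiveSpec(
            o["structure"],
            o["kind"],
            o["d_ref_gy"],
            o.get("weight", 1.0),
            o.get("v_ref"),
        )
        for o in raw.get("objectives", [])
    ]
    cfg = RunConfig(
        template=template,
        scenario=case.get("scenario", "lateral"),
        voxel_size_cm=case.get("voxel_size_cm", 0.4),
        beam_angles_deg=tuple(beams["angles_deg"]) if "angles_deg" in beams else None,
        lens_radius_cm=beams.get("lens_radius_cm", 5.0),
        lens_to_iso_cm=beams.get("lens_to_iso_cm", 50.0),
        focal_fwhm_cm=beams.get("focal_fwhm_cm", 1.0),
        histories_per_beamlet=transport_cfg.get("histories_per_beamlet", 4000),
        step_cm=transport_cfg.get("step_cm", 0.1),
        cutoff_mev=transport_cfg.get("cutoff_mev", 2.0),
        n_batches=transport_cfg.get("n_batches", 20),
        pruning_tau=raw.get("pruning_tau", 1e-3),
        objectives=objectives,
        max_iterations=opt.get("max_iterations", 300),
        rel_tolerance=opt.get("rel_tolerance", 1e-6),
        seed=raw.get("seed", 0),
        output_dir=Path(raw.get("output_dir", "out")),
    )
    return cfg


def _provenance(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed, "version": __version__}


def _write_provenance(cfg: RunConfig, out: Path, stage: str, extra: dict | None = None) -> None:
    payload = _provenance(cfg) | {"stage": stage} | (extra or {})
    (out / f"provenance_{stage}.json").write_text(json.dumps(payload, indent=2) + "\n")


def run_pipeline(cfg: RunConfig, write_artifacts: bool = True):
    """Execute phantom -> spots -> beamlets -> influence -> optimize ->
    normalize -> evaluate; returns a dict of in-memory results."""
    cfg.validate()
    out = Path(cfg.output_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "phantom"
    try:
        t0 = time.perf_counter()
        phantom, structures = make_planning_case(
            cfg.template, cfg.scenario, voxel_size_cm=cfg.voxel_size_cm
        )
        missing = [
            o.structure for o in cfg.objectives if o.structure not in structures
        ]
        if missing:
            raise ValueError(f"objectives reference unknown structures: {missing}")
        results["phantom"], results["structures"] = phantom, structures
        if write_artifacts:
            write_volume(phantom, out / "density.nii")
            for name, mask in structures.masks.items():
                write_volume(mask, out / f"mask_{name}.nii", grid=phantom.grid)
            cfg.template.to_json(out / "template.json")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "spots"
        t0 = time.perf_counter()
        lattice = generate_diamond_grid(
            structures["PTV"], phantom.grid, cfg.template.margin_cm, cfg.template.spacing_cm
        )
        results["lattice"] = lattice
        if write_artifacts:
            lattice.to_csv(out / "spots.csv")
            lattice.to_json(out / "spots.json")
        log.info("stage %s: %d spots in %.1fs", stage, len(lattice), time.perf_counter() - t0)

        stage = "beamlets"
        t0 = time.perf_counter()
        catalog = build_catalog(lattice, cfg.beams(), cfg.focal_fwhm_cm)
        influence = compute_influence_matrix(
            phantom, catalog, cfg.transport_config(), cfg.pruning_tau
        )
        results["influence"] = influence
        if write_artifacts:
            influence.save(out / "influence.h5")
            _write_provenance(cfg, out, stage, {"n_beamlets": len(catalog)})
        log.info(
            "stage %s: %d beamlets in %.1fs", stage, len(catalog), time.perf_counter() - t0
        )

        stage = "optimize"
        t0 = time.perf_counter()
        plan = optimize(
            influence,
            cfg.objectives,
            structures,
            OptimizationConfig(cfg.max_iterations, cfg.rel_tolerance, seed=cfg.seed),
        )
        dose = influence.dose(plan.weights)
        scale, dose = normalize_plan(
            dose, structures["PTV"], cfg.template.normalization, cfg.template.prescription_gy
        )
        plan.scale = scale
        plan.weights = plan.weights * scale
        plan.normalization = cfg.template.normalization
        plan.prescription_gy = cfg.template.prescription_gy
        results["plan"], results["dose"] = plan, dose
        if write_artifacts:
            plan.save(out / "plan.json")
            write_volume(dose.astype(np.float32), out / "dose.nii", grid=phantom.grid)
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "evaluate"
        t0 = time.perf_counter()
        metrics = compute_plan_metrics(
            dose, structures, cfg.template.prescription_gy, plan_name=cfg.template.name
        )
        results["metrics"] = metrics
        if write_artifacts:
            metrics.to_json(out / "metrics.json")
            plan_report([metrics]).to_csv(out / "report.csv", index=False)
            _write_provenance(cfg, out, stage)
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return results


def characterize_water(
    out_dir: str | Path,
    energies_mev: tuple[float, ...] = (50.0, 150.0, 250.0),
    focal_lengths_cm: tuple[float, ...] = (10.0, 15.0, 20.0),
    histories: int = 100_000,
    seed: int = 0,
    box_cm: tuple[float, float, float] = (12.0, 20.0, 12.0),
    voxel_cm: float = 0.25,
    lens_to_surface_cm: float = 7.0,
) -> dict[tuple[float, float], object]:
    """Water-box characterization over an energy x focal-length grid, with
    the lens a fixed distance upstream of the box surface.

    ``histories == 0`` is a dry run that writes CSV skeletons only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    phantom, _ = make_water_box(box_cm, voxel_cm)
    surface_y = box_cm[1] / 2
    lens_to_iso = surface_y + lens_to_surface_cm  # beam at 0 deg travels -y
    for e in energies_mev:
        for f in focal_lengths_cm:
            stem = f"water_{e:g}MeV_f{f:g}cm"
            if histories == 0:
                for suffix in ("depth_dose",):
                    p = out_dir / f"{stem}_{suffix}.csv"
                    p.write_text("depth_cm,dose_gy_per_history,rel_uncertainty\n")
                continue
            beam = BeamConfig(0.0, 5.0, lens_to_iso, e)
            spot = beam.lens_center + beam.travel_direction * f
            beamlet = BeamletSpec(beam, tuple(spot), f)
            cfg = TransportConfig(histories, seed=seed)
            res = characterize(beamlet, phantom, cfg)
            res.write_csv(out_dir, stem)
            results[(e, f)] = res
    return results
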