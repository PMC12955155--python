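# fvheeplan

Inverse treatment planning for magnetically **f**ocused **v**ery-**h**igh-**e**nergy
**e**lectron (fVHEE) beams on synthetic voxel phantoms.

A focused electron beamlet converges from a magnetic-lens aperture to a
Gaussian focal spot at depth, producing a dose peak analogous to a proton
Bragg peak. The package implements the full two-stage spot-scanning
workflow:

1. **Beamlet dose calculation** — focal spots are placed on a 3D
   diamond-pattern (hexagonal close-packed) lattice covering the target
   plus a margin, shared across all beam angles; each (beam, spot) beamlet
   is transported with a simplified condensed-history Monte Carlo engine
   (CSDA energy loss + Highland multiple scattering, batch uncertainty)
   into a sparse dose-influence matrix.
2. **Inverse optimization and evaluation** — nonnegative beamlet weights
   are optimized by projected gradient descent against one-sided quadratic
   dose and dose-volume objectives, the plan is normalized (D95 or D50 of
   the PTV to prescription), and evaluated via exact DVHs, Dx%/VxGy,
   homogeneity index and Paddick conformity index.

A Fermi–Eyges analytic model of the lateral beamlet spread serves as an
independent oracle for the Monte Carlo engine, and a characterization
command reproduces water-box depth-dose curves and lateral profiles over
an energy × focal-length grid.

No patient data ship with the package: synthetic phantoms (water boxes and
cylindrical "patients" with spherical PTVs and rod/shell OARs) stand in for
clinical CTs, while the shipped case templates (`B`, `H`, `L1`, `L2`, `P1`,
`P2`, `F`) carry the clinical beam angles, margins, lattice spacings,
prescriptions and normalization modes.

## Command-line usage

```bash
fvheeplan run --config examples/lateral_case.yaml --seed 1   # end-to-end plan
fvheeplan phantom    --config examples/lateral_case.yaml     # phantom + masks (NIfTI)
fvheeplan spots      --config examples/lateral_case.yaml     # diamond lattice (CSV/JSON)
fvheeplan beamlets   --config examples/lateral_case.yaml     # influence matrix (HDF5)
fvheeplan optimize   --config ... --influence out/influence.h5
fvheeplan evaluate   --config ... --dose out/dose.nii
fvheeplan characterize --out characterization --histories 100000
```

`run` writes density/masks/dose volumes (NIfTI or NRRD), the spot lattice,
the influence matrix, the optimized plan with its convergence trace,
DVH metrics and a comparison-ready report, all stamped with the config
hash and seed; every stage can be rerun from the previous stage's saved
artifacts. `--fast` switches to 1e4 histories per beamlet for demo plans
(use 1e6 for characterization-grade dose).

## Conventions

World units are cm, right-handed, origin at the isocenter; x lateral,
+y anterior, z longitudinal; a voxel's world position is its center. At
gantry angle θ the beam travels along (−sin θ, −cos θ, 0). Dose is stored
in Gy per unit beamlet weight (per history); media are water-like, scaled
by mass density.
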