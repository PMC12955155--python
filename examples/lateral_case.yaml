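# Synthetic lateral planning case using the femoral-head-like template
# (46.5 Gy in 10 fractions, D50 normalization), with the beam angles
# overridden to avoid the contralateral rod OAR.
case:
  template: F
  scenario: lateral
  voxel_size_cm: 0.4
  spacing_cm: 0.6        # lattice spacing override for the demo geometry

beams:
  angles_deg: [-30.0, 0.0, 30.0]
  lens_radius_cm: 5.0
  lens_to_iso_cm: 50.0
  focal_fwhm_cm: 1.0

transport:
  histories_per_beamlet: 6000
  step_cm: 0.1
  cutoff_mev: 2.0
  n_batches: 2

pruning_tau: 1.0e-3

objectives:
  - {structure: PTV, kind: uniform, d_ref_gy: 46.5, weight: 100.0}
  - {structure: PTV, kind: min_dose, d_ref_gy: 46.5, weight: 300.0}
  - {structure: contralateral, kind: max_dose, d_ref_gy: 4.65, weight: 30.0}
  - {structure: BODY, kind: max_dose, d_ref_gy: 48.8, weight: 5.0}

optimization:
  max_iterations: 2000
  rel_tolerance: 1.0e-10

seed: 1
output_dir: out/lateral_demo
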