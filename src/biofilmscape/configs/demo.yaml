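# Demo run: a 6 x 6 mm synthetic landscape under the slow-flow condition,
# processed end to end (imaging, forward transects, flow/transport,
# rate fitting, landscape upscaling) at desk-scale problem sizes.
seed: 1
flow: slow
landscape:
  domain_size_mm: [6.0, 6.0]
  pixel_mm: 0.05
oct:
  axial_step_mm: 0.01
hydro:
  nx: 36
  dz_fine_m: 5.0e-5
  width_mm: 4.0
  smooth_sigma_mm: 0.2
transect:
  sigma_conc: 2.0e-3
  inlet_conc: 0.3
fit:
  max_iter: 60
  restarts: 1
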