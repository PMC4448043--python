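# Optrode fiber scenario: 105 um NA-0.22 fiber -> 300 um saline -> cortex
media:
  saline: {refractive_index: 1.34, mu_a: 0.0, mu_s: 0.0, g: 0.0}
  tissue: {refractive_index: 1.36, mu_a: 0.07, mu_s: 11.7, g: 0.88}
geometry:
  regions:
  - {medium: saline, z_lo: -0.3, z_hi: 0.0, r_lo: 0.0, r_hi: .inf}
  - {medium: tissue, z_lo: 0.0, z_hi: 5.0, r_lo: 0.0, r_hi: .inf}
  domain_radius: 5.0
  z_min: -0.3
  z_max: 5.0
  back_plane_radius: 0.0525
  back_plane_policy: absorb
  back_plane_reflectivity: 1.0
source:
  type: fiber
  core_diameter: 0.105
  numerical_aperture: 0.22
  gaussian_sigma: null
  tip: [0.0, 0.0, -0.3]
  medium: saline
  na_reference: medium
  power: 1.1
n_photons: 1000000
seed: 1
transport: {roulette_threshold: 0.0001, roulette_survival: 0.1, step_cap: 100000,
  termination: roulette}
grid: {dr: 0.01, dz: 0.01, r_max: 1.5, z_lo: -0.4, z_hi: 2.0}
analysis_thresholds: [1.0]
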