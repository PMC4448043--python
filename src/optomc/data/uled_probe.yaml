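# uLED probe scenario: 30 um Lambertian pixel -> 100 um sapphire -> cortex
media:
  sapphire: {refractive_index: 1.77, mu_a: 0.0, mu_s: 0.0, g: 0.0}
  saline: {refractive_index: 1.34, mu_a: 0.0, mu_s: 0.0, g: 0.0}
  tissue: {refractive_index: 1.36, mu_a: 0.07, mu_s: 11.7, g: 0.88}
  probe: {refractive_index: 1.77, mu_a: 1000.0, mu_s: 0.0, g: 0.0}
geometry:
  regions:
  - {medium: sapphire, z_lo: -0.1, z_hi: 0.0, r_lo: 0.0, r_hi: 0.075}
  - {medium: tissue, z_lo: -0.1, z_hi: 0.0, r_lo: 0.075, r_hi: .inf}
  - {medium: tissue, z_lo: 0.0, z_hi: 5.0, r_lo: 0.0, r_hi: .inf}
  domain_radius: 5.0
  z_min: -0.1
  z_max: 5.0
  back_plane_radius: 0.075
  back_plane_policy: absorb
  back_plane_reflectivity: 1.0
source:
  type: uled_disc
  diameter: 0.03
  center: [0.0, 0.0, -0.1]
  medium: sapphire
  collimated: false
  power: 1.0
n_photons: 1000000
seed: 1
transport: {roulette_threshold: 0.0001, roulette_survival: 0.1, step_cap: 100000,
  termination: roulette}
grid: {dr: 0.01, dz: 0.01, r_max: 1.5, z_lo: -0.4, z_hi: 2.0}
analysis_thresholds: [1.0]
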