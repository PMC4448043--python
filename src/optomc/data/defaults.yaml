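# Shipped physical defaults. Everything here is overridable from a run
# config; nothing below is hard-coded in the library.
#
# Units: lengths mm, interaction coefficients mm^-1, power mW,
# irradiance mW/mm^2, current mA. Single design wavelength: 450 nm.

media:
  # thinned single-crystal sapphire substrate (handbook value at 450 nm)
  sapphire: {refractive_index: 1.77, mu_a: 0.0, mu_s: 0.0, g: 0.0}
  # physiological saline (handbook value)
  saline: {refractive_index: 1.34, mu_a: 0.0, mu_s: 0.0, g: 0.0}
  # neocortical grey matter optical constants at ~450 nm
  tissue: {refractive_index: 1.36, mu_a: 0.07, mu_s: 11.7, g: 0.88}
  # opaque stand-in for the probe shank body (metal tracks + oxide):
  # photons entering it are absorbed within ~1 um
  probe: {refractive_index: 1.77, mu_a: 1000.0, mu_s: 0.0, g: 0.0}

probe:
  uled_diameter: 0.030        # emitting pixel
  sapphire_thickness: 0.100   # substrate between pixel and tissue
  half_width: 0.075           # probe tip is 150 um wide

fiber:
  core_diameter: 0.105
  numerical_aperture: 0.22
  saline_standoff: 0.300      # fiber tip sits above the cortical surface
  output_power: 1.1           # mW at the tip
  na_reference: medium        # NA cone evaluated in the launch medium

domain:
  radius: 5.0                 # photons beyond are tallied as escaped
  z_max: 5.0

grid: {dr: 0.01, dz: 0.01, r_max: 1.5, z_lo: -0.4, z_hi: 2.0}

transport:
  roulette_threshold: 1.0e-4
  roulette_survival: 0.1
  step_cap: 100000
  termination: roulette       # "threshold" reproduces plain cut-off termination

calibration:
  # bench anchors: drive current (mA) -> irradiance at the probe/tissue
  # interface (mW/mm^2); interpolated piecewise-linearly, never extrapolated
  interface_irradiance:
    - [0.1, 0.5]
    - [4.0, 40.0]
    - [6.0, 52.0]

analysis:
  chr2_threshold: 1.0         # community-standard ChR2 activation fluence rate
  threshold_sweep: {lo: 0.5, hi: 2.0, n: 10}
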