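# Methods

## Model

`optomc` solves the radiative transport problem for light delivered into
neocortex by two device classes — an implantable sapphire-substrate µLED
probe and a surface optical fiber — with a weighted Monte-Carlo photon
random walk, the standard method for turbid biological media.

Photons are launched with statistical weight 1 and moved in discrete steps
between interaction sites. Step lengths are drawn from the Beer–Lambert
exponential by inverse-CDF sampling, `s = −ln(u)/µ_t` with
`µ_t = µ_a + µ_s`. At each collision a fraction `µ_a/µ_t` of the weight is
absorbed (deposited into the absorption tally of the current medium) and the
photon scatters into a new direction drawn from the Henyey–Greenstein phase
function with anisotropy `g`; the azimuth is uniform (unpolarized
transport). At refractive-index boundaries the unpolarized Fresnel
reflectance is evaluated and the photon is reflected or refracted
probabilistically with a single deviate — photon count stays constant, and
total internal reflection (reflectance 1 beyond the critical angle) emerges
naturally. Fluence is scored with a track-length estimator on a cylindrical
(r, z) grid: every traversed segment is split exactly at each voxel
boundary it crosses and each voxel is credited `weight × path length`.
Dividing by `voxel volume × photons launched` and multiplying by the source
power gives fluence rate in mW/mm².

Assumptions: elastic, incoherent, unpolarized transport at a single design
wavelength (450 nm); homogeneous media; axisymmetric geometry. Coherent
effects (thin-film interference in the sapphire) are outside radiative
transport and are not modelled; only incoherent multiple reflection is.

## Geometry and sources

Coordinates: z along the emission axis, z = 0 at the probe/tissue (or
saline/tissue) interface, tissue at z > 0; lengths in mm; all bins
half-open `[lo, hi)`. The domain is a cylinder (default radius 5 mm, depth
5 mm); weight crossing its outer faces is tallied as escaped. The volume is
tiled by axisymmetric annular-slab regions, validated against gaps and
overlaps on a probe lattice at construction.

**µLED probe.** A 30 µm disc at the GaN/sapphire interface emits a
cosine-weighted (Lambertian) hemisphere into a 100 µm sapphire slab
(n = 1.77, transparent), laterally bounded at the 150 µm probe width, with
cortical tissue (n = 1.36, µ_s = 11.7 mm⁻¹, µ_a = 0.07 mm⁻¹, g = 0.88)
beyond the substrate and beside it. The GaN layers (a few µm) are not
modelled as a distinct medium. The reflective p-contact behind the pixel is
by default an absorbing back plane (tallied separately); a specular-mirror
alternative with configurable reflectivity is a config switch — absorbing
is the conservative, parameter-free choice since the contact reflectivity
is not characterised. With a non-zero insertion depth, tissue also fills
the volume above the pixel plane and the shank above the pixel is modelled
as an opaque probe body (n = 1.77, µ_a = 1000 mm⁻¹), i.e. light may reach
shallow cortex only by scattering through tissue; real shank light-piping
is neglected, which is the conservative choice for depth-selectivity
claims.

**Fiber.** A 105 µm core, NA 0.22, standing 300 µm above the tissue in
saline (n = 1.34). Near field: centred 2-D Gaussian over the core,
truncated at the rim, with σ = core radius / 2 by default (≈ 86% of the
untruncated mass inside the core, a typical multimode near field; σ is
configurable since it is rarely specified). Far field: uniform in solid
angle inside the acceptance cone. The cone half-angle is
`arcsin(NA/n_launch)` by default — divergence in saline is physically
reduced by refraction — with an `na_reference: air` switch for the
in-air convention.

Sapphire (n = 1.77) and saline (n = 1.34) are handbook values at 450 nm;
they live in the shipped `defaults.yaml`, not in code, as does every other
physical constant.

## Termination and variance control

Photons terminate when they leave the domain, hit the back plane, or by
Russian roulette once their weight falls below 10⁻⁴ (survival probability
0.1, survivor weight boosted ×10). Roulette is unbiased, so the global
energy balance — launched = absorbed + escaped + back-plane + edge +
capped + roulette net — closes to floating-point precision and is asserted
at < 0.1% on every run. A strict plain-threshold mode (`termination:
threshold`) terminates at the weight threshold instead and tallies the
discarded weight so the balance still closes. A step cap (default 10⁵)
flags pathological walks; capped weight is tallied, never silently dropped.

## Random numbers and reproducibility

Each photon owns a counter-based substream: the splitmix64 finalizer
applied to a Weyl sequence seeded from (run seed, photon index). Results
are therefore reproducible, independent of execution order, and identical —
bit for bit — between the compiled (numba) production kernel and the naive
scalar pure-Python reference engine, which consume the same deviate
sequence and perform the same floating-point operations. One subtlety: when
`cos(φ)` and `sin(φ)` are computed side by side the compiler may fuse them
into a `sincos` whose sine differs from libm's by 1 ulp, so the contract
derives sin from cos via `±sqrt(1−c²)` (statistically exact for a uniform
azimuth). The equivalence oracle asserts zero discrepancy across fates,
tallies, step counts and the full deposited grid.

## Calibration and derived metrics

The probe is driven by current; bench characterisation anchors the map from
drive current to irradiance at the probe/tissue interface (0.1 mA →
0.5 mW/mm², 4 mA → 40 mW/mm², 6 mA → 52 mW/mm²), interpolated
piecewise-linearly and never extrapolated. The table stores interface
irradiance directly rather than deriving it from on-die surface irradiance,
whose ratio to the interface value is strongly current-dependent. Transport
is linear in power, so one unit-power simulation per geometry suffices: the
map is rescaled so its peak first-tissue-bin irradiance matches the
calibrated value for the requested current.

Metrics: **activation volume** — total volume of tissue voxels (voxel
centre in tissue) with fluence rate ≥ threshold; **penetration depth** —
deepest z-bin centre with any above-threshold tissue voxel (−inf sentinel
when none); **interface profile** — the radial fluence row of the first
tissue layer and its half-max diameter, computed as the standard FWHM
(first crossing below half-peak scanning outward from the peak bin,
linearly interpolated between bin centres; the outermost-bin convention is
too coarse because the fluence of a Lambertian disc genuinely peaks on
axis). The ChR2 activation threshold defaults to 1 mW/mm² — the community
standard figure — and every threshold-dependent result carries a 0.5–2
mW/mm² sensitivity sweep rather than trusting one constant.

Default grid: Δr = Δz = 10 µm, r ≤ 1.5 mm, z ∈ [−0.4, 2.0] mm — resolves
the 30 µm source with 3 radial bins at < 10⁶ voxels.

## Verification

* **Beer–Lambert oracle** — collimated pencil beam in a pure absorber;
  on-axis transmitted fraction vs `exp(−µ_a z)` within 3 binomial s.e. at
  10⁶ photons.
* **Energy balance** — residual < 0.1% of launched weight, every run.
* **Sampler moments** — HG mean cosine within 3 s.e. of g; exponential and
  isotropic draws pass Kolmogorov–Smirnov at the 1% level.
* **Fresnel closed forms** — normal-incidence sapphire→tissue reflectance
  ((0.41/3.13)² = 0.017159) and TIR beyond the 50.2° critical angle, to
  1e−12.
* **Engine equivalence** — compiled kernel vs scalar reference, exact.
* **Regression surface** — identical config + seed produces byte-identical
  HDF5 grid files (object timestamps disabled).
* **Diffusion limit (advisory)** — the deep-tissue decay rate vs
  `µ_eff = sqrt(3 µ_a (µ_a + µ_s(1−g)))` = 0.556 mm⁻¹. At these constants
  (albedo 0.994, g = 0.88) the fitted slope over 2–4 mm sits ~10–15% above
  the asymptotic value, as expected of a near-field diffusion comparison;
  the check brackets rather than gates.

## Problem sizes

The headline metrics (activation volume at 4 mA; fiber penetration depth)
are computed at 10⁶ photons — a full run takes about half a minute per
scenario on one core with the compiled kernel. Distributional checks use
10⁵–10⁶ direct draws; the scalar reference engine, ~10³× slower than the
kernel, is exercised at 10²–10³ photons, which is ample for an exact
comparison. Examples default to 2×10⁵ photons for interactive turnaround.

## Known limitations

* Axisymmetric geometry only; the compiled kernel additionally assumes
  emission along +z. Multi-LED probes are handled by superposing
  single-source runs at analysis time.
* No polarization, no wavelength resolution, no fluorescence, no thermal
  modelling.
* The back-plane reflectivity and the fiber near-field σ are not
  device-characterised; both are explicit config parameters with
  conservative defaults.
* Tissue is homogeneous: no vasculature, no layer-dependent optical
  properties, no probe-insertion trauma effects. Published cortical
  constants vary by tens of percent between preparations; absolute
  activation volumes inherit that uncertainty even where the Monte-Carlo
  statistics are much tighter.
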