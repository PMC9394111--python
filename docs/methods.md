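# Methods

## Tissue gas exchange

Every triangular patch of every organ exchanges CO₂ according to the
nonrectangular hyperbola (NRH). The gross rate is the lower root of

    θ·A_g² − (Φ·I + A_max(T))·A_g + Φ·I·A_max(T) = 0,

where `I` is the **absorbed** photosynthetic photon flux density
(µmol photons m⁻² s⁻¹), `Φ` the maximal apparent quantum efficiency of CO₂
fixation (mol CO₂ per mol absorbed photons), and `θ ∈ (0,1)` the convexity.
Net assimilation is `A_g − R_d(T)`. Temperature enters through two
dimensionless quadratic multipliers, one for `A_max_net` and one for `R_d`,
both re-normalised at construction so they equal exactly 1 at 25 °C; the
gross saturated rate is `A_max(T) = A_max_net(T) + R_d(T)`. Tissue
temperature is taken equal to air temperature — there is no leaf energy
balance, matching the use of recorded cuvette/air temperatures for
parameterisation.

Computationally the lower root is evaluated in closed form; the test suite
checks it against `numpy.roots` on 1000 random parameter draws to 1e-10, and
asserts monotonicity in `I` and the bound `0 ≤ A_g ≤ A_max(T)`.

**Units and area basis.** All rates are per unit *total mesh patch area* of
the organ. This matters for nonfoliar tissue: a spikelet is meshed as a
closed box, so roughly a quarter of its area faces the sun at any moment and
a per-total-area saturated rate of ~5 µmol m⁻² s⁻¹ corresponds to a much
higher rate per projected area. Total area is used because the ray tracer
and the hyperbola then share one consistent basis.

### Fitting

- **A–Q curves** record *incident* flux; fitting multiplies by the tissue
  absorptance `1 − K_r − K_t` before applying the NRH, then back-converts
  the fitted rates to 25 °C with the supplied temperature multipliers.
  Bounded trust-region least squares over
  `A_max_net,25 ∈ [0, 50]`, `R_d,25 ∈ [0, 10]`, `Φ ∈ [0, 0.125]`
  (the theoretical quantum-yield ceiling), `θ ∈ [0.05, 0.99]`. Curves with
  no dark point double the `R_d` bound and are flagged; non-convergence is
  flagged, never silent.
- **Temperature tables** are fitted with an unweighted quadratic per series
  and re-normalised exactly at the fitted 25 °C value.
- **Nitrogen responses** are linear maps LNC → each parameter, evaluated
  with clipping to the fitting bounds (clips are logged) over a declared
  LNC domain.
- **Spike two-component inversion.** The de-awned spike is traced in the
  chamber and non-awn parameters fitted to the de-awned A–Q curve; the
  intact spike (awns now shading non-awn tissue) then yields the awn
  parameters from the intact curve; the two fits alternate until the
  maximum relative parameter change is below 1e-4 (cap 50 iterations).
  Because transport is linear in the injected flux, the chamber is traced
  once per mesh at unit total flux and scaled to each set light level.
  Since the de-awned configuration contains no awn tissue, step A is
  independent of the awn estimate and the loop converges on the second
  sweep. Awn area below 1 % of the spike total is declared unidentifiable
  rather than fitted. Awn and non-awn convexities are independent (the
  convexity is weakly identifiable; its recovery tolerance is 10 % where
  the other parameters recover to 2 %).

## Optical properties

Tissue optics derive from nitrogen content by the empirical chain
`SPAD = 9.7·LNC + 7.13`, `chl = 0.0599·e^(0.0493·SPAD)·100` (µg cm⁻²),
`K_r = 0.3605·chl^−0.502`, and for leaves
`K_t = −0.082·ln(chl) + 0.3761` (floored at 0); stem, spikelet and awn
patches are opaque (`K_t = 0`). The transmittance formula is read with the
natural logarithm: at chl ≈ 70 µg cm⁻² it gives K_t ≈ 2.7 % (a plausible
healthy-leaf transmittance) where a base-10 reading would give ≈ 22 %.
Inputs for which `K_r + K_t ≥ 1` are outside the fitted domain and rejected.

## Ray tracing

Forward Monte-Carlo transport over triangle soups in a uniform voxel grid
(cell size ≈ 2× the median patch edge, clamped to ≤ 96 cells per axis),
walked with the Amanatides–Woo DDA, Möller–Trumbore intersection, in numba
kernels. Direct light launches as parallel rays from a stratified grid above
the canopy; diffuse light as cosine-weighted rays from random top positions
(uniform sky radiance). Per-ray weight is set so injected power equals the
horizontal-plane flux times the domain area.

On a hit, the carried weight splits: `1 − K_r − K_t` is absorbed; a
reflected child carries `K_r·w` in a direction sampled from a Beckmann
(Cook–Torrance) half-vector lobe (roughness default 0.3, configurable;
single-lobe energy normalisation, i.e. the lobe shapes directions while the
weight carries the energy); where `K_t > 0` a transmitted child carries
`K_t·w` in a cosine-weighted direction on the far side. Beckmann draws that
land below the horizon fall back to a cosine draw about the normal, which
gives the correct specular limit at roughness → 0 and approaches a cosine
hemisphere at large roughness.

Children below a termination fraction of the primary ray weight (default
5×10⁻⁴ — equivalent to an absolute 1 µmol m⁻² s⁻¹ cutoff under a
2000 µmol m⁻² s⁻¹ sky, kept relative so behaviour is consistent across
light levels) are discarded *and accounted*, so the ledger
`injected = canopy-absorbed + ground-absorbed + escaped + discarded`
closes to machine precision by construction; the acceptance suite verifies
closure within 0.5 % on 60 random scattering scenes.

**Boundaries.** Lateral boundaries are periodic: a small dense domain
behaves as a laterally infinite (closed) canopy. Patches are wrapped into
the domain by centroid at assembly; a patch straddling the boundary
protrudes slightly, a sub-centimetre approximation at the patch scale. A
central-window analysis mode (e.g. the inner 0.4 m × 0.4 m of a larger
canopy) is available for fidelity runs via `TraceSettings.analysis_window`.
The ground at z = 0 absorbs `1 − ρ` and re-emits Lambertian with ρ = 0.10 by
default; it is an implicit plane, not meshed, and its absorption is reported
separately. The chamber mode launches parallel beams from two opposing LED
panels; walls absorb (reported under `escaped`, floor under
`ground_absorbed`). The LED spectrum is not modelled; PPFD is treated as
spectrally flat. Traces are bit-reproducible for a fixed seed via a
counter-based splitmix64/xorshift generator keyed by (seed, ray index),
independent of launch order.

**Validation oracle.** Random horizontal black patches with uniform Poisson
coverage at one-sided area index L intercept a vertical beam with
probability `1 − e^−L`; the tracer matches at L ∈ {0.5, 1, 2, 4} within
±0.01 at 10⁵ rays.

## Architecture

Leaves are ribbons: the midrib polyline integrates an inclination profile
(degrees from vertical vs normalized length) in a vertical plane; cross-ribs
take the local width (profile × max width, zero at the tip) and rotate about
the midrib tangent by the twist profile; triangulation yields 2 patches per
segment. Stems are square-section prism chains; the spike is a thin rachis
prism with closed box spikelet hulls in two alternating ranks and one
3-facet prismatic awn per spikelet, rising ~15° off the rachis. Closed
spikelet hulls make zero transmittance physically consistent. Leaf
attachment azimuths alternate 180° with rank (distichous wheat phyllotaxis).

Canopy assembly places `floor(x/row_spacing) × floor(y/in_row_spacing)`
tillers on the grid; each position draws a library tiller uniformly, a lean
angle uniform on [0, α₀] and an azimuth uniform on [0, 360°), all from one
seeded generator, so re-assembly with the stored seed is bit-identical.

Perturbation operators edit blueprints and rebuild with the original seed:
`scale_height` scales internodes and insertion heights only (leaf and spike
shapes preserved); `straighten_leaves` fixes the inclination at its basal
value; `flatten_leaves` zeroes the twist; `lower_spike` drops the spike base
to the flag-leaf insertion by shortening the top internode;
`remove_spikes` filters spikelet and awn patches in place; plus awn/spike/
spikelet size scalings and planting-density changes.

## Canopy simulation

One trace per weather timestep (dark steps skip tracing), per-patch NRH
evaluation, area-weighted sums per tissue class and organ normalised by the
analysis-region ground area, trapezoidal integration to daily ledgers.
Daily sums integrate the weather file's full span; diurnal outputs
additionally report the 6:00–18:00 window. Night respiration uses the air
temperature at each timestep. LUE is daily gross ÷ daily absorbed light.
The canopy temperature response collects net rates at steps above
1500 µmol m⁻² s⁻¹ (normalised to 1 at 20 °C) and night respiration
(normalised at 10 °C), binning by air temperature; identical light
environments are traced once and reused across temperatures.

## Synthetic data and study conditions

No field data ship with the package; seeded generators stand in for the
measurements:

- **Tiller library.** Truncated-normal draws per growth stage (tillering /
  heading / milking). Magnitudes are plausible wheat: stem heights
  0.16/0.75/0.80 m by stage, flag leaves ~0.20 m × 14 mm, 18-spikelet
  spikes ~9 cm with 6 cm awns, leaf LNC ~3 %, maximal tiller lean 15°
  (a synthetic default — field values vary by cultivar).
- **Weather days.** 10-min cadence by default; sunny days follow the solar
  elevation curve (direct fraction 0.85), cloudy days multiply seeded slow
  dips into it, overcast days are pure diffuse at 30 % flux; temperature is
  a sinusoid peaking at 14:00. Solar position uses the Spencer declination
  series and hour-angle geometry; timestamps are treated as local solar
  time.
- **A–Q curves.** Forward NRH plus seeded Gaussian noise at the measurement
  protocol's light sequences (11 leaf levels 2000…0; 10 spike/stem levels).
- **Tissue parameters** (`DEFAULT_TISSUE_PARAMS`): leaf
  A_max_net,25 = 25 (mid-range of the 20–35 µmol m⁻² s⁻¹ span typical of
  field wheat), spikelet 5 and awn 7 per total area with θ = 0.85 (spike
  tissue saturates under field sun), stem 5; respiration 1.2 / 1.0 / 0.6 /
  0.4 µmol m⁻² s⁻¹ respectively. The photosynthesis temperature multiplier
  peaks at 25 °C (`1 − 0.0014(T−25)²`); the respiration multiplier rises
  monotonically (~2× from 25 to 40 °C). With these defaults a dense heading
  canopy shows nonfoliar tissues absorbing ~43 % of light and producing
  ~34 % of gross photosynthesis with leaf LUE > stem > spike — the regime
  the tissue-resolved model exists to study.
- **Nitrogen-response lines** (`default_nitrogen_response`): A_max_net =
  12·LNC − 12, R_d = 1.0·LNC − 0.8, Φ = 0.012·LNC + 0.008, θ = 0.75, over
  LNC ∈ [1.2, 4.5] % — low-nitrogen leaves are capacity-limited while
  respiration rises linearly, which is what makes the canopy nitrogen
  optimum interior.
- **Noisy-recovery study.** The generating leaf uses R_d,25 = 2.0
  µmol m⁻² s⁻¹: a Cramér–Rao analysis of the 11-level protocol at noise
  σ = 0.2 shows the information content only supports ~5 % median recovery
  of R_d when the true value is ≳ 2 — smaller values make that precision
  unattainable for any estimator, so the study is posed where the protocol
  is informative.

What the generators do **not** emulate: organ-level biological covariance
(e.g. between leaf size and nitrogen), within-organ nitrogen gradients,
measured cultivar geometry, row-orientation effects, and real sky radiance
distributions. Passing tests therefore demonstrate correctness of the
machinery and the direction of canopy-level mechanisms under realistic
magnitudes, not agreement with any particular field canopy.

**Problem sizes.** Scenario runs use a 0.2 m × 0.0594 m periodic domain at
the 20 cm × 0.66 cm planting pattern (9 tillers ≈ 757 m⁻²), 5-tiller
libraries, 2-h weather cadence and 8000 + 4000 rays per step; validation
oracles use 10⁵ rays. These sizes were chosen so a full validation pass
runs in minutes on one CPU while leaving the Monte-Carlo noise well below
the effect sizes being tested (paired seeds cancel most of it).

## Known limitations

- No transpiration or energy balance (tissue temperature = air temperature);
  no stress physiology; no growth or source–sink dynamics.
- Spectrally flat transport: no per-wavelength optics, fluorescence or
  thermal radiation.
- The periodic-wrap approximation at patch scale slightly blurs the domain
  boundary; use the central-window mode when absolute fidelity at the plot
  edge matters.
- The hyperbola is empirical: no Farquhar biochemistry, stomatal
  conductance, or CO₂ response; parameters are only valid near the CO₂ and
  humidity conditions they were fitted at.
- Organ meshes are idealised solids (boxes, prisms); real glume/awn
  micro-geometry is not represented.
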