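# Methods

`qpat` recovers absolute chromophore concentration maps from multispectral
3-D photoacoustic (PA) images by fitting a Monte-Carlo (MC) fluence forward
model to the data. This note records the model, the numerical choices, what
the synthetic experiments emulate, and the package's own design decisions.

## Forward model

A PA image approximates the initial pressure

    p0(r, λ) = Γ(r) H(r, λ) = Γ(r) μa(r, λ) Φ(r, λ),

with Γ the Grüneisen (thermoelastic conversion) parameter, H the absorbed
energy density, μa the absorption coefficient and Φ the fluence per unit
incident pulse energy. Absorption mixes linearly over chromophores,

    μa(r, λ) = Σ_k c_k(r) α_k(λ),

where the c_k are molar concentrations (the water channel is a volume
fraction in [0, 1] and α_water is the absorption coefficient of pure
water), and the Grüneisen parameter carries a linear concentration
dependence

    Γ(r) = Γ_water (1 + Σ_k β_k c_k(r)),

with Γ_water = 0.124 and empirical β_CuSO4 = 0.708 M⁻¹,
β_NiSO4 = 0.325 M⁻¹. Units: lengths in mm, μa in mm⁻¹, α in mm⁻¹ M⁻¹,
Φ in J mm⁻² per J incident; p0 is kept in model units because measured
data are scaled into them by the calibration factor K (below).

## Monte-Carlo light transport

Photon packets are launched collimated (+z) through the sensor plane with
entry positions sampled from the beam-profile distribution (default: a
Gaussian of 13 mm 1/e² diameter, the profile of the fibre-coupled OPO beam
it emulates). Transport uses:

- exact ray-voxel stepping with piecewise-constant optics per voxel;
- continuous weight attenuation exp(−μa ℓ) along each segment, scattering
  free paths sampled from μs; Henyey–Greenstein phase function with the
  phantom's g (0.9 for the milk background);
- a track-length fluence estimator (weight × path length / voxel volume),
  which remains defined as μa → 0 and has lower variance than
  absorption-weighted scoring; the absorbed-energy tally is the exact
  integral of the same segments, so H = μa Φ holds identically;
- Russian roulette below packet weight 1e-4 with survival probability 0.1,
  with explicit bookkeeping so the energy ledger
  (absorbed + exited + roulette residual = launched) closes to machine
  precision;
- unpolarized Fresnel reflection at the z = 0 face for the
  internal/external index step (1.33 water / 1.5 sensor polymer); all
  other faces of the padded domain absorb;
- a water-only padding margin (default 8 voxels laterally and below) so
  backscatter from outside the image volume is represented, mirroring the
  extended-domain convention of the emulated acquisition;
- a counter-based splitmix64 RNG stream per packet derived from the master
  seed, making runs bit-reproducible and independent of batching.

The scattering background follows the milk-dilution fit
μs′(λ) = a (λ/nm)^b with a = 6.65e3, b = −1.317 (≈1 mm⁻¹ at 800 nm) and
μs = μs′/(1−g). Tube interiors default to the same scattering law and tube
walls are not modelled, consistent with the model the package emulates.

Validation oracles: ballistic Beer–Lambert decay (exact for the
continuous-attenuation estimator), energy-ledger closure, and the
diffusion-approximation point-source solution for a pencil beam on a
matched semi-infinite medium (isotropic source at one transport length,
extrapolated boundary at 2D), which the MC matches to a few percent at
3–5 mm depth — well inside the 15 % band expected of the approximation.

## Acoustic model and limited-view correction

The wave solver is a first-order pressure–velocity k-space pseudospectral
scheme for a homogeneous medium (c0 = 1499 m/s, ρ0 = 1000 kg/m³): spectral
derivatives on a spatially staggered grid, the correction factor
κ = sinc(c0|k|dt/2) that makes the homogeneous scheme dispersion-exact
(verified to 0.1 % at 4-voxel wavelengths), CFL ≤ 0.3, and a split-field
PML (default 10 voxels, quartic absorption profile) around the image
volume. Computational grid sizes are rounded up to FFT-friendly lengths;
the slack lies inside the absorbing boundary. Sensors are ideal point-like
omnidirectional detectors; time reversal re-emits the reversed series as a
Dirichlet source on the sensor voxels with the same solver.

Planar detection under-samples the field; reconstructed amplitudes of deep
objects are attenuated several-fold. The correction matrix

    η(r) = (1/N_λ) Σ_λ p0_fw/bw(r, λ) / p0_smooth(r, λ)

divides, per wavelength, a forward-propagate/time-reverse round trip over
the same aperture by its (smoothed, thresholded) input; the measured
images are divided by the wavelength-averaged η. Smoothing is a separable
Hann window applied in the spatial-frequency domain (unit DC gain, so
volume sums are preserved); thresholding raises values below 1/100 of each
wavelength's maximum to that floor *after* smoothing. η is floored at 0.05
to keep the division bounded where the round trip leaves almost nothing.
Because a single η is shared across wavelengths, voxelwise spectral ratios
of the data — and hence concentration ratios — are untouched by the
correction.

## Calibration

A calibrated absorber of known μa(λ) and Γ inside the image volume ties
scanner units to model units. The scaling factor is implemented as the
mean (not the raw double sum) of Γ H0 / p0m over the absorber voxels and
wavelengths, so K = 1 at perfect agreement and K is independent of mask
size; it is recomputed from the current fluence after every iteration. On
synthetic measured data the absorber mask comes from the phantom labels;
`refine_mask_by_intensity` optionally keeps only the bright positive core
(top half by worst-case intensity across wavelengths), emulating the
conservative manual segmentation a measured data set receives and
protecting the calibration from edge voxels corrupted by partial volume
and reconstruction ringing.

## Inversion

The data misfit is the wavelength-mean least-squares functional

    ε = (1/N_λ) Σ_λ ∫ ½ [K p0m − p0]² dΩ,

whose frozen-fluence gradient with respect to each voxel's concentration is

    ∂ε/∂c_k(r) = −(1/N_λ) Σ_λ [K p0m − p0] V_vox
                 [Γ_water β_k H + Γ α_k,λ Φ].

The fluence's own dependence on the concentrations is neglected — the
standard approximation when scattering is known and fixed; the gradient is
verified against frozen-fluence central finite differences to well below
1 %.

Each iteration: fresh-seeded MC fluence at every wavelength (sub-seeds
derived deterministically from the master seed and iteration index, so the
gradient noise is independent across iterations while the whole run stays
reproducible) → forward fields → K → ε and gradients → Adam update →
projection onto [0, bound]. Upper bounds are the sulfate solubilities
(CuSO4 1.28 M, NiSO4 2.36 M) and 1 for the water fraction; the calibrated
absorber's voxels are clamped to its known fill throughout, holding its μa
and Γ fixed. Initialisation is homogeneous water.

Step sizes are preconditioned twice:

- per chromophore, γ_k = γ_Cu (Σ_λ α_Cu c_max,Cu)/(Σ_λ α_k c_max,k) with
  γ_Cu = 0.1, so weakly absorbing chromophores (water) receive
  proportionally larger steps; c_max are the stock concentrations
  (0.28 M Cu, 1.54 M Ni, 1 for water) — rough estimates suffice;
- per voxel, γ_k,scaled(r) = γ_k / (Φ_norm(r) + ε_Φ) with ε_Φ = 1e-4 and
  Φ_norm the wavelength-mean fluence normalised by its spatial maximum
  (the normalisation is a package choice; it is configurable). Steps grow
  where little light arrives, up to a 1/ε_Φ cap. Disabling this scaling
  demonstrably stalls the deep-tube convergence within a fixed budget —
  the ablation is part of the acceptance suite.

Adam uses the canonical defaults (0.9 / 0.999 / 1e-8). Two desk-scale
refinements address the stochastic gradients at reduced photon budgets
(the emulated protocol used 5e6 packets per wavelength and 300 iterations
on a GPU, where the MC noise floor is far lower):

- tail averaging: the returned estimate is the mean of the last N iterates
  (Polyak-style), damping the residual Adam oscillation at the optimum;
- a two-stage photon schedule: coarse gradients (e.g. 2e4 packets/λ) steer
  the early search, and the budget rises (e.g. 8e4) inside the averaging
  window where precision matters.

Both are options of `InversionConfig` (defaults off) and are enabled by
the desk-scale experiment protocols.

## Synthetic experiments and what they show

The nine-tube "published" preset records the emulated acquisition: a
146×145×75 grid at 110 μm pitch, three rows of three 670 μm tubes at
2/4/7 mm depth filled with CuSO4/NiSO4 mixtures whose stock-normalised
ratio R = (c_Ni/1.54)/(c_Ni/1.54 + c_Cu/0.28) spans 0–100 %, the shallow
centre tube acting as the calibrated absorber.

The desk preset scales this to one CPU core: a 36×36×24 grid at 250 μm
pitch with two tubes — the calibrated absorber at 2 mm (R = 50 %) and a
deep target at 4 mm (R = 25 %). The 9×9 mm aperture keeps the
aperture-to-depth ratio of the planar detection geometry (≈2.3) equal to
the reference acquisition's; a smaller aperture over the same depth
exaggerates limited-view crosstalk beyond anything the emulated scanner
produces (spectra of deep tubes are then contaminated by arc artifacts of
shallow ones — the same mechanism the full-scale experiment shows for a
tube lying under a strong arc artifact).

Synthetic "measured" images pass through the full acoustic chain (planar
detection, time reversal) plus additive white Gaussian noise at 20 dB
image SNR, and are scaled by an arbitrary scanner-unit factor so that the
calibration does real work. An inverse-crime mode bypasses acoustics and
noise: data generated by the same optical forward model isolate MC noise
and optimizer convergence, and tube-mean concentrations are then recovered
to within 5 %. In the realistic mode absolute deep-tube concentrations
remain biased low (the η correction restores roughly 80 % of the deep
amplitude here) while the concentration ratio R is recovered to a few
percentage points — reproducing the central robustness-of-R finding.

What the synthetic data do *not* emulate: sensor directivity and frequency
response, speed-of-sound heterogeneity, wavelength-dependent pulse-energy
drift, and real detection-noise statistics. Passing tests therefore
validate the algorithms under the stated physics, not scanner-specific
effects.

## Numerical details and degenerate inputs

- Isotropic voxels; voxel-centre coordinate convention with the sensor
  plane at z = 0 and depth along +z.
- Zero-measured values on the calibration mask, all-zero volumes sent to
  the smoother, tubes outside the grid, overlapping tubes, rank-deficient
  spectra over the chosen wavelengths, and CFL violations all raise
  immediately rather than propagating.
- All stochastic stages consume explicit seeds; two runs with the same
  configuration are bit-identical.
- Problem sizes used by the shipped validation suite: 16³–40³ optical
  grids, 2e4–3e5 photon packets, 32³ acoustic grids, 70-iteration
  inversions; these are the desk-scale study conditions, chosen once as a
  realistic single-core budget.

## Known limitations

- Scattering is assumed known and fixed; recovering μs (e.g. with multiple
  illuminations) is out of scope.
- The Eq.-5-style gradient ignores the fluence's dependence on the
  unknowns; with unknown scattering it would not be adequate.
- The acoustic operator is not part of the inversion forward model, so
  reconstruction artifacts map into recovered concentrations (masked
  background aside), as in the emulated study.
- Water sensitivity is intrinsically low at 688–867 nm; recovered water
  fractions are indicative only, and errors there negligibly affect the
  solutes.
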