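# Methods

This note documents the models behind `dentalcbct`, the defaults and why,
what the synthetic fixtures do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Phantom model

A phantom is a 3-D grid of structure labels plus a parallel grid of
per-tooth instance IDs (anatomical numbering 101–128). Eleven structures
are defined (IDs 0–6 and 8–11; ID 7 is unassigned): air, cranium
cortical/spongiosa, mandible cortical/spongiosa, cervical-spine
cortical/spongiosa, residual head tissue, skin, tooth, and air inside the
body. Each maps to a material row — density (mg/cm³) and weight percent of
H, C, N, O, P, Ca — patterned on ICRP reference-phantom compositions. Two
deliberate literalisms: air density is kept at the tabulated 1 mg/cm³
rather than silently corrected to 1.2, and the printed weight fractions are
kept even though most bone rows sum to 99.2% (the ICRP minor elements Na,
Mg, S, Cl, K are dropped); validation therefore accepts row sums within
±1% of 100.

Voxel pitch is 0.2 mm by default. The toolkit is grid-size agnostic; the
size and pitch always come from the volume header (overridable).

**Library expansion.** Two operations grow a phantom library from one base
phantom:

* `deform_tooth` — per-axis rescale of one tooth's binary mask about its
  centroid, with per-axis factors in (0.5, 2.0), realized as a
  nearest-neighbour pull-back (a voxel belongs to the scaled tooth iff its
  pre-image lies in the original mask). The fill rule for vacated voxels is
  parameter-free: iterative 6-neighbourhood majority vote from non-tooth
  donors, so contractions heal with the surrounding label (bone around
  roots, tissue around crowns). Expansion overwrites any non-tooth label
  but never another tooth. Nearest-neighbour resampling makes the operation
  approximately invertible: on convex fixtures, scale followed by inverse
  scale recovers the mask with Jaccard ≥ 0.9 (tested).
* `vary_densities` — multiplies material densities per structure ID,
  leaving grids and weight fractions untouched. Attenuation is linear in
  density, so this is the cheap axis of image-contrast variation.

**Synthetic jaw fixture.** `build_synthetic_jaw` builds a deterministic
(seeded) geometric stand-in: a soft-tissue block with a skin shell in air, a
mandible slab (cortical shell, spongiosa core), and ellipsoid-crown /
cylinder-root teeth planted along the slab. It is a *fixture*, not anatomy:
it reproduces the label topology, material contrast and per-tooth instance
structure that the pipeline needs, but not tooth morphology, enamel/dentin
substructure, anatomical curvature, or inter-patient variation. Tests
passing on these fixtures validate the imaging and learning machinery, not
anatomical generalization.

## X-ray physics

All computation lives on a 1-keV grid from 10 to 120 keV. The linear
attenuation of a material is `μ(E) = ρ Σ_m w_m (μ/ρ)_m(E)` with per-element
mass attenuation read from a bundled table that keeps the photoelectric /
Compton / Rayleigh decomposition as separate columns (each column already
absorbs the Z·N_A/A electrons-per-gram factor).

The bundled table is generated by an analytic model
(`dentalcbct/_physics_model.py`, regenerated by
`scripts/make_bundled_data.py`):

* Compton — exact free-electron Klein–Nishina cross section × Z. Electron
  binding corrections (percent level for Z ≤ 20 above ~20 keV) are
  neglected.
* Photoelectric — per-element `τ(E) = τ₃₀ (30/E)³`, with τ₃₀ anchored so
  the element's *total* mass attenuation at 30 keV matches standard
  reference values.
* Rayleigh — `C_R Z^2.5/A (30/E)²` with one constant calibrated on liquid
  water at 60 keV.

The resulting totals agree with standard reference tables to within a few
percent over 30–120 keV for H, C, N, O, P, Ca, Al (e.g. water at 60 keV:
0.209 vs 0.206 cm²/g; cortical bone: 0.312 vs 0.315). That accuracy is
ample for realistic beam hardening and material contrast; it is *not* a
dosimetry-grade cross-section library. K-edges do not occur in range for
these elements, so every per-element curve decreases monotonically above
30 keV (tested). Off-grid energies round to the nearest bin with a logged
warning; out-of-range energies are an error — no extrapolation.

**Spectra.** Three tube spectra ship as CSVs: soft-90kVp (2.5 mm Al),
hard-90kVp (6.5 mm Al) and 100kVp (6.5 mm Al), produced by a simplified
tungsten-anode model: Kramers bremsstrahlung `(E_max−E)/E`, tungsten K
lines added only above the 69.5-keV K edge (so only the 100-kVp spectrum
carries them), and aluminium filtration using the bundled Al attenuation.
They are plausible dental-CBCT spectra with the stated kVp and filtration,
not measurements of any particular tube; the CSV format (`energy_keV,
weight`) lets users drop in their own. Monoenergetic test spectra are
synthesized on demand as `mono-<keV>`.

## Forward projection

Because attenuation depends on a voxel only through its structure label,
each ray reduces to a per-label path-length vector: the traversal
accumulates `L[label]`, and the polychromatic sum becomes
`ratio = Σ_E w(E) exp(−L·μ(E))` — one small matrix product per detector
view. Path lengths are exact (incremental parametric / Siddon traversal,
Numba-compiled); the sum of lengths along a ray equals the analytic chord
through the volume bounding box to 1e-6 relative (tested on 1000 random
rays).

Geometry follows a dental CBCT layout: source-to-isocenter 30 cm,
source-to-detector 55 cm, flat detector of 2000 × 1000 pixels at 0.2 mm,
360 projections at 1° — all configurable; the test geometry is scaled
(128 × 64 detector, 60 views). Convention: projection k is at
k·Δθ degrees counterclockwise about +z (viewed from above), source on +x
at angle 0; detector pixels are ideal points sampled at their centres (no
footprint integration, no scattered-photon transport — cross sections enter
attenuation only).

**Noise.** `I* = I + z√I` with `I = I₀·ratio` and z standard normal — the
Gaussian limit of Poisson counting noise; Var(I*) = I (tested to 5% over
10⁴ pixels) and the SNR of the line integrals grows as √I₀ (tested:
√10 ± 10% between I₀ = 10⁴ and 10⁵). Noise is single-shot per stack;
post-noise ratios are floored at 1e-6 before any logarithm, with the
floored-pixel count logged and recorded in metadata.

**Cutoff.** The limited dynamic range of a real detector is emulated by
`max(ratio, c)`, c ∈ (0,1), applied *after* noise (the documented order of
the two optional transforms); idempotent by construction. Typical values:
0.004 and 0.016.

## FDK reconstruction

Standard Feldkamp–Davis–Kress for a circular full scan: cosine weighting
`R/√(R²+u²+v²)` of `y = −ln(ratio)` on the isocenter-scaled detector,
row-wise frequency-domain filtering, and distance-weighted `(R/(R−s))²`
voxel-driven backprojection with bilinear detector interpolation, scaled by
Δβ/2 over 2π (each plane integral is measured twice in a full scan).
Filtering zero-pads each row to the next power of two ≥ 2·cols so the FFT
product is a linear convolution.

The ramp filter is windowed as
`H(ν) = |ν|·[α + (1−α)cos(πν/(γ·ν_N))]` for |ν| ≤ W·ν_N, zero beyond, with
ν_N = 0.5 cycles/sample and defaults α = 0.54 (Hamming-style apodization),
γ = 1.0, W = 0.8. The exact analytic form of the divergent-beam filter
these parameters historically parameterize admits more than one reading;
the realization above sits behind the `ramp_window` interface so an
alternative can be swapped in without touching the FDK chain.

Correctness anchors (all tested): a homogeneous 2-cm cylinder at
monoenergetic 60 keV reconstructs its known μ to within 10% in the core
with a flat radial profile; an all-ones scan reconstructs to ≈ 0; doubling
density doubles the reconstruction (monoenergetic linearity); doubling the
view count reduces RMS error against the ground-truth μ map; contrast
ordering tooth > cortical bone > soft tissue survives reconstruction.

The median post-filter is 2-D 3×3 per axial slice with edge replication
("image" filter semantics); a 3×3×3 variant is available as an option.
Values remain effective linear attenuation in 1/cm; no Hounsfield
conversion.

## Dataset factory

Conditions enumerate as the Cartesian product phantom-variant × density-set
× spectrum × noise × cutoff (phantom slowest, cutoff fastest). The default
grid is 7 phantom variants (base + six single-axis tooth
expansions/contractions at ±15%), 2 density sets, 3 spectra, 3 noise
levels (noise-free, 10⁴, 10⁵) and a single pass-through cutoff slot: 126
conditions; with 27 teeth per phantom and 50 augmentations this enumerates
to 170,100 samples. The same total also factorizes as 252 conditions
(2 cutoffs) × 27 teeth × 25 augmentations; both are expressible through
`ConditionGrid` and neither is asserted as canonical. Which per-axis scales
and density sets produce the "right" 7 variants and 2 sets is a free
choice; the defaults (±15% scale, +5% bone/tooth density) are plausible
within-population variation, and users can supply their own.

Per-tooth crops expand the instance-mask bounding box by per-face margins
drawn uniformly from 2–10 voxels (a default that keeps molar-sized teeth
inside the cube), clip to the volume, and resample to the output cube —
trilinear for images, nearest-neighbour for masks; the mask contains only
the target tooth. Orientation augmentation draws without replacement from
the 48-element group of axis permutations × per-axis flips, identity
first; when the augmentation count exceeds 48 the surplus draws re-sample
crop margins instead, keeping samples distinct. Every sample's manifest
row carries its condition tuple, crop box, seeds and transform, and the
whole corpus regenerates bit-exactly from the global seed (tested).
Generation is resumable per condition shard; failed conditions are marked
in the manifest and the run continues.

## Segmentation

The network is a 3-D U-Net operating on single-channel cubes: per encoder
level a 3×3×3 convolution (batch norm, ReLU) followed by a 3×3×3
convolution with stride 2×2×2 (batch norm, LeakyReLU slope 0.01); a
bottleneck convolution; per decoder level 2×2×2 nearest-neighbour
upsampling, skip concatenation and a 3×3×3 convolution (batch norm, ReLU);
a final 1×1×1 convolution with sigmoid. Binary masks threshold the
probabilities at 0.5, ties to foreground.

The engine underneath is a deliberately minimal numpy implementation with
manual backprop (`dentalcbct.nn`): convolution lowers to one BLAS matmul
via an im2col view, its input gradient scatters back with one vectorized
add per kernel offset, and the analytic gradients are verified against
central differences in the test suite. It runs entirely on CPU; memory for
the im2col buffers makes 128³ inputs at full width impractical on desk
hardware, so desk-scale work uses 32³–64³ crops with 2–3 levels and 8–16
base channels. The full-scale protocol (128³, 4 levels, ~2000 epochs) is
expressible but intended for long runs.

Training: soft-Dice loss, Adam (default 1e-3; the scaled runs use 3e-3),
batch 2 by default, in resampled rounds — each round draws `round_size`
samples from the corpus (defaults 500 drawn, 80% train / 20% validation,
~50 epochs per round, ~2000 epochs total), keeps the best-validation-Dice
state, then redraws. Loss/optimizer/schedule are recorded in the protocol
object and trivially overridable.

Evaluation reports per-sample DSC with mean ± population standard
deviation, grouped by (model, input source) labels.

## Scaled acceptance run

`scripts/acceptance.py` re-computes everything at desk scale: the
combinatorics count; 1000-ray tracer exactness; Beer–Lambert agreement
(<0.5%); noise variance and SNR scaling; cutoff clamping; FDK recovery
(<10%); and a scaled training surrogate — a 64³ two-tooth fixture phantom
(10-voxel crowns) imaged under 4 conditions (base + deformed variant,
noise-free + 10⁵ photons), 90-view reconstruction, 32³ crops with 8
orientation augmentations (64 samples), a 2-level/8-channel U-Net trained
50 epochs, evaluated on a random held-out quarter of the crops.

Two scale effects are worth being explicit about. First, the fixture
crops are boundary-limited: an optimal-threshold oracle on them tops out
near DSC 0.95 (FDK blur, the median filter and crop resampling acting on
~2 mm fixture teeth), and the trained network lands at 0.91–0.95
depending on seed — it saturates the scaled corpus's image quality rather
than the task. Full-scale corpora of large, high-resolution teeth support
higher ceilings. Second, the surrogate's random holdout tests unseen
crops, not unseen teeth or unseen orientations: with two fixture tooth
shapes there is too little diversity to probe shape generalization, and
plain convolutional networks have only weak orientation equivariance (the
suite checks prediction self-consistency under a flip at the DSC > 0.8
level). What the surrogate does establish is that the generated corpus is
learnable end-to-end and that images and masks stay geometrically
consistent through the whole simulate → reconstruct → crop → augment →
train loop.

## Known limitations

* Cross sections and spectra are analytic approximations (few-percent
  accuracy), not reference data; no K-edge materials beyond Z = 20.
* No scatter transport, bowtie filter, detector lag/glare or energy
  response (the cutoff stands in for dynamic range), no short-scan
  weighting, no iterative reconstruction or artifact correction.
* Fixture phantoms are geometric, not anatomical; no enamel/dentin
  substructure, no diseased teeth, no metal inserts.
* The neural engine is CPU-only and memory-hungry at full resolution.
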