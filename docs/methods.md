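# Methods

`protonrv` re-creates, at desk scale, an in-beam proton dose-range
verification system: scintillator tiles around a phantom integrate the
energy deposited by protons scattered out of the beam ("currents"), and a
learned inverse model reconstructs the 3D (or central-slab 2D) dose
distribution — in particular the Bragg-peak position — from those currents,
optionally conditioned on the phantom's density grid (its "CT"). This note
records the model assumptions, the numerical choices, and what the
synthetic studies do and do not demonstrate.

## Forward physics model

**Stopping and range.** Electronic stopping power follows the uncorrected
Bethe–Bloch form, `S = K ρ (Z/A) β⁻² [ln(2 mₑc² β²γ²/I) − β²]`, with
effective (Z, A, I) per material chosen to reproduce tabulated Z/A and mean
excitation energies (water I = 75 eV). Shell and density corrections are
omitted: protons between ~1 and 250 MeV sit far from both regimes, and the
form reproduces tabulated water values to ~1–2 % (150 MeV: 5.44 MeV/cm;
CSDA range at 200 MeV: 26.0 cm). CSDA ranges integrate 1/S from a 1 MeV
cutoff — the same cutoff at which transported protons stop and deposit
their remainder locally. The cutoff sits above the low-energy turnover of
the uncorrected formula for every registry material (relevant for Pb,
I = 823 eV).

**Condensed-history transport.** Protons advance in fixed steps of half the
smallest voxel edge. Per step: Bethe–Bloch mean energy loss with Gaussian
(Bohr) straggling, variance `0.1569 ρ (Z/A) Δx` MeV²; a Highland
multiple-scattering deflection `13.6 MeV/(β c p) √t (1 + 0.038 ln t)`,
`t = Δx/X₀`, applied as two independent transverse kicks; and, with
probability set by the hard-scatter model, one large-angle Rutherford
deflection. Radiation lengths come from Dahl's approximation on the
effective (Z, A). Energy is conserved exactly: every MeV ends in the dose
grid, a detector, or an escaping proton (the energy-ledger test enforces
closure).

**Hard scattering.** The single-scattering cross-section is Rutherford,
`dσ/dΩ = (Z e²/4E)² / sin⁴θ` in the printed convention, with the textbook
`sin⁴(θ/2)` variant available everywhere. Because only the *relative*
cross-section is specified, the absolute rate is one global constant,
calibrated so that ≈0.5 % of 200 MeV protons in water suffer at least one
hard scatter (θ > 2°) over a full stopping track. The angular density over
θ (including the solid-angle factor) is `∝ sinθ·dσ/dΩ`; for the printed
convention this diverges at both 0 and π, so sampling is restricted to
[θ_min, π − θ_min]. Transport defaults to the `sin⁴(θ/2)` convention: with
the printed form half of all deflections are near-180° backscatters (the
density is symmetric about 90°), and no scattered protons reach the lateral
detectors — the measurement principle itself requires the forward-peaked
form.

**Variance reduction (essential at desk scale).** At 3 × 10⁴ protons per
sample, analog sampling detects essentially zero scattered protons (the
large-angle tail is rare, and the E⁻² rate concentrates scatters at track
end where protons cannot escape the phantom). The engine therefore splits
the density: real protons sample only the small-angle branch
(θ < 10°), with their statistical weight multiplied by that branch's true
probability, while weighted *virtual protons* carry the large-angle tail.
Virtuals are spawned at a flat rate per step (default 0.03, importance
sampling in both occurrence and energy) with weight
`(true tail-scatter probability per step)/(spawn rate)`, their polar angle
drawn from a bounded mixture of the true tail density and a uniform
density up to 90°, and they propagate on straight CSDA rays with a 4×
step (no straggling or further scattering — their dose share is ~10⁻³ of
the total). Expectations of dose and currents are unchanged; only their
variance drops, by roughly three orders of magnitude for the currents.
Below 30 MeV (range ≪ any escape path) the tail is sampled analogically,
which keeps the decomposition exact. Per-detector current noise at the
default settings is ~15–25 % relative, comparable to a counting-limited
measurement.

**Detector scoring.** Escaped protons travel in straight lines (air
scattering over the 10 mm standoff is negligible) and the first
10 × 10 mm² tile face crossed absorbs
`min(remaining energy, scintillator stopping power × chord)` — a 3 mm tile
does not stop a fast proton.

## Phantoms, beams, detectors

Axes: x beam, y horizontal, z vertical. Families:

* **A** — water rectangle 36 × 20 × 20 cm (36 cm depth so that the deepest
  220 MeV peak, ~30.5 cm, stays inside), voxels (1.875, 5, 5) mm; pencil
  beam ⌀1 cm, 180–220 MeV, y-shift ±4 cm; 24 tiles per side on the two y
  faces (48 total), centers 10 mm off the surface, spanning the x extent.
* **B** — family A plus an air slab spanning the y–z cross-section:
  thickness uniform 1–5 cm, center uniform over the middle 80 % of x
  (so it sometimes intersects the Bragg peak); 24 tiles on each of the four
  lateral faces (96).
* **C** — water cylinder r = 20 cm, height 40 cm (axis z), 10 mm voxels,
  containing 3–6 inclusions of hydroxyapatite (3.076 g/cm³) or glass
  (1.8 g/cm³), shapes drawn from {ellipsoid, box, cylinder} with per-axis
  sizes uniform in 5–20 cm, clipped to the cylinder (the printed size range
  is large relative to the phantom; clipping preserves the count). Wobbler
  beam (disc center swept on a circle of 1.5× the beam radius, uniform
  phase per proton), 120–180 MeV, ⌀1–4 cm, shifts ±16 cm in y and z.
  Detector barrel: 36 columns at 10° steps on a cylinder 10 mm outside the
  surface × 12 gap-free rows (10 mm pitch) centered on the beam plane;
  tiles whose centers lie within 2 cm of the beam envelope (an infinite
  cylinder of the beam radius around the beam axis) are removed, and their
  readout entries stay zero in the fixed 36 × 12 current map. Because the
  rows follow the beam plane, the currents carry no absolute-z reference;
  vertical localisation must come from the density grid, and only the
  depth (x) direction is held to a quantitative bound.

## Reconstruction

Targets are stored in the evaluation's own normalized-dose convention
(each sample's target grid scaled to a total of 100 Gy), so the network
solves a shape problem and the evaluation's normalization factor is exactly
one. Family A/B targets are the central x–y slab (two 5 mm z-voxels
summed), rebinned to 10 mm transversely — (192, 20) pixels at
(1.875, 10) mm, keeping full depth resolution where the millimetre bounds
apply. Family C targets are the full 40³ grid at 10 mm.

Models: a current encoder (two dense layers → 256-wide latent for the
rectangular layouts; two stride-2 convolutions over the 36 × 12 current map
for the cylindrical layout), an optional CT encoder (two stride-2 3D
convolutions + dense) whose features are concatenated with the current
latent, and a decoder that maps the latent through a dense layer to a
coarse grid and upsamples ×2 per stage with halving filter counts
(2D: 24→12→6 filters; 3D: 8→4→2), batch norm + LeakyReLU(0.2) after every
convolution except the last, tanh output. Loss is MSE on targets affinely
mapped to (−1, 1) by the training-split dose maximum; currents are scaled
by the training-split 99th percentile (a square-root input compression is
available but off by default — it degraded accuracy in the pilot studies).
Optimizer is Adam, batch size 4, initial learning rate 10⁻³ annealed
cosine-wise to 1/20th; the best-validation-loss parameters are restored
after training. Everything is seeded NumPy; the layers are hand-written
(dense/conv/batch-norm with explicit backward passes, compiled inner loops)
and gradient-checked against finite differences.

Augmentation mirrors train/validation samples about the y midplane
(families A, B) or z midplane (family C): grids flip, the current vector is
permuted by the layout's mirror map (side swap for rectangles;
column k → −k mod 36 or row reversal for the barrel), and recorded beam
shifts change sign. Flips happen after splitting, so no test sample ever
has an augmented twin in training.

## Evaluation

Peak positions are voxel-argmax centers (ties to the smallest flat index);
peak errors are absolute per-axis differences. `delta_dose` is the
root-sum-squared voxel difference after scaling both grids by the factor
normalizing the MC total to 100 Gy. The gamma index is evaluated discretely
at voxel centers (no sub-voxel interpolation), with the dose tolerance
taken globally as a percentage of the normalized reference maximum and no
low-dose threshold by default; the reference is always the MC dose. The
distance-to-agreement search is restricted to offsets within twice the
distance criterion — beyond that the distance term alone gives Γ ≥ 2, so
the restriction provably cannot change the strict γ < 1 decision, and the
tests verify exact equality with an unrestricted brute-force minimization
wherever γ < 2. A voxel passes for γ strictly below 1.

The substitution experiment compares per-detector currents over repeated
seeds with Welch t-tests under Benjamini–Hochberg control at 5 % across
detectors — needed for a defensible "consistent within error" call on the
around-peak substitution. The detector-reduction experiment retrains the
FC-encoder variant on evenly decimated column/row subsets (the barrel's
36→18 and 12→6 halvings), 10 repeats per point by default. The CT ablation
trains both arms on identical splits and seeds.

## Desk-scale study conditions

The quantitative studies run 200 samples (A, B) / 220 samples (C) at
3 × 10⁴ protons each, epochs 70 (A, B) / 20 (C). Sample counts, proton
numbers, epoch counts and the network widths were set by profiling the
forward model and trainer so that one full three-family pass (generation,
training, evaluation) completes in roughly a quarter hour on one CPU
core; they are the package's standing defaults, reproducible from a single
seed.

## What the synthetic studies show — and what they do not

The generator *is* the study design: phantoms, beams and detectors are
drawn from the stated distributions, and the "CT" is the generator's own
density grid, i.e. perfectly registered and noise-free. Passing tests
demonstrate that the pipeline recovers dose distributions from
scattered-proton currents *under its own forward model*: no claim is made
about detector energy resolution or dark current (not modelled), nuclear
interactions and secondary particles (not modelled — currents are
proton-only), patient anatomy, HU-to-density calibration, or motion. The
inverse model is trained and tested on the same forward model, so forward-
model bias cancels; against a different simulator or measurement the
errors would be larger.

## Known limitations

* The voxel-argmax peak is fragile when a prediction develops a secondary
  blob of comparable height; rare samples can contribute large outlier
  peak errors to the means.
* Desk-scale gamma passing rates saturate near the model's voxelwise
  accuracy (~2–4 % of maximum) rather than near the MC noise floor
  (MC-replica gamma at these proton numbers is 100 %); closing the last
  few percent toward the full-scale figures requires roughly an order of
  magnitude more samples and training than the defaults run.
* Family C's vertical (z) localisation is weakly constrained by design
  (see the detector-row note above); its depth error remains the
  meaningful figure.
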