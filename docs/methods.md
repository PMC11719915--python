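# Methods

This note documents the models implemented in `comptoncam`, the
assumptions behind them, the defaults that matter, and what the
synthetic pipeline does and does not establish about real data.

## Physics and coordinate conventions

All positions are in mm in a right-handed frame, all energies in MeV.
The body cylinder (radius 30 mm, height 100 mm, soft tissue) has its
axis along z and is centered at the origin; the canonical imaging
region is the 80 × 80 × 160 mm parallelepiped around it, sampled by
default at 4 mm (20 × 20 × 40 voxels). Voxel values sit at voxel
centers; indices are 0-based in (x, y, z) order.

Constants: mₑc² = 0.511 MeV (fixed, not configurable), prompt-photon
energy 0.478 MeV, capture-reaction Q value 2.79 MeV. The dominant decay
branch leaves Q − Eγ = 2.312 MeV of kinetic energy to the α/⁷Li pair;
the photon is the imaging signal, and the source activity is taken
proportional to the boron concentration.

Kinematics are the exact single-Compton relations. The inverse
(energy → angle) raises a typed `KinematicallyForbiddenError` when the
implied cos θ leaves [−1, 1], so simulator and reconstructor can count
rejections instead of silently clipping. The cone-angle error
propagated from an energy error dE₁ is dθ = mₑc² dE₁ / (sin θ (Eγ −
E₁)²); the implementation asserts agreement with central finite
differences of the inverse kinematics, which pins the formula's
algebraic form. Doppler broadening and electron binding are out of
scope.

## Phantoms

Tumor regions are parametric solids (sphere, ellipsoid, box, spherical
shell, torus ring, multi-sphere) with a rigid pose; a packaged catalog
defines 20 defaults, chosen to span compact, hollow, elongated and
multifocal shapes since only the ring geometry is visually constrained
by precedent — the rest is deliberately generic. Activity is 1 in the
tumor and 1/(T/N) in normal tissue (0 for an infinite ratio), with the
therapeutic premise T/N ≥ 1 enforced. Rototranslations compose poses in
continuous space and the solid is re-voxelized, never resampled, so
repeated transforms are exact; the four augmentation transforms are
fixed configuration entries (not random draws), which keeps the
catalog's 71 → 355 bookkeeping deterministic. Emission positions are
drawn voxel-proportionally with uniform jitter inside the voxel.

## Event simulation

The simulator is an analytic Monte Carlo of the idealized
Compton-then-photoabsorption event topology, not a general particle
transport:

- isotropic monoenergetic 478 keV emission from the activity map;
- free path through the CZT crystal set sampled exponentially with a
  configurable mean free path (default 15 mm, an order-of-magnitude
  value for ~0.5 MeV photons in CZT); chords through all intersected
  crystals are concatenated, which is exact for one uniform
  attenuation coefficient;
- at the first interaction, Compton scattering with probability
  `p_compton` (default 0.8); photoabsorption there aborts the event
  (no cone). The scattering angle is drawn from the Klein–Nishina
  distribution by rejection sampling;
- the scattered photon is transported once more; any interaction is a
  forced full-energy photoabsorption. Same-crystal sequences are kept
  only if the two points are ≥ 1 mm apart (a position-resolution
  surrogate);
- energies are exact by default; optional Gaussian smearing (per
  deposit) makes the 0.470–0.485 MeV total-energy window selective.

Multiple scattering, partial-deposit escape, absorber-first
mis-ordering, neutron physics and structural-boron background are
deliberately not modelled. Consequences: simulated events are exactly
window-compatible when unsmeared, every cone is kinematically
consistent with its true emission point to numerical precision (the
test suite exploits this), and detection efficiency (~0.6% for the
four-module layout at 60 mm) is only an order-of-magnitude match to a
full transport simulation. The detector geometries — one module of
four 20 × 20 × 5 mm crystals with its front face 60 mm from the axis,
and the four-module arrangement (±60° rotations plus ±10 mm axial
translations of the original) — are constructed exactly.

## List-mode MLEM

The system-model element for event d and voxel b is a Gaussian in the
angular distance δ of the voxel from the event's cone surface times an
inverse-square distance factor, truncated at `cutoff` σ (default 3)
and row-normalized to unit sum. The exact matched-physics system
matrix is not reproduced here; the Gaussian cone-surface kernel is the
standard practical choice and all reconstruction statements in this
package are made under it. The width σ defaults to each event's
propagated angular uncertainty at a 5 keV energy-resolution surrogate,
clipped to [10⁻³, 0.5] rad with a 0.05 rad fallback at degenerate
angles; a single global σ can be set instead. Row normalization makes
each row a conditional density over voxels: it stabilizes the scale of
the update denominator and affects only absolute, not relative,
intensities.

Sensitivity is uniform by default (the small-detector limit); a
Monte-Carlo solid-angle mode estimates the fraction of isotropic
directions from each voxel that meet any crystal, floor-clamped at
10⁻⁶ so the EM division stays defined. The reconstruction mask is the
body cylinder dilated by one voxel; outside voxels are frozen at zero.
Events whose cone misses the mask, or whose kinematics are forbidden,
are dropped and counted; an event whose forward projection vanishes at
some iteration is skipped for that iteration and counted. The
multiplicative update preserves non-negativity; the tracked list-mode
Poisson log-likelihood is checked non-decreasing in tests. A dense
binned-mode implementation of the same EM update serves as an
equivalence oracle: with singleton bins, unit counts and sensitivity
equal to the column sums it coincides with the list-mode iterate to
float precision. Iterations 10 and 60 are the canonical
(input, label) snapshot pair for network training.

At desk-scale event counts (10³–10⁴ per phantom) iterating longer
sharpens structure — the reconstructed mass fraction inside the true
tumor region rises from iteration 10 to 60 — while voxel-wise
agreement with the ground-truth activity map can worsen, the familiar
EM noise amplification. Point-like and compact sources localize
essentially exactly; low-contrast extended sources over a warm
background (e.g. a ring at T/N = 4:1, where ~85% of emissions come
from normal tissue) are at the edge of what these event counts
support. None of this affects the supervised chain, whose labels are
iteration-60 reconstructions rather than ground truth: the noise that
grows with iterations is part of what the networks learn to remove.

## Framelet operators

All pooling is stride-2 with the orthonormal convention: average
pooling is the block mean scaled by 2^(d/2), so analysis rows are
orthonormal, unpooling is the exact adjoint, and ΦΦ⊤ is an orthogonal
projection. Under this convention every frame identity used by the
networks holds exactly: the dual-frame synthesis (I − ΦΦ⊤/2)·bypass +
Φ·coarse/2 inverts the extended decomposition; cond(I + ΦΦ⊤) = 2 on
every shape (spectrum {1, 2}); and the separable 3D Haar bank (tensor
products of (1, ±1)/√2) gives 8 orthonormal subbands with Parseval
energy preservation. Whether a reference implementation would use
orthonormal or plain averaging is not determinable from architecture
diagrams alone; both conventions are provided (`orthonormal=False`
gives plain block means), and the frame identities are verified under
the orthonormal one, which is the package's working convention. Odd
spatial sizes raise an error pointing at the reflect-padding helper —
never silent cropping.

## Networks

All variants are residual: output = input + n_θ(input), computed in
normalized [0, 1] intensity space with a linear output layer (residual
corrections may be negative; predictions are clamped to ≥ 0 before
metrics). The final convolution is zero-initialized by default, so an
untrained network is exactly the identity — a useful baseline and a
structural test. Channel widths and per-level depths are not dictated
by the architecture family; defaults are base 8 channels doubling per
level, two 3×3×3 conv + batch-norm + ReLU units per stage, two levels,
all configurable. Batch normalization sits between convolution and
ReLU; with batch size 1 it is per-channel spatial normalization with
running statistics for evaluation mode.

The variants differ only in the resolution-halving and merge
operators: concatenation skips with average pool/unpool (standard);
the fixed dual-frame synthesis applied channel-wise (dual-frame); Haar
analysis with the low-pass subband descending a level and a learnable
weighted sum of nine tensors — the eight per-subband syntheses plus
the bypass — as the merge (tight-frame), i.e. 9 scalars per merge
point instead of a concatenation convolution. Merge weights initialize
at 1, which makes the initial merge "bypass + exact synthesis".

The whole stack (im2col 3D convolution, batch-norm, the framelet
operators and their adjoints, ADAM) is implemented directly in numpy
with hand-derived gradients, verified against central finite
differences for all three variants. This keeps the package
dependency-light and is entirely adequate for desk-scale volumes;
training at clinically realistic resolutions would require a GPU
framework and is a known limitation.

## Dataset, training, metrics

Noise augmentation adds i.i.d. Gaussian noise to the *input* only,
with σ = (max − min)/{16, 20, 30, 40} by level; the 41 noisy variants
cycle through the levels (11/10/10/10), a near-uniform deterministic
choice. Noisy inputs are clamped at zero by default (intensities are
activities); a flag disables clamping for literal unclamped noise.
Splits are assigned to whole samples — 265/30/60 of the 355 at full
scale, the unique sample-level grouping consistent with image totals
of 11,130/1,260/2,520 under 42 images per sample (the nominal 70:10:20
is approximate) — optionally stratified on geometry kind by systematic
stratification (within-class rank-fraction ordering), with the seed
recorded in the manifest. Stratification uses geometry kind rather
than concentration ratio because kind dominates the image structure
the networks must learn.

Training is ADAM at learning rate 0.001, batch size 1, NMSE loss, no
early stopping; the epoch with the lowest validation mean NMSE is
retained. All randomness (initialization, shuffling, noise) descends
from one recorded master seed.

Metrics: NMSE = ‖f* − f̂‖²/‖f*‖²; PSNR = 10 log₁₀(‖f*‖∞²/MSE) with the
peak taken as the maximum absolute voxel value (+∞ sentinel for
identical images); SSIM with global volume statistics and stabilizers
c₁ = (0.01 L)², c₂ = (0.03 L)² on the label's data range L — the
global form matches the metric's defining expression, and a 7³
uniform-window variant is available (cross-checked against
scikit-image). Metrics are computed on normalized volumes, matching
the training normalization.

## Desk-scale problem sizes

The shipped defaults are sized for a single CPU: 20 × 20 × 40 (4 mm)
reconstruction grids, 10⁵–10⁶ simulated gammas per phantom (10³–10⁴
accepted events), 16 × 16 × 32 training volumes, ~10 samples × 6 image
variants per demo dataset, networks of a few thousand parameters, and
a handful of epochs. These sizes demonstrate every mechanism —
localization, EM monotonicity, frame identities, learning above the
identity baseline — but deliberately do not reproduce large-scale
training outcomes: relative rankings among the three variants at desk
scale are recorded as observations, not claims. What the passing tests
show about real data is correspondingly limited: they validate the
algorithms and their contracts, not detector realism (no Doppler, no
multiple scattering, no background) and not full-scale network
performance.

## Numerical choices

- Ray-box intersections use the slab method with explicit handling of
  axis-parallel rays; interaction points are nudged 10⁻⁹ mm forward
  before re-transport to avoid self-intersection at boundaries.
- Klein–Nishina sampling bounds the rejection envelope by the density
  maximum on a 4001-point cos θ grid (the density is smooth; the bound
  is inflated by 10⁻⁴).
- Near θ = 0 or π the arccos conditioning limits the energy↔angle
  round trip to ~10⁻⁷ rad absolute; away from the endpoints it is
  better than 10⁻¹² relative, and the error-propagation formula is
  singular at the endpoints by construction (typed error).
- MLEM zero-denominators, empty rows and forbidden events are counted,
  never silently imputed; an empty event list returns the
  initialization unchanged.
- The condition-number computation symmetrizes the assembled operator
  against round-off before the eigendecomposition and is restricted to
  small shapes (dense assembly).
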