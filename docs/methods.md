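# Methods

`mthelix` re-implements, at desk scale and on synthetic data with known
ground truth, the computational workflow used to solve kinesin-13-decorated
microtubule structures by helical single-particle cryo-EM: protofilament-type
classification, filament-axis refinement, gold-standard reconstruction with
helical symmetry, FSC-based resolution estimation and post-processing, 2D
classification of curved-protofilament rings, and screw-axis decomposition
of tubulin curvature. This note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## Geometry model

**Lattice.** A microtubule is modelled as a seamless helical lattice of
alpha/beta-tubulin dimers on 11-16 protofilaments. The asymmetric unit is
one dimer (plus an optional kinesin motor-domain density); successive units
along the 1-start helix are related by the per-unit screw
`(twist_deg, rise_A)`. For the 15R kinesin-decorated lattice the defaults
are twist 168.083 deg and rise 5.50 A (the curved-complex variant uses
168.089 deg / 5.57 A). Defaults not determined by those screws are the
canonical tubulin dimensions: monomer spacing 40.95 A along a
protofilament and lattice radius 110 A; both are plain config parameters.
The B-lattice seam is not modelled — no implemented computation uses it.

**Subunits.** Each monomer is a rigid cluster of six non-coplanar,
chirality-bearing pseudo-atoms (~20 A footprint) so that least-squares
superposition between subunits is well-posed and recovers inter-subunit
transforms exactly. Beta-tubulin carries 1.3x the alpha mass weighting;
this gives the density a per-dimer periodicity (as alpha/beta contrast does
in real maps) without moving any coordinate, so every geometric measurement
is unaffected.

**Curved protofilaments.** Rings and spirals place monomer centres on a
helix of per-dimer rotation theta and per-dimer rise (zero for closed
planar rings), with the intra-dimer curvature split evenly between the two
monomer steps: the published 24 deg/dimer thus reads 12 deg/monomer, and
the curved-complex helical path is 23.82 deg and 11.1 A per dimer. The ring
radius follows from chord geometry, `r = spacing / (2 sin(theta/4))`
(~196 A at 24 deg/dimer). Kinesin decoration places one motor cluster per
decorated dimer 38 A outward of the tubulin annulus, either on every dimer
or on every other dimer (the "skipping" pattern).

**Screw decomposition.** A rigid transform `x -> Rx + t` is decomposed into
a rotation angle in [0, 180] deg about a unit axis (handedness carried by
the axis sign), the translation component along the axis (rise), and the
perpendicular component (shear, >= 0). A `shear_dir` unit vector is kept so
composition is exactly invertible (round-trip < 1e-8 on random transforms).
For all constructed lattices and spirals the measured shear is numerically
zero; rotations below 1e-9 deg return the translation direction as the axis.

## Imaging conventions

Euler angles are ZYZ intrinsic, `R = Rz(phi) Ry(theta) Rz(psi)`; a
projection integrates the volume along `R z`, and psi is the in-plane
rotation of the projection. All real-space rotations/shifts use linear (or,
where noted, cubic/quintic spline) interpolation; pure translations are
exact Fourier phase ramps. The working geometry is 4 A/pixel with 64-96 px
boxes throughout — the scale the original classification stage used — so
Nyquist is 8 A and every benchmark is interpreted against that ceiling.

Rendering sums per-atom isotropic Gaussians (sigma = 1 voxel by default)
whose discrete sums equal the atom weights, so the grid total equals the
model weight exactly and rendering is linear in the model.

Alignment normalizes images to zero mean / unit variance inside a circular
support, then searches in-plane rotations exhaustively (step 2 deg by
default) with FFT cross-correlation over translations clipped at +-5 px;
both the rotation and the translation peak are refined by one-dimensional
parabolas. Ties break deterministically: lowest reference index, then
smallest rotation.

## Synthetic data

The simulator is the ground-truth authority and deliberately shares no code
with the imaging path it validates: images are formed by *analytic* 2D
splatting of projected pseudo-atom positions (the exact line integral of
the 3D Gaussian kernel), while pipeline references go through 3D rendering
plus numerical projection.

Per filament, segments are cut every 82 A (about 15 helical rises) along
the axis; each segment's exact orientation relative to the canonical model
frame is recorded in the manifest: translating a filament by `s` along its
axis equals rotating the reference by `-round(s/rise)` twists, with the
sub-rise remainder appearing as an axial image shift. Picked-coordinate
error is modelled as a smooth sinusoid (2 px amplitude, 2500 A wavelength)
plus 0.5 px white jitter, mimicking manual picking. Noise is additive white
Gaussian with SNR defined as signal variance over noise variance inside the
particle support circle. An optional CTF applies the standard weak-phase
transfer `-(sqrt(1-A^2) sin chi + A cos chi)` with 300 kV, Cs 2.7 mm,
amplitude contrast 0.07 and underfocus defaulting to the 1.3-2.2 um range
of the source data collection; phase flipping is the implemented correction.
CTF is off in the benchmarks, which is also where the accuracy contracts are
defined.

What the simulator does *not* emulate: structured ice/solvent background,
detector MTF, beam-induced motion, lattice defects and seam effects,
flexible conformational heterogeneity. Passing benchmarks therefore show
the algorithms are correct and self-consistent at realistic SNR, not that
real micrographs of this quality would reach the same numbers.

## Pipeline stages

**Protofilament-type classification.** Model references for each candidate
type (11-16 pf, R/L) are rendered at 4 A/voxel, low-passed to 15 A, and
projected over the azimuth (200/type at full scale; the benchmarks use 8,
which the slow azimuthal variation of filament projections makes
sufficient). Segments are matched by exhaustive rotation x translation
correlation; filaments are called by plurality vote (ties excluded), and
only runs of at least 10 successive target-type segments are retained. A
second classification pass against projections of an experimental
reconstruction is available (`references_from_volume`). At SNR 0.2 the
per-segment accuracy on the 300-segment 15R/14R/13L benchmark exceeds 95%.

**Axis refinement.** Picked coordinates are fitted per lateral coordinate
by a quadratic polynomial — the declared reading of "maximum degree of
freedom 2" — against the principal-direction parameter, resampled every
82 A, and re-centred for 4 cycles by translation-only alignment of 15 A
low-passed boxes against reference projections rotated to the local tangent
(both filament polarities tried); only the perpendicular shift component is
kept. The stated sampling interval appears in the source description once
as 82 A and once as 82 nm; 82 A (= 15 x 5.5 A rise) is used, and the value
is config-overridable. On the standard perturbed track the residual to the
true axis falls below 0.5 px.

**Reconstruction.** Back-projection inserts each image's centred 2D
transform as a central slice at its ZYZ orientation, with 2x Fourier
oversampling, trilinear spreading, per-voxel weight normalization and
enforced Friedel symmetry. Helical symmetrization averages each voxel over
every screw power that maps it into the central 80% of the box; restricting
sources to that window makes the operation idempotent there (< 1e-3 of map
max on band-limited maps with quintic interpolation; cubic is the faster
in-loop default). Symmetry estimation maximizes the real-space correlation
between the central region and its screw-transformed copy over a
twist x rise grid with separable parabolic refinement and a bounded simplex
polish; confidence is the peak's margin over the landscape median
(featureless maps are flagged below 0.1). Recovery accuracy on synthetic
volumes is ~0.003 deg in twist and ~0.013 A in rise — well inside the
0.05 deg / 0.02 A targets.

**Gold standard.** The data are split into halves by filament half, each
half started from its own phase-randomized (beyond 20 A) copy of the
initial model, and refined completely independently: project the current
reference over the azimuth (restricted out-of-plane by construction of the
filament geometry), align each segment with the in-plane search windowed
+-6 deg around the axis direction, back-project, symmetrize, and low-pass
the next reference to the resolution estimated from the half's two quarter
sets (alternating segments). The data entering alignment are limited to
10 A then 8 A. Sub-grid azimuth refinement (parabola over neighbouring
references) matters: at the 110 A lattice radius a 3 deg azimuth
quantization is a 6 A smear. Refinement stops when the quarter-set
resolution stops improving or worsens twice (best round kept). Half-map
volumes carry a `half_set` tag and the final FSC refuses two volumes with
the same tag. On noiseless desk-scale data (100 segments/half) the
half-to-half FSC 0.143 reaches the Nyquist limit.

**Post-processing.** The solvent mask follows the published recipe: 12 A
low-pass, threshold, 2 px dilation, 5 px raised-cosine edge. The threshold
value itself is unstated in the source description; 0.1 x max is this
package's declared default. Sharpening multiplies amplitudes by
`exp(-B s^2 / 4)` (the source maps used B of -130, -100 and -20 A^2).
Region-masked FSC stands in for sliding-kernel local resolution — a stated
simplification of scope.

**Rings.** Ring particles are masked at 540 A diameter and classified by
iterative align / reassign / average rounds with per-round re-centring by
the inverse alignment transform. The in-plane search spans one ring period
(~30 deg) — rings are nearly invariant under rotation by 360/n, so this
loses nothing while saving an order of magnitude. Classes are kept only if
the mean annulus intensity at the detected ring radius exceeds 2x the
image's robust scale — an automated surrogate (declared, not derived) for
what was originally a visual selection of "distinct tubulin rings". Dimer
counting takes the dominant angular harmonic in [10, 20] on the tubulin
annulus; the count is undetermined unless the harmonic beats the runner-up
by 2.0x (calibrated so white noise false-positives are below 1%).
Decoration is called from two-dimer sub-particles centred on inter-dimer
interfaces (the midpoint of adjacent dimer centres, masked at 176 A): the
two flanking dimer-centre sites on the kinesin annulus are probed per
member particle, and two occupied sites means one motor per dimer, one
means the skipping pattern. Note the tubulin harmonic peaks on the heavier
beta monomers, a quarter dimer-period away from the kinesin sites. On the
mixed 13/14/15 benchmark at SNR 0.3 class purity is >= 95% and noiseless
decoration calls are exact.

## Numerical choices and degenerate inputs

- Resolution is the first downward FSC threshold crossing with linear
  interpolation between shells; a curve that never crosses reports Nyquist.
- `estimate_symmetry` requires the search ranges to bracket one optimum;
  the simplex polish is clamped to the ranges.
- Rise below half a voxel refuses to symmetrize (undersampled).
- A rotation angle of ~0 in screw decomposition returns the translation
  direction as the axis with zero shear.
- Every stochastic function takes a seed or Generator; the filament/ring
  simulators split geometry and noise into separate spawned streams so the
  same seed yields the same underlying particles with or without noise.
- Alignment scores are correlation-like but clipped to [-1, 1]; rotation
  by interpolation can nudge them slightly, and the dimer-count confidence
  likewise moves a few percent under resampling (the count itself is
  rotation-invariant).

## Known limitations

- All benchmarks live at 4 A/pixel; nothing here demonstrates behaviour at
  the ~1 A/pixel scale of real acquisitions.
- The reconstruction refines no CTF parameters and ignores the Ewald
  sphere; the seam-free lattice model means no seam-aware processing.
- Half-map frame agreement relies on the shared low-resolution anchor of
  the phase-randomized starting models; with very few segments per half the
  two refinements can settle into slightly different frames and the
  gold-standard FSC honestly reports the resulting loss.
- The per-subunit RMSD between straight and curved tubulin against
  deposited coordinates requires downloading those models; the offline
  suite exercises the same code path on synthetic perturbations, for which
  a 6-point subunit absorbs rigid degrees of freedom and the expected RMSD
  of an iid sigma-displacement is sigma*sqrt(2) rather than sigma*sqrt(3).
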