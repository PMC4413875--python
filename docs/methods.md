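# Methods

This note documents the models, parameter choices and numerical decisions
behind crystomo, in the spirit of a methods section a maintainer can audit.
Everything quantitative stated here is computed by the test suite or the
acceptance script at run time.

## The synthetic specimen

The generator emulates a 2D membrane crystal of a large rotary ATPase
imaged by single-axis cryo-electron tomography.

**Phantom.** The complex is a set of soft-edged solids: a spherical
catalytic head (diameter 100 Å, centre 150 Å above the membrane midplane),
a central stalk (r = 10 Å) connecting head and rotor ring, a peripheral
stalk (r = 16 Å, offset 40 Å from the axis — the only feature that breaks
rotational symmetry about the long axis), an annular rotor ring
(r = 12–22 Å) spanning the 40 Å bilayer, and the bilayer itself at half the
protein contrast. Edges follow an erf profile with σ = 8 Å: a smooth
contrast model whose power spectrum decays realistically toward ~25–30 Å
rather than ringing like a hard solid, and which behaves well under
trilinear resampling.

**Crystal.** Unit cell a = 179.1 Å, b = 171.4 Å, γ = 94.9°; per cell two
up-face monomers forming a pair (axes tilted θ = 16° from the crystal
normal, tilt azimuths Δφ = 97.93° apart, which by
cos α = cos²θ + sin²θ·cos Δφ makes the intra-pair axis angle exactly 24.0°)
and two down-face monomers obtained from the up rotations by a 180° flip
about x followed by a ρ = 90° in-plane rotation, rotor rings apposed across
the bilayer (30 Å lateral offset along the row direction). The membrane is
a piecewise-planar zigzag whose vertices coincide with the particle rows:
segments alternate at ±κ/2 with κ = 43°, so two monomers meeting at a
vertex imply a dimer angle of 2κ = 86°. θ and κ are independent knobs; the
inclination is defined relative to the crystal-plane *normal* (equivalently
the rotor-ring plane is inclined 16° to the crystal plane). Positional
jitter is 2 Å and angular jitter 1° (1σ) — modest lattice disorder.
Because particles sit *in* the jittered membrane at triangle-wave vertices,
lateral jitter slightly shrinks the expected row-mean kink (to ≈41.5° for
κ = 43°); this is a property of the specimen, not of the estimator.

**Acquisition.** ±60° single-axis series at 1.5° (81 projections), ideal
alignment (no fiducials), no CTF; additive white Gaussian noise with
σ = 8 per projection pixel against a peak projected protein signal of ~15 —
per-pixel SNR below one, chosen once as a realistic desk-scale operating
point that leaves alignment feasible after 60 Å band-limiting while keeping
the half-map agreement noise-limited beyond the 30 Å alignment band.
Reconstruction is R-weighted back-projection (linear interpolation, plain
ramp; an optional low-frequency plateau on the ramp is available but off by
default). The default field of view is 96³ voxels at 6.66 Å — about
3.5 × 3.5 unit cells, ~32 recorded particles.

## Subtomogram averaging

Two half-sets are refined independently through a 60 → 40 → 30 Å schedule
(binned 2×, binned 2×, unbinned) under the stated constraints: out-of-plane
tilt of the reference axis limited to ±45°, azimuth and spin free, per-axis
shifts up to 12 voxels (applied progressively: 3 → 6 → 12 voxels across
stages, because the picks are accurate and a full 12-voxel search at low
resolution invites locks onto packing neighbours). Scores are normalized
cross-correlations over the intersection of the particle's missing-wedge
mask and the (rotated) reference's own Fourier support. Averaging
compensates the wedge by dividing the Fourier sum by the per-voxel count of
contributing wedges (floored at 1).

Design choices that proved necessary on this specimen, all documented here
as the package's own methodology:

- **Single-particle bootstrap reference.** A plain average of unaligned
  one-face boxes converges to an azimuthally chimeric reference (the
  lattice holds the motif at two azimuths); the starting reference is one
  seeded subvolume instead. The same bootstrap seeds both half-sets — a
  common starting model, standard in gold-standard practice — so the two
  half-frames stay mutually aligned. The bootstrap's arbitrary pose is a
  global gauge that cancels out of every geometric readout.
- **Stage-wise search modes.** The 60 Å stage performs a full global
  orientation search (it can see the axis, not the spin); the 40 Å stage
  searches the spin exhaustively around the current axis; the 30 Å stage
  refines locally. The spin search runs in the reference frame so the
  rotated references are shared across the whole stack.
- **Alignment masks and neighbour subtraction.** The reference is masked to
  a cylinder about its axis, cut below the stalk base (the bilayer forms a
  lattice-oriented "tent" there); before the spin stage the current
  (spin-smeared) average, masked to the particle envelope, is pasted at
  every neighbouring pick, wedge-filtered, amplitude-matched and
  subtracted from each box.
- **Face linkage.** The spin gauge can settle independently for the two
  membrane faces; a final step aligns the down-face average onto the
  up-face average over spin and applies the single correction to all down
  particles.

**Known limitation — per-particle spin.** Even with all of the above, the
spin about the long axis of roughly a third of the particles locks onto
lattice-correlated decoys offset by ≈Δφ or ≈ρ: the peripheral stalk is the
only spin carrier (angular width ≈44°, so the spin landscape is flat
elsewhere) and in a tight lattice the residual neighbour correlations are
competitive with it. Isolated, context-free particles recover spin
perfectly, which localizes the failure to the packing context, not the
scoring machinery. Consequently the refined Euler tables are written but
are not used for the packing angles.

## Packing geometry without spin

All reported packing angles are *axis-level* quantities: the spin cancels
from the inclination and the pair angle trivially, and also from the
cross-face interface rotation — with R_d = R_z(ρ)·R_x(180°)·R_u, the
azimuths of the two partner axes alone determine ρ
(ρ = az(axis_down) + az(axis_up); verified exactly in the tests).

Per-particle axes are therefore measured directly from the reconstruction,
the re-insertion logic of the hybrid workflow: the head (soft-ball matched
filter) and the rotor ring (soft-annulus matched filter) are localized
around each picked position — first the head alone (provisional axis from
pick to head), then both in tight windows along that axis; the ring window
is deliberately small (13 Å) because the partner's ring sits only ~30 Å
away. The axis is the unit vector over the ~150 Å ring-to-head baseline; a
collinearity gate (head–pick–ring within 12 Å of a line) rejects captures
of neighbouring particles. On the default noisy reconstruction the
per-particle axis error is ~4–5° (mean), giving a mean inclination within
~1.5° of truth.

From the axes: the crystal plane is fitted to the midpoints of same-face
pairs' mid-membrane anchors (pair midpoints lie on the midplane by
construction, cancelling the zigzag's ±h row alternation); pairs and
interfaces come from mutual/nearest neighbours on those anchors; the
membrane kink is the piecewise-linear zigzag through the per-row mean
anchor heights (the direct density ridge of a near-planar bilayer is
unsampled in a ±60° single-axis reconstruction — both 21.5°-tilted segment
families lie inside the 30° missing cone — so the rows of rings, which the
wedge leaves visible, carry the membrane height instead; the ridge tracer
itself is validated on generator volumes, where it recovers 43 ± 1°); the
head height is read symmetrically across the two faces
(½·(mean up-head z − mean down-head z)) so that the midplane position and
any common localization offset cancel.

**Known bias.** The measured interface rotation carries a systematic
offset of ≈ +9° (99° for a true 90°): the peripheral stalk sits at a fixed
azimuth relative to each axis' lean direction and drags the head
localization by a constant angle, which the sum of partner azimuths picks
up twice. The inclination and pair angle are far less sensitive (the drag
is largely common-mode for them). A stalk-aware localization template did
not remove it at this resolution; the bias is reported rather than
calibrated away.

## Validation

FSC uses 1-voxel shells, no masking of the half-maps; resolution is the
first downward 0.5 crossing (linear interpolation; never-crossing curves
report Nyquist with a flag). Phase randomization beyond 40 Å draws its
random phases from the Fourier transform of a real white-noise field
(exact Hermitian symmetry, amplitudes untouched) and is applied per
subvolume; the final alignment iteration is repeated on the randomized
data and the verdict is "overfit" when the randomized half-map FSC exceeds
3/√n beyond the cutoff on average. The randomized FSC is evaluated over
the jointly wedge-covered Fourier voxels only — voxels no wedge covers are
identically zero in both halves and would fake correlation. The Fermi
filter is 1/(1+exp((k−k_c)/T)) with k in reciprocal pixels, T = 0.002 px⁻¹.

On the default run the FSC(0.5) resolution is ~40 Å — coarser than the
30 Å alignment limit, as it must be for a noise-limited average of ~16
particles per half — and the randomization verdict is clean.

## 2D crystallography

z-slices spanning 426.2 Å (64 layers at 6.66 Å) are summed into a
projection image. Lattice detection windows the image, pads the FFT 4×,
picks significant power-spectrum peaks in a 40–400 Å band, chooses the two
shortest independent reciprocal vectors, verifies that every strong peak
indexes integrally — extending and re-reducing the basis when a peak
reveals a finer sublattice (the two-monomer motif approximates a centred
arrangement, so odd-index reflections are weak) — and refines the basis by
weighted least squares over all indexed peaks. Cells are reported reduced,
a ≥ b, γ obtuse. Recovery on the default tomogram is within ~0.5% and
~0.25°.

Unbending correlates the image with a Gaussian-windowed, lattice-filtered
reference patch (local energy normalization), reads one displacement per
unit cell (accepted only above a correlation significance, so noise images
skip with a warning), removes the affine component (which belongs to the
lattice parameters, not the distortion), interpolates the remainder and
resamples; if the (1,0) peak/background quality would not improve, the
input is returned unchanged (no-op guard). Structure factors are exact
DTFT samples at the reciprocal nodes within 30 Å (phases referred to the
image centre; background from a 3–5 pixel off-peak annulus; snr =
amplitude/background). Maps are p1 Fourier syntheses; the p2 test grid-
searches and locally refines the phase origin minimizing the snr-weighted
deviation of phases from 0°/180°. On the default crystal the p2 residual
stays well above 20°, consistent with merging in p1 — the two monomers per
cell are not related by a twofold at any common origin.

## Problem sizes and determinism

The default field (96³ voxels, ~32 particles, 81 tilts) runs the whole
pipeline in ~4 minutes on one CPU; tests use the same default once (shared
fixture) plus smaller grids for unit checks. All randomness (crystal
jitter, projection noise, half-set split, phase randomization) derives
from one seed via a seed sequence; identical config + seed reproduce
byte-identical reports, which the suite asserts.

## What passing tests do and do not show

The generator omits CTF, dose damage, fiducial alignment errors, membrane
deformability beyond the piecewise-planar zigzag, and realistic molecular
density. Parameter recovery here demonstrates the internal consistency and
the honest error behaviour of the workflow at a desk scale — including
which quantities a missing-wedge reconstruction genuinely supports (axis
geometry, lattice, ring-row heights) and which it does not (per-particle
spin, the direct density ridge of a near-planar membrane, resolution
beyond the noise limit). It does not certify performance on real
micrographs.
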