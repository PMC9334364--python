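# Methods

This note records the physical model, the numerical choices and the design
decisions behind `holotrack`, and what the synthetic benchmark does and does
not demonstrate.

## Optical model

**Scalar coherent optics.** All propagation is scalar and monochromatic
(default vacuum wavelength λ = 0.532 µm in water, n₀ = 1.33). Free-space
steps use the angular-spectrum method: the field's FFT is multiplied by
`exp(i·z·√(k² − kx² − ky²))` with `k = 2π·n₀/λ`; evanescent components
(kx² + ky² > k²) are zeroed outright rather than attenuated — standard,
stable, and irrelevant at the propagation distances used here (≫ λ). The
discrete frequency grid follows from the pixel pitch and grid shape; odd
grid sizes are supported. An optional zero-padding factor guards against
periodic wrap-around of edge fringes (off by default: the simulator and the
tracker share the same discrete transform, so wrap-around is
self-consistent between them).

**Multiple scattering.** Propagation through the bead-filled volume uses a
first-order split-step beam propagation scheme: per slice of thickness dz
(default 1 µm), a thin phase-and-absorption screen
`exp(i·k₀·(n(x,y) − n₀)·dz)` followed by a homogeneous diffraction step.
Sequential screen/diffraction composition captures forward multiple
scattering; backscatter and wide-angle corrections are neglected
(paraxial-ish forward model, adequate at Δn ≤ 0.26). A symmetric half-step
variant was considered and rejected: at these contrasts the first-order
error is negligible, and applying the screen at the slice entrance
partially offsets the sphere's focus displacement (below).

**Scene.** Beads are perfect spheres voxelized by voxel-centre membership;
overlaps resolve last-writer (and are prevented upstream by the trajectory
generator). The rasterized volume is padded axially by one bead radius on
each side of the declared sample volume so spheres centred at its faces
still fit; the remaining distance to the detector is covered by a single
angular-spectrum step. The recorded intensity is
`H = B·(1 + |u|²) + N` with `u` the total propagated field of a unit
incident plane wave, the package's reference recording model.
The `1 + |u|²` form double-counts the unscattered order relative to the
textbook Gabor intensity `|u|²`; both are implemented
(`hologram_model = "literal" | "intensity_only"`, default literal) and
differ only in the relative weight of the quadratic fringe term after
background removal.

**Noise.** The hologram SNR is defined scale-free: `N` is zero-mean white
Gaussian with σ_N = σ_signal / SNR, where σ_signal is the standard
deviation of the noiseless hologram about its mean. SNR = ∞ disables noise
exactly. Negative intensities after noise addition are clipped to zero with
a logged count. No shot noise or quantization is modelled.

**Coordinates.** x runs along columns, y along rows, both in µm from the
top-left pixel centre; z increases from source to detector. Ground-truth
and detected axial positions are *backpropagation distances from the
detector*: a bead at depth s inside a sample of depth z₁ whose exit face
sits z₂ before the detector has z = z₂ + (z₁ − s). All interfaces use µm;
the only pixel-typed quantities are explicitly named (window sizes, areas).

## Default geometry

The defaults model a lens-based in-line system with an effective object-side
pixel of 0.4 µm (e.g. 20× magnification over a ~8 µm camera pixel) on a
500 × 500 grid (200 × 200 µm field of view), recording distance z₂ = 150 µm
and sample depth 110 µm spanned by 121 reconstruction planes (0.92 µm
spacing). Two considerations fix this operating point: the Nyquist-limited
effective NA is λ/(2·n₀·pitch) ≈ 0.5, giving a coherent depth of field of a
few µm — necessary for micrometre-level axial localization (at a 2 µm pixel
the capped NA of 0.1 makes ~±35 µm axial errors unavoidable, verified
empirically) — and the fixed benchmark volume of 10/2270 mm³ then maps to a
~110 µm deep sample, matching a 121-plane stack at ~1 µm spacing. Every
value is overridable per run.

## Detection pipeline choices

* **Background removal**: per-frame division by a Gaussian-smoothed copy
  (σ = image/16 pixels) minus one, or division by the temporal median of the
  sequence. The lowpass mode needs no sequence; the temporal mode cancels
  static artifacts exactly but fails for stationary objects. Default:
  lowpass.
* **Dark volume**: modulus of the backpropagated background-free field.
  Phase or intensity variants were rejected: the modulus of a zero-mean
  field gives the advertised high-contrast dark background.
* **Gradient volume**: *squared* lateral gradient magnitude by central
  differences with replicated borders, per µm. The squared form is kept as
  the working quantity everywhere (detection image, axial weights):
  weighting by the unsquared magnitude measurably drags the axial estimate
  toward the defocus haze (single-bead bias −2.7 µm vs −1.2 µm).
* **Detection image**: `I = M_DV · M_GV` rescaled to [0, 1] by its maximum;
  binarization is local-mean adaptive (window = image/8, offset =
  sensitivity × global std with sensitivity 1.0, minimum area 4 px, holes
  filled). The local mean keeps faint objects detectable next to bright
  ones; the sensitivity default was chosen on crowded noisy scenes, where
  it suppresses noise-floor components (16 → 5 spurious per 100 beads)
  without affecting isolated-bead accuracy.
* **Axial localization**: gradient-weighted mean of the per-pixel GV-argmax
  depths over the object mask — continuous, not snapped to the plane grid.
  Degenerate objects (zero total weight) are dropped, never imputed.
* **Lateral localization**: argmax pixel of DV at the plane nearest the
  object's z (ties toward smaller z; row-major tie-break among pixels). No
  sub-pixel refinement: for spheres the in-focus dark field is a bright rim,
  and the argmax occasionally sits on the rim rather than the centre, which
  bounds worst-case lateral error by the bead radius. Centroid/model-fit
  refinement is deliberately out of scope.
* **EDOF**: per-pixel minimum of DV over z (suppressing twin-image haze)
  with each object's dilated mask (2 px) filled from its own focal plane.
* **Known limitation**: objects overlapping in (x, y) at different depths
  merge into one detection — inherent to projection-based masking.

## Track linking

Frame-to-frame optimal assignment (Hungarian) on the 3D distance from a
constant-velocity prediction (last position + last displacement once a
track holds ≥ 2 points; plain last position before that), with a gate
radius (default 15 µm ≈ 3 bead diameters per frame) and termination after
`max_gap` (default 1) unmatched frames. A pure nearest-neighbour mode is
kept as a comparison fallback; the velocity term is what resolves
crossings of counter-moving particles.

## Benchmark protocol

5 µm beads, n = 1.59 (polystyrene in water), in one fixed sample volume of
10/2270 mm³ — the volume at which 10 beads give 2270 beads/mm³, so
concentration scales with the bead count — over SNR ∈ {∞, 20, 10, 5} ×
counts {10, 25, 50, 100}. Trajectories are reflected Gaussian random walks
(step 1 µm/frame/axis, exact model unspecified upstream and exposed in
config). Detections are matched to truth per frame by optimal assignment
under a 2-diameter gate; only matched pairs enter the pooled RMS, with
missed and spurious counts reported separately. Tests and the acceptance
script run the grid at 2–4 frames per cell with one replicate — enough for
stable pooled RMS at these match counts — and everything is bit-reproducible
from (protocol, seed).

Measured behaviour at these conditions: RMS XY ≈ 0.9–1.2 µm and RMS Z ≈
1.2–2.2 µm across the grid, growing with bead count (fringe crosstalk) and
everywhere well below the bead diameter; detection rates 80–100 %,
decreasing with crowding.

## What the synthetic data does and does not show

The simulator shares its discrete propagator with the tracker, so the
benchmark isolates algorithmic accuracy from model mismatch; real
recordings add aberrations, partial coherence, camera nonlinearity, shot
noise and non-spherical objects, none of which are modelled. Passing the
benchmark therefore demonstrates the pipeline's intrinsic localization and
linking accuracy under controlled multiple-scattering conditions, not
end-to-end performance on experimental data. Worst-case (as opposed to RMS)
localization is bounded by physics, not by sampling: the axial spread
follows the coherent depth of field (~2–3 µm here) plus the transparent
sphere's focus ambiguity, and the lateral worst case is the rim radius —
finer plane spacing or pixel pitch does not shrink either.
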