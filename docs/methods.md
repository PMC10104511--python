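# Methods

`fibremech` quantifies the mechanical interaction between a contractile
cell and a fibrous hydrogel from multi-channel 3D confocal stacks, without
fiducial beads: the fluorescently labeled fiber network is its own
displacement reporter.  This note documents the models, conventions, and
numerical choices behind each stage, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Conventions

Voxel arrays are ordered `(z, y, x)`; every physical computation (distance
transforms, displacement magnitudes, volumes) honors per-axis voxel sizes
in micrometres, defaulting to isotropic 0.57 µm voxels, the geometry of a
typical confocal acquisition for this assay (512×512×~175 voxels covering
roughly 230×230×100 µm³).  Vector quantities are exported with `(x, y, z)`
components in µm; conversion between the two orderings happens in exactly
one place (`fibremech.core`).

Displacement sign: recovered vectors map *relaxed* positions (after
cytochalasin D abolishes actomyosin contraction) to *stressed* positions
(cell pulling), so matrix points around a contracting cell carry vectors
pointing toward the cell.

## Preprocessing

* **Denoising** is penalized least squares: minimise ‖z − y‖² + s·‖Δz‖²
  over the voxel grid.  With DCT-II boundary conditions the solution is a
  per-frequency shrinkage of the DCT coefficients, `ẑ = DCT⁻¹[DCT(y)/(1 +
  s·Λ²)]`, where Λ are the Laplacian eigenvalues — the standard Whittaker
  smoother for gridded images.  The penalty `s` defaults to `"auto"`:
  minimising the generalized cross-validation score over log₁₀ s ∈ [−8, 8].
  The DC term is untouched, so the mean intensity is preserved exactly.
* **Contrast stretching** rescales the [0.1, 99.9] percentile window to
  [0, 1] with clipping; the robust percentiles protect against hot pixels.
  A constant stack maps to zeros with a warning rather than an error.
* **Drift correction** estimates the stage shift by phase correlation on
  the fiber channel only and applies the same correction to every channel.
  Integer mode (default) uses whitened cross-correlation and a circular
  shift — exact for integer circular drifts of any magnitude up to half the
  grid.  Subvoxel mode refines the peak by ×10 Fourier upsampling using the
  plain (unwhitened) cross correlation, which is less biased on
  band-limited images, and applies the correction by trilinear
  interpolation.  Phase correlation assumes a rigid offset; when
  cell-induced deformation pervades the entire (small) field of view the
  peak degrades — in practice drift estimation needs either a field of view
  much larger than the displacement decay length, or small deformations.

## Segmentation

* **Cell / nuclei**: global Otsu threshold, then removal of 26-connected
  components below a physical volume floor (defaults: 100 µm³ for cells,
  30 µm³ for nuclei, both far below a plausible cell at 0.57 µm voxels).
  Otsu makes the mask invariant to affine intensity rescaling.
* **Clumped cells** are split by marker-controlled watershed on the negated
  anisotropy-aware Euclidean distance transform of the cell mask, seeded
  with the nuclei; this is shape-based, so intensity gradients inside the
  clump do not move the split.  One nucleus returns the mask unchanged;
  zero nuclei is an error.
* **Densified polymer**: the threshold is the 99th percentile (linear
  interpolation between order statistics) of the intensities in the outer
  frame of the image — the x–y border band, 10 % of each lateral extent, on
  every z-slice.  The frame is far from the (centred) cell, so it samples
  undensified matrix; recomputing it per stack makes the threshold adapt
  across time points.  The z-faces are not framed: confocal stacks are
  shallow in z and their extreme slices are not background-representative.
  Voxels strictly above threshold are kept, small objects removed, holes
  filled.  Hole filling turns a closed densification shell into a solid
  region whose boundary is the *outer* shell — which is exactly the surface
  the remodeling-range metric is defined against, and which makes
  "densified volume = polymer volume − cell volume" correct as stated.

## Morphometry

* **Inscribed sphere**: centre = argmax of the Euclidean distance transform
  inside the cell mask (ties broken at the lowest `(z, y, x)` index),
  R = that distance.  A single-voxel mask pins the degenerate convention
  R = one voxel (distance to the nearest background voxel centre).
* **Protrusions**: mask voxels farther than 2R (physical distance) from the
  inscribed-sphere centre; 26-connected components; components below 5 µm³
  are discarded as digitisation slivers.  The centre is the natural
  reference point because it is the only point the preceding step defines.
* **Protrusion length** uses the equivalent-ellipsoid convention:
  `2·√(5·λ_max)` with λ_max the largest eigenvalue of the voxel-coordinate
  covariance in physical units.  A uniform solid ellipsoid of semi-axis a
  has coordinate variance a²/5 along that axis, so the formula returns its
  full length exactly; for a uniform cylinder of length L it returns
  L·√(5/3) ≈ 1.29 L.  Empirically, applying it to the *truncated* component
  beyond 2R recovers the full base-to-tip protrusion length within ~15 %
  for slender protrusions of length ≥ 3R, because the inflation of the
  ellipsoid convention roughly offsets the truncation at 2R.
* **Sphericity** is solidity in percent: mask voxel count over the voxel
  count of its convex hull, clipped at 100.  The hull is built over
  surface-voxel centres and voxelised by reducing each (y, x) column to its
  feasible z-interval from the facet inequalities — equal voxel-for-voxel
  to a brute-force all-voxel facet test, but O(facets × slice) instead of
  O(facets × volume).  With the centre convention a digitised ball reports
  ≈ 100 %.

## Displacement recovery

Free-form deformation registration of the stressed fiber image onto the
relaxed one:

* the transform is a cubic B-spline control lattice (default spacing 8
  voxels at the finest level, one coarser level at 16 voxels);
* the similarity is the normalised correlation coefficient (NCC),
  estimated each iteration on a fresh seeded random sample of 20 000 voxel
  positions;
* the optimiser is stochastic gradient ascent with per-parameter adaptive
  step estimation (Adam, base step 0.1 voxel decaying linearly to zero,
  200 iterations per level).  The analytic NCC gradient is back-propagated
  through trilinear image interpolation onto the lattice.

Two numerical safeguards matter.  First, the Adam epsilon is *relative*
(10 % of the lattice-wide RMS gradient): control points in texture-poor
regions see gradients dominated by sampling noise, and an absolute epsilon
would let them random-walk at full step size; the relative epsilon scales
their steps down in proportion to their signal.  For the same reason an
iteration whose sampled NCC is numerically perfect (> 1 − 1e−9, e.g.
identical inputs) skips its update entirely — the residual gradient is
floating-point dust that scale-invariant normalisation would amplify —
which makes identity registration return an exactly zero field.  Second,
registration
fails loudly rather than silently: content-free images raise (correlation
undefined), and so does a net NCC decrease across the finest level.

Because the per-iteration cost is set by the sample count rather than the
volume, a 128³ pair registers in ~30–40 s on one core.  On noiseless
synthetic scenes with radial fields of 1–3 voxel amplitude the median
field RMSE is ≈ 0.3 voxel; identical inputs give an exactly zero field
(zero gradient at every iteration).  The `valid_mask` excludes a one-
control-spacing border where the B-spline support is truncated.

The registered transform maps relaxed to stressed coordinates; the true
warp satisfies `stressed(x) = relaxed(x − u(x))`, whose exact inverse
differs from `u` by ~(∇u)·u — below 0.15 voxel for the amplitudes and
decay lengths at stake — and this inversion error is inside the reported
RMSE.

**Decay profile**: each trusted voxel outside the cell is assigned by its
anisotropy-aware distance to the cell surface to half-open 5 µm bins
[0, 5), [5, 10), …, capped at 150 µm (about the largest cell-surface
distance a 230 µm field of view supports); per-bin mean, population SD and
count are reported, and the binning is bit-identical to a naive per-voxel
loop.

## Remodeling metrics

* **Densified volume** = polymer-mask voxels × voxel volume − cell-mask
  voxels × voxel volume (the literal definition; the full cell volume is
  subtracted, not the overlap), floored at zero with a warning.
* **Remodeling range**: cell-surface voxels are mask voxels with a
  6-neighbour outside; for each, the nearest polymer-boundary voxel
  distance (kd-tree, physical units) gives the distribution; the
  complementary `extent_max` is the farthest densified voxel's distance to
  the cell surface.  Both are emitted because "how close does densification
  sit" and "how far does it reach" answer different questions.
* **Retained fraction** after contraction is abolished: a plateau is
  declared when the last 3 samples (20-min spacing, matching an hour-scale
  relaxation) vary by < 2 % relative spread; the retained fraction is the
  plateau mean over the initial volume, clipped to [0, 1].  Without a
  plateau the last-point ratio is returned with a warning.  The package
  deliberately reports the unambiguous *retained* (plastic) volume
  fraction; the reversible fraction is its complement.

## Rheology

* **Degree of plasticity** of a creep–recovery test: residual strain after
  recovery over the maximum strain at the end of creep.  The residual is
  the mean over the final 10 % of the recovery phase (robust to noise); a
  tail whose relative slope exceeds 1 %/min warns that equilibrium was not
  reached.  The ratio is clipped to [0, 1] with a warning, since noise can
  push a fully-recovered trace marginally negative.
* **Stiffening decomposition** of a live-cell G′(t) trace with a cytoD
  event: plateau = mean G′ over the hour before cytoD, post = mean over the
  final hour (hour-scale windows match the plateaus such traces show);
  reversible = plateau − post, irreversible = post − cell-free baseline,
  stiffening ratio = plateau / baseline.  On noiseless traces reversible +
  irreversible equals plateau − baseline exactly.  Without a baseline the
  reversible part is still reported; ratio and irreversible part are not.

## The synthetic-scene generator

The generator provides every input the analyses need, with exact ground
truth recorded pre-noise and pre-drift:

* **Fibers**: random 3D line segments (length 15–45 µm) of uniform
  intensity rasterised and blurred with a σ = 1 voxel Gaussian PSF —
  polyisocyanide fibers (10–20 nm) are far below the resolution limit, so
  their apparent width is the PSF's.
* **Cell**: a spherical body with capsule protrusions whose directions are
  drawn with ≥ 40° pairwise separation; the nuclei channel is a smaller
  concentric ball.  Fibers are zeroed inside the cell.
* **Densification**: within a shell at a set distance range from the cell
  surface the fiber channel becomes `factor × (0.7·I_fiber + 0.6·fiber
  texture)` — a bright quasi-continuum (densely packed sub-resolution
  fibers merged by the PSF) that still carries texture, so registration has
  signal inside the shell.  The truth densified mask is the shell itself.
* **Displacement field**: radial, inward, magnitude A·exp(−d/λ) with d the
  distance to the cell surface (default A = 1.5 µm, λ = 20 µm), linearly
  tapered to zero at the cell centre so the discrete gradient stays
  bounded.  The exponential is a stand-in reproducing the observed monotone
  decay; it asserts nothing about the true constitutive behaviour of
  fibrous gels.  The stressed stack samples the relaxed one at x − u(x)
  (trilinear, reflect boundaries), then optional integer circular drift,
  then noise.
* **Noise**: Poisson on scaled intensities followed by additive Gaussian —
  the standard confocal model — applied last, independently per stack.
* **Rheology traces**: creep strain saturates toward σ/G and recovers
  exponentially toward `plastic_fraction × ε_end`; G′(t) rises from the
  baseline toward `baseline × stiffening_ratio` (defaults 45 Pa and 3,
  plateauing well before the 24 h cytoD event) and falls to `baseline +
  irreversible_fraction × stiffening`; densified-volume relaxation decays
  exponentially to the retained fraction with 2 % multiplicative noise at
  20-min sampling.

What passing tests on these scenes shows — and does not.  The generator
matches the *statistical structure* the algorithms assume: textured fiber
images, smooth radial decay fields, shells of elevated intensity, noise of
confocal type.  It does not simulate network mechanics (no force balance,
no strain stiffening, no fiber realignment or bundling), non-radial or
multi-cell displacement fields, bleaching, optical aberrations, or
anisotropic PSFs.  Recovery numbers quoted here are therefore statements
about algorithmic correctness under the stated conditions, not about
accuracy on any particular real acquisition.

## Problem sizes

The test-suite and acceptance computations use 128³ scenes for drift and
registration (ten seeded scenes, amplitudes 1–3 voxels), 160³ mask-only
scenes for the 50-cell morphometry census, 96³ scenes for densification,
and 64³/48³ fixtures wherever an exact brute-force oracle (per-voxel
binning, all-pairs distances, voxelised hulls) is compared bit-for-bit.
These sizes were chosen so every oracle comparison stays exact and the
whole suite runs on a single core at desk scale.

## Known limitations

* Drift estimation and FFD registration share one assumption: enough
  static or smoothly-deforming texture.  Fields whose decay length rivals
  the field of view bias the drift estimate (see above).
* The 2R protrusion rule measures the component beyond 2R; very short or
  very thick protrusions (length < 3R, radius ≳ R/2) blur the distinction
  between protrusion and body, and count recovery degrades.
* `split_clumped_cells` assigns basins by mask shape only; cells fused
  over a broad front (no neck) split along the distance-transform ridge,
  which need not be the biological boundary.
* The registration returns the forward (relaxed→stressed) field; users
  needing the inverse at amplitudes ≫ the control spacing should invert
  explicitly rather than negate.
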