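# Methods

## Model and pipeline

One acquisition is an ordered stack of *k* co-registered single-channel
images (default channel order blue, green, red, NIR emission). Channels
are assumed co-registered — true for filter-wheel acquisition in front of
a single camera — and no registration is attempted. Coordinates are
raster order: row index = y, column index = x, 0-based; "along the
x-axis" always means "within one image row".

The pipeline runs two independent preprocessing branches, each followed
by the same median filter, each feeding its own PCA:

```
cube ── std  (row standardization) ── median 4 ── PCA ── composite_std
    └── clahe (clip 12.0, 10x10)   ── median 4 ── PCA ── composite_clahe
```

The branches are complementary, not alternatives: row standardization
removes per-line illumination and exposure variation and accentuates
within-row contrast (hard tissue, epithelium), at the price of amplified
noise in rows crossing no structure; adaptive equalization raises
inter-structure contrast with a better signal-to-noise ratio and favors
stromal detail.

### Row standardization (Std)

Each row is mapped to zero mean and unit population standard deviation
(ddof = 0, the convention of the standard scaler this reproduces).
Degenerate rows map to zeros rather than NaN so they cannot poison the
PCA. Constancy is detected by `max == min` rather than `std > 0`:
floating-point summation can assign a bit-identical row a spuriously
nonzero standard deviation, and standardizing such a row produces a
constant ±1 artifact. Rows whose variance underflows to exactly zero are
likewise treated as degenerate. The Std output is kept real-valued (no
re-quantization before PCA); PCA is scale-agnostic per component.

### CLAHE

Implemented from first principles in the OpenCV convention, because the
canonical clip limit (12.0) is only meaningful relative to that
convention:

* the per-bin ceiling is `max(int(clip_limit × tile_pixels / n_bins), 1)`
  counts — the limit is tile-size- and bin-count-relative;
* the clipped excess is redistributed as a uniform batch of
  `excess // n_bins` per bin, with the residual dropped one count at a
  time at stride `max(n_bins // residual, 1)`; no re-clipping pass is
  made, so bins may end marginally above the ceiling;
* each tile's mapping is the cumulative histogram scaled by
  `255 / tile_pixels`, rounded half-to-even;
* pixels are mapped by bilinear interpolation among the mappings of the
  four nearest tile centers (`f = (coord + 0.5)/tile − 0.5`), which
  degrades to linear/nearest at borders and corners by index clamping.

CLAHE operates on an 8-bit domain: 16-bit and float channels are
linearly min–max rescaled onto [0, 255] and rounded first, making the
quantization explicit and reproducible. Images whose dimensions do not
divide the tile grid are edge-replicate padded on the bottom/right and
cropped after mapping. With `clip_limit = ∞` and a 1 × 1 grid the
operator reduces exactly to global histogram equalization, which the
test suite uses as a closed-form limit.

### Median filter

A true rank filter: the window of size *s* spans offsets
`[-(s // 2), …, +((s − 1) // 2)]` per axis (for the default *s* = 4:
−2…+1), out-of-bounds samples replicate the nearest edge, and the median
of an even window population is the **upper** middle order statistic
(sorted index `n // 2`, 0-based) — always a member of the window, never
an average. These conventions match the rank-filter behavior of the
scientific-Python ecosystem (verified against `scipy.ndimage` with
nearest-edge mode in the tests) and are stated explicitly because an
even window size is unusual.

### Spectral PCA

The decomposition treats **channels as observations and pixels as
features** — the opposite of per-pixel-spectrum PCA common in
hyperspectral work. Each channel is flattened row-major (a 1392 × 1040
channel becomes a vector of length 1,447,680), the per-pixel mean across
channels is subtracted, and the top three right-singular directions are
computed exactly via the k × k Gram matrix: for centered `X`,
eigenpairs `(λ_i, u_i)` of `XXᵀ` give pixel-space axes
`v_i = Xᵀu_i / √λ_i`. With k ≤ 8 channels this is exact, cheap, and free
of iterative-solver nondeterminism, so composites are bit-stable across
runs. No whitening is applied; eigen-images are unit-norm axes.

Numerical choices:

* **Sign rule.** Eigenvector sign is arbitrary; each component is
  flipped so that its largest-magnitude channel loading is positive,
  ties broken by lowest channel index.
* **Null components.** Eigenvalues below 10⁻¹² × λ_max are treated as
  zero: the component becomes a zero grid with zero loadings and ratio
  0 (the axis `Xᵀu/√λ` is numerically meaningless there).
* **Degenerate input.** An all-constant cube (zero total variance)
  raises an error rather than returning zeros — silent all-black output
  would mask upstream bugs.
* **Normalization.** Composite planes are affine min–max maps onto
  [0, 255], rounded half-to-even; a constant component maps to zeros.
  PC1 → red, PC2 → green, PC3 → blue.

With 4 channels, centering leaves rank ≤ 3, so the three retained
explained-variance ratios sum to 1 up to 10⁻⁹ — a rank invariant the
acceptance checks exercise.

## Synthetic phantom

The generator emulates the statistical structure of a multi-dye-stained
periodontal thick section imaged through four emission filters:

* **Geometry.** Default: five vertical bands (root, bone, ligament,
  gingiva, background) so that *every image row crosses the full tissue
  sequence* — the situation row-wise standardization is designed for,
  and the layout a periodontal section presents along a scan line.
  Nested-ring (`annulus`) and random-cell (`voronoi_seeded`) layouts are
  available; all three partition the image exactly.
* **Signatures.** Per-tissue 4-channel emission strengths in [0, 1] of
  full scale. The defaults encode dyes chosen for complementary
  contrasts: mineralized tissue bright in blue/green, soft tissue in
  red/NIR, near-dark background. The centered signature matrix has
  three comparable singular values (0.72 / 0.63 / 0.28), i.e. the class
  structure is genuinely three-dimensional — no single channel orders
  all five tissues, which is precisely the regime in which a
  three-component decomposition pays off.
* **Crosstalk.** A row-stochastic mixing matrix applied to the
  signature (default 0.15 uniform off-diagonal leakage) models each
  dye's emission bleeding into neighbouring passbands.
* **Autofluorescence.** A uniform additive background (default 0.05 of
  full scale), well below the labeling signal.
* **Illumination.** A multiplicative per-row tilt, top bright to bottom
  dim (default 30% falloff) — uncorrected field inhomogeneity of a
  wide-field macroscope. It is exactly the line-to-line variation the
  Std branch removes, and the raw channels suffer.
* **Noise.** Poisson shot noise at a fixed photon budget (default 2,000
  counts at full scale, i.e. ~1.4% relative at mid-intensity — weak
  fluorescence needing long exposures), plus additive Gaussian read
  noise (default 2% of full scale), then clipping and quantization to
  8 or 16 bits. Tying the Poisson scale to a photon budget rather than
  to digitizer units keeps shot-noise magnitude independent of the
  stored bit depth.

Generation is a pure function of the spec including its seed. The
defaults deliberately reproduce the operating regime that motivates the
method: no single raw channel separates the five classes well (Fisher
score ~10 at 256 × 192), while the Std-branch composite does (~15).

What the phantom does **not** model: optics (PSF, depth attenuation),
dye photochemistry and bleaching, spatial texture within a tissue,
non-rigid channel misregistration, and 3D structure. Passing tests
therefore demonstrate the pipeline's algebra and its behavior under
crosstalk/illumination/noise, not performance on real histology.

## Separability score

trace(S_b) / trace(S_w): between-class scatter of class-mean pixel
vectors (weighted by class pixel counts) over pooled within-class
scatter, computed on whatever plane set is supplied (3 composite planes,
or a single raw channel). The trace ratio stays defined when a plane is
near-constant, where a determinant ratio would collapse. It is invariant
under translations, orthogonal maps and uniform rescaling applied
identically to all pixel vectors — but not under arbitrary non-singular
linear maps, a property only eigenvalue-based criteria have; the
property tests cover exactly the invariances the statistic possesses.
Zero within-scatter with distinct means returns a documented +∞
sentinel (serialized as `"inf"`).

## Problem sizes

The test suite and acceptance script run phantoms between 64 × 96 and
256 × 192, plus one full-CCD run at 1392 × 1040; the 100-replicate
enhancement comparison runs at 256 × 192. These sizes give stable scores
(≈50k pixels per replicate) at interactive runtimes.

## Known limitations

* CLAHE agreement with the reference convention is asserted at ±1 gray
  level; exact bit-equality with any particular binary is not claimed
  (floating-point summation order differs).
* The Std branch's output is unbounded; persisting it requires float
  TIFF (`bit_depth="float"` channels round-trip losslessly).
* The separability score compares per-pixel vectors only; it does not
  credit texture or boundary sharpness, so it understates the visual
  benefit of the CLAHE branch, whose adaptive stretch is locally — not
  globally — consistent by construction.
* Channel counts other than 4 work (n_components ≤ k), but the RGB
  composite always requires exactly three retained components.
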