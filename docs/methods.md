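# Methods

This note documents the models, numerical choices and known limitations of
`lffundus`. The package simulates a focused plenoptic ("plenoptic 2.0")
fundus camera imaging a model eye, recovers depth from the raw light-field
capture, and quantifies optic-disc cupping.

## Camera model

The camera is described by a sensor (raster size, pixel pitch, bit depth), a
hexagonal microlens array (MLA), and the fore-optics magnification.

* **Full configuration**: 4024 × 3036 px at 1.85 µm (diagonal 9.33 mm),
  80 µm MLA pitch (43.243 px), lateral magnification 1.5, axial
  magnification 1.5² = 2.25. The nominal 18 µm depth resolution of this
  configuration is carried as metadata only; its derivation is not
  reconstructed here.
* **Hex grid**: one lattice axis parallel to the sensor rows by default, one
  lens anchored at the sensor center, and only lenses whose full circular
  footprint lies on the sensor are kept. The three interleaved focal-length
  types (`near`, `middle`, `far`) are assigned by the proper 3-coloring
  `(q − r) mod 3` of the axial hex coordinates, so adjacent lenses never
  share a type. The real array's type layout is undisclosed; only the type
  *labels* are modeled, not distinct per-type focus.
* **Virtual depth**: `v = baseline / disparity` in units of the MLA–sensor
  distance (the standard focused-plenoptic convention). Map "v-mm" equal
  `v` times a configurable map scale, default 1. Depth differences convert
  to object mm by dividing by the axial magnification.
* **MTF frequency axis**: object-space frequency is image-side frequency
  divided by the lateral magnification (doubling the magnification halves
  every object-space frequency). All closed-form MTF checks are
  convention-independent.

### Desk-scale default

The default camera for simulation studies is a reduced **desk scale**:
1006 × 759 px at 5.55 µm (three times the full pixel pitch, one quarter the
raster per axis) with the *physical* 80 µm MLA, i.e. 14.41 px lens pitch.
Two constraints drove this choice over a naive uniform shrink:

1. The subimage footprint must hold a 5 px matching patch *plus its bilinear
   interpolation support* with room for the disparity search at the working
   virtual depths; a 10 px pitch cannot, and patch supports that cross the
   vignette rim pick up neighboring-lens pixels and bias disparities
   systematically.
2. The lens pitch must stay non-integer in pixels, as it is on the real
   sensor (80/1.85 = 43.243 px). An exactly integer pitch makes every lens
   pair sample the scene with the same fractional phase, so interpolation
   and aliasing errors are coherent across the whole array and do not
   average out.

The reference virtual depth of the fundus plane is 3.2 at desk scale: far
enough that the disparity search fits the footprint, close enough that the
subimage minification (≈ v texture pixels per sensor pixel) does not alias
the scene texture.

## Synthetic eye model

The generator emulates a 1:1 physical eye phantom:

* **Geometry**: spherical fundus of radius 10 mm (axial sag `R − √(R²−r²)`)
  plus an optic-cup excavation of configurable depth (study set 0.2 / 0.4 /
  0.8 / 1.0 mm) and radius (default 0.6 mm). The default cup profile has a
  flat bottom and steep walls (smoothstep over the outer 45 % of the cup
  radius); a cosine profile is available.
* **Virtual-depth coupling**: a surface point of elevation `z` mm renders at
  `v = v_ref + 2.25 · z`, the exact inverse of the measurement chain's
  metric correction — so depth recovery closes the loop end to end.
* **Vessels**: seeded smooth curves radiating from the disc rim (widths
  taper ≈ 30 → 10 µm object scale, i.e. 2–6 px at desk scale), start angles
  excluded around the four cardinal directions so N/E/S/W rim marking stays
  possible. Vessel darkness per band follows the Michelson relation
  `I_vessel = I_bg (1−C)/(1+C)` for band contrast `C`.
* **Spectral model**: vessel contrast per band {450: 0.50, 520: 0.70,
  600: 0.35, 650: 0.15} — peaked in the green, collapsed in the red — and a
  choroid-visibility scalar rising toward the red that adds a faint
  low-frequency pattern. These are qualitative lookups, not radiative
  transfer.
* **Background texture**: two-scale Gaussian-correlated mottling
  (correlation lengths 0.012 and 0.028 mm) standing in for pigment/lacquer
  micro-structure; its amplitude scales with the band contrast. The fine
  scale localizes the correlation peak, the coarse scale stays resolvable
  even at the deepest (most minified) cup.
* **Rendering**: non-inverted pinhole views per lenslet; the subimage pixel
  at offset `u` from lens center `c` samples the scene at `X = c + u·v(X)`
  (fixed-point iterated three times), which makes inter-subimage disparity
  exactly `baseline/v`. The texture is band-limited by a Gaussian of
  0.3 · v_ref px before sampling, approximating the pixel-aperture
  integration of the v-times minified subimage view. Hard circular
  vignettes, additive Gaussian noise on linear intensity before
  quantization.
* **Not modeled**: physical optics (cornea, achromat, stray light), per-type
  microlens focus, subimage inversion (cancels in disparity), occlusion at
  steep cup walls, photon-transfer noise. Passing tests therefore certify
  the *algorithmic* chain, not robustness to real anterior-segment optics.

Artifact injection reproduces the observed classes qualitatively:
checkerboard-like reflection patches, blurred dots on the MLA lattice, and
the internal fixation needle as a straight high-contrast line.

## Depth estimation

Defaults reproduce the reference expert-mode processing parameters: minimum correlation
0.860, minimum patch standard deviation 0.006 of full scale, patch diameter
5 px, stride 1 px, all lens types enabled, depth range 0–130 %, consistency
check on. Preprocessing (gradation, denoise, sharpening, ROI) is the
documented identity.

* Matching is pairwise along the three positive hex lattice directions and
  the accepted points of all pairs are pooled; the vendor's proprietary
  multi-view aggregation is not reproduced.
* The percent depth range maps linearly onto a virtual-depth window
  (defaults: 0 % → v = 1, 100 % → v = 10, so 130 % → 12.7).
* Correlation is evaluated on a half-pixel lag grid and refined by a
  three-point parabola (ties toward the smaller lag); patch centers and the
  shifted patch must lie, with interpolation support, inside the circular
  footprint.
* The consistency check re-matches from the rounded reverse landing offset
  and keeps a point only if the reverse match lands within 1 px of the
  source patch. The exact vendor semantics of the "reverse calculation" are
  unpublished; this is the package's own definition, mirrored by the
  brute-force oracle in the tests.
* Point coordinates are the virtual-image positions `c + u·v` in raw-raster
  pixels, so points from all lenses land in one common image frame.

**Known error mode**: smooth, band-limited texture has correlation sidelobes
above 0.86 about one pixel off the true lag, and a symmetric false peak also
passes the reverse check. Roughly 10 % of accepted points sit on such wrong
lobes. The median of any pooled region is unaffected, and the circle-area
means used for all depth measurements suppress the tail, but raw
single-pixel map values carry it (see the depth-profile tests, which assert
median < 0.05 mm and 90th percentile < 0.15 mm against ground truth rather
than a uniform bound).

## Depth map and image synthesis

* Rasterization bins points at one quarter of the raw raster per axis
  (1006 × 759 full scale), averaging points per bin; untouched bins are
  invalid.
* The inconsistency filter invalidates pixels deviating more than 20 % from
  the median of their valid neighbors (lookup distance 1). The filter is
  named in the reference parameter set without a tolerance; 20 % is this
  package's constant, chosen conservatively (it removes order-of-magnitude
  outliers without eating the cup walls). Filling (0 iterations by default,
  the reference setting: filter only) copies the nearest valid neighbor,
  nearest-first with row-major tie-break; `complete_fill` repeats until no
  gap remains.
* The bilateral filter smooths valid pixels only: spatial Gaussian of sigma
  radius/2.5 truncated at radius 10 px, range kernel of width
  0.025 × (display span 5.5 v-mm) = 0.1375 v-mm.
* Total focus: per output pixel (half the raw raster per axis, 2012 × 1518
  full scale), the samples of every lens that sees the point at its local
  map depth are averaged; an all-invalid map falls back to a central mosaic
  with a warning. Refocus fixes a single v; sharpness metrics should be
  restricted to pixels with ≥ 3 contributing lenses (exposed via
  `with_count`), because sparsely covered pixels look artificially sharp at
  wrong depths.
* Colorization maps [0.5, 6.0] v-mm through a perceptually uniform rainbow
  colormap (matplotlib `turbo` by default, configurable); invalid pixels
  render gray. The exact vendor palette is unknown, so palette choice is
  untested.

## Measurements

* **MTF**: mean of 50 row profiles of 400 px across a vertical
  back-illuminated edge, forward-differenced, `|rfft|`, DC normalized to 1.
  The finite-difference sinc response is divided out by default; a Hann
  window is available behind a flag (off by default — plain differentiation
  plus transform). Landmarks: first linear-interpolated 0.5 crossing, and
  the frequency of minimum amplitude as cutoff.
* **Michelson contrast**: measured on a disc-eroded (radius 8 px,
  border-clipped minimum filter) total-focus image at a ring of twice the
  papilla radius; in synthetic mode the three darkest well-separated ring
  minima are taken as venules, each with two flanking background samples
  13 px along the ring (far enough that the erosion halo of the vessel does
  not reach them). Per venule, contrast is `(I_bg − I_v)/(I_bg + I_v)` with
  `I_bg` the flank mean; the reported value is the three-venule mean.
* **Papilla geometry**: center from the E–W and N–S rim-mark midpoints,
  radius the larger half-extension; in simulation the marks come from the
  generator's ground truth. Depth positions are counted inside the circle
  of diameter 5.5 papilla radii, always clipped to the map.
* **Cup depth**: "circle area of 20 px" is read as a circle *containing*
  20 pixels (radius ≈ 2.5 px), not radius 20 — the smaller reading matches
  manually placed points on ~1000 px maps; the area is a parameter. The
  eye-model variant uses an 85 px circle on the ground and four reference
  circles on the flat surround at 1.5 papilla radii (E/W averaged for the
  horizontal depth, N/S for the vertical), then the h/v mean is divided by
  2.25. The sphere's own sag between center and reference ring (≈ 0.04 mm)
  enters the measurement as a small constant offset, exactly as it would on
  the physical model; it does not affect the calibration slope.
* **Calibration**: ordinary least squares of measured metric depth against
  true model depth, with R² and residuals.

## Study conditions

The packaged experiments run at desk scale on one CPU:

* **Model study**: cup depths {0.2, 0.4, 0.8, 1.0} mm × 5 seeded replicates
  (a bench campaign would use ~30 captures per depth; 5 suffices for the
  calibration at these noise levels), render noise 0.005 of full scale
  (bench-like), green illumination. Typical outcome: slope ≈ 1.02,
  R² ≈ 0.997.
* **Spectral study**: one scene geometry rendered at 450/520/600/650 nm with
  noise 0.02 of full scale — the in-vivo captures are photon-starved
  relative to the bench model, and at bench noise the band-dependent count
  differences nearly vanish, which contradicts the strong observed drops
  off the green optimum. At 0.02 the counts drop ≈ 15 % (450), ≈ 37 %
  (600) and ≈ 80 % (650) relative to 520 nm.
* Every replicate/band derives its own seed from the run seed (kept below
  2³¹); seeded runs are byte-identical, and each study writes a provenance
  JSON (config hash, seed, versions).

## Limitations

* The simulation validates the algorithm chain against its own forward
  model; real captures add stray light, reflections, astigmatism and
  wavefront error that are out of scope (artifact injection is qualitative
  only).
* Virtual depth is not metrically calibrated end-to-end against an external
  scale; the 2.25 axial correction is the system's computed magnification,
  and calibration offsets (as against an external depth reference) are
  reported, not explained.
* Depth estimation requires image structure; homogeneous regions stay
  invalid by design, and linear structures (vessels) can lock onto wrong
  correlation lobes along their own direction — an artifact the filter
  reduces but does not eliminate.
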