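# lffundus

Light-field (focused plenoptic) fundus imaging: simulation, depth
estimation, and quantification of optic nerve head cupping.

## The problem

Glaucoma risk shows up early as abnormal cupping of the optic disc, but a
conventional fundus photograph is two-dimensional: it documents the papilla
without measuring its depth. A focused plenoptic camera — a hexagonal
microlens array (MLA) in front of the sensor, each lenslet forming a small,
slightly shifted subimage of an intermediate retinal image — turns a single
exposure into a 3-D measurement: any structure seen by at least two lenslets
can be triangulated. This package re-implements that analysis chain as
tested, open code, together with a synthetic eye model (spherical fundus,
interchangeable cup depths, painted vessels) so that every stage can be
validated against known ground truth without any physical hardware.

It is written for researchers in ophthalmic imaging and computational
optics who want to study or extend plenoptic depth estimation of the
retina: the depth recovery, the depth-map post-processing, the image-quality
metrics (MTF, Michelson vessel contrast), and the cup-depth calibration are
all first-class, scriptable functions.

## Model and method

For two lenslets with baseline `b` (pixels) observing the same point at
disparity `d`, the **virtual depth** is

    v = b / d

(dimensionless; "v-mm" once scaled into map units). Matching uses normalized
cross-correlation of small pixel patches (diameter 5 px, minimum correlation
0.860, minimum normalized standard deviation 0.006 as a contrast gate, all
three interleaved lens focal types enabled, reverse-match consistency
check) along the three hex baseline directions. Accepted points are binned
into a depth map (one quarter of the raw raster per axis: 1006 × 759 for
the full 4024 × 3036 sensor), cleaned by an inconsistency filter, smoothed
with an edge-preserving bilateral filter (radius 10 px, edge smoothing
0.025), and rendered as total-focus images.

With fore-optics of lateral magnification `m = 1.5`, depth differences scale
with the **axial magnification** `m² = 2.25`:

    depth_mm = Δv / m²

Cup depth is the difference between the periphery and the ground of the
optic nerve head, each sampled as a circle-area mean on the depth map, taken
horizontally and vertically and averaged, then corrected by `1/2.25`.
Calibration against the eye model's printed cup depths (0.2, 0.4, 0.8,
1.0 mm) is an ordinary least-squares line; image quality is characterized by
the edge-based MTF (average of 50 row profiles, differentiation, Fourier
transform, object-space frequency axis) and by the Michelson contrast of
venules on an eroded total-focus image.

## Worked example

```python
import numpy as np
from lffundus.plenoptic_model import desk_camera
from lffundus.synthetic_data import make_fundus_scene, render_raw_lightfield
from lffundus.depth_estimation import estimate_depth
from lffundus.pipeline import RunConfig, process_raw, scene_papilla_geometry
from lffundus.papilla_metrics import model_papilla_depth

camera = desk_camera()                       # 1006x759 px, 80 um hex MLA
scene = make_fundus_scene(papilla_depth_mm=0.8, seed=1)
raw = render_raw_lightfield(scene, camera, noise_sd=0.005, seed=1)

points = estimate_depth(raw)
print(f"{len(points)} depth points, median v = {np.median(points.v):.3f}")

dmap = process_raw(raw, RunConfig())         # rasterize + filter + smooth
geom = scene_papilla_geometry(scene, camera, dmap.resolution)
result = model_papilla_depth(dmap, geom, camera.magnification)
print(f"cup depth: {result.depth_mean_vmm:.3f} v-mm -> "
      f"{result.depth_mm:.3f} mm (truth 0.800 mm)")
```

prints

```
78859 depth points, median v = 3.604
cup depth: 1.737 v-mm -> 0.772 mm (truth 0.800 mm)
```

The 78 859 sparse points triangulated from the raw capture have a median
virtual depth of 3.604 (the fundus surround sits at the camera's reference
virtual depth plus its spherical sag); the cup of the 0.8 mm eye model is
measured as 1.737 v-mm between surround and ground, and dividing by the
axial magnification 2.25 recovers 0.772 mm — within 30 µm of the printed
model depth.

The same chain is packaged as a CLI:

```sh
lffundus simulate --depth 0.8 --seed 1 --out out/
lffundus estimate out/raw_d0.8_b520_r0.tiff --out out/
lffundus model-study --seed 1 --out out/model
lffundus spectral-study --seed 1 --out out/spectral
```

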