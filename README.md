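# htoplan

Automatic correction-angle planning for medial opening-wedge **high
tibial osteotomy (HTO)** on standing long-leg AP radiographs, using the
**Miniaci method**. The package is aimed at researchers in orthopedic
image analysis who want a tested, scriptable implementation of the full
landmark-detection-to-angle chain, and at method developers who need a
synthetic-phantom harness with exact ground truth to validate each stage.

## The method

HTO shifts load from the damaged medial to the healthy lateral knee
compartment by opening a wedge in the proximal tibia. Planning the
opening angle by the Miniaci construction requires five landmarks on the
radiograph, which `htoplan` finds automatically inside externally
supplied regions of interest (femoral head / knee / ankle boxes, e.g.
from an object detector, ingested in the darknet text dialect):

| landmark | detector |
|---|---|
| femoral head center `F` | circular Hough transform (vote array over `(x−a)² + (y−b)² = r²`, radii proportional to the box, gradient-direction peak selection) |
| tibial plateau edges `M`, `L` (inner/outer knee points) | Active Shape Model or Active Appearance Model (PCA shape + gray-profile / texture statistics), trained per laterality on 17-, 31- or 59-point contours |
| talus border points → ankle center `A` | horizontal Sobel + Otsu threshold + morphology on the tibiotalar joint band; `A` is the midpoint of the band's extremes |

From these, in image coordinates (y down):

- Fujisawa point `Fu = M + 0.625 (L − M)` — 62.5% of the plateau width
  lateral to the medial edge;
- mechanical axis `F→A`; correction axis `F→Fu`, extended to the ground
  level where it meets `G`;
- hinge point `HP` = outer knee point shifted 14% of the knee width along
  x toward the inner point and 18% downward;
- correction angle `α` = angle at `HP` between rays `HP→A` and `HP→G`
  (atan2 of cross/dot; positive = valgus-producing correction).

Rotating the distal limb about `HP` by `α` carries the ankle center onto
the correction axis — exactly what the osteotomy achieves. Full details,
parameter defaults and limitations are in [`docs/methods.md`](docs/methods.md).

Because the clinical stages are separable, every stage is also exercised
on **synthetic leg phantoms** (`htoplan.phantom`): stylized radiographs
with a bright head disk, shafts, plateau contour and dark joint band,
whose deformity is constructed by *inverting* the Miniaci geometry so the
ground-truth landmarks reproduce a requested angle exactly. A naive
intensity detector (`htoplan.roi.phantom_detector`) stands in for the
trained box detector so the whole pipeline runs with no learned model.

## Worked example

Generate a phantom with a known 12° varus deformity, train right-leg knee
models on seeded phantoms, and plan it:

```sh
$ htoplan phantom --n 1 --seed 42 --angle 12 --out fixtures
wrote 1 phantom fixture(s) to fixtures

$ htoplan train-knee --points 59 --laterality right --n-train 12 --seed 100 \
      --model knee_right.npz
trained 59-point right knee models in 0.2 s -> knee_right.npz

$ htoplan plan fixtures/phantom_000.png --boxes fixtures/phantom_000.txt \
      --model knee_right.npz --out plan.json
single: correction angle 12.01 deg (varus)
```

The planned angle (12.01°) recovers the phantom's constructed 12.00°
deformity to 0.01°; `plan.json` additionally records the axis endpoints,
the hinge point (here `[170.0, 440.8]` px), the ground row used (705.5,
the detected ankle level), the signed angle, per-stage timings and the
config hash. `fixtures/phantom_000.json` holds the exact truth the
phantom was built from, and `fixtures/phantom_000.txt` is the darknet box
sidecar — on real radiographs this file would come from your detector.

The same operations are available as a library:

```python
from htoplan import Laterality, PipelineConfig, run_pipeline, train_knee_bundle
from htoplan.phantom import render, sample_specs
from htoplan.roi import phantom_detector

bundle = train_knee_bundle(laterality="right", n_train=12, seed=100)
spec = sample_specs(1, angle_distribution=12.0, seed=42)[0]
image, truth = render(spec)
result = run_pipeline(image, phantom_detector(image),
                      {Laterality.RIGHT: bundle}, PipelineConfig())
print(result.legs[0].plan.correction_angle_deg)   # 12.01
```

Agreement statistics between raters (ICC(2,1) with 95% CI, Bland–Altman
bias and limits, absolute-error summaries, skew-normal case-mix fits)
live in `htoplan.evaluation` and behind `htoplan evaluate --ratings
table.csv`.

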