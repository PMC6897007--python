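# ctcpolyp

Analysis pipeline for CT colonography (CTC, "virtual colonoscopy"):
boundary-based colon segmentation, kVp-adaptive electronic cleansing of
orally tagged colonic fluid, and skeleton-based measurement and
classification of small polyps — together with a synthetic phantom
generator that provides voxel-level ground truth, so every stage of the
pipeline is quantitatively testable without patient data.

## Who this is for

CTC screening looks for colorectal polyps in CT volumes of the
air-distended colon.  Three image-processing problems dominate the
measurement accuracy of such systems, and this package implements one
tested solution for each:

1. **Colon segmentation.**  The colon volume of interest (VOI) is
   extracted slice by slice: edge-preserving adaptive smoothing, Canny
   boundary detection (5×5 Gaussian, σ = 1.4, hysteresis thresholds with a
   2:1–3:1 high:low ratio, defaults 100:40 on the 8-bit display image),
   connected-component labeling of the boundary points, a colonic
   distension rule that discards blobs under 2 cm axial diameter, and
   scan-line stitching between extreme boundary points so that protruding
   structures (haustral folds, polyps) stay inside the VOI with their
   original HU.  The resulting boundary is closed and one pixel thick.

2. **Electronic cleansing (EC).**  Residual fluid is tagged with oral
   contrast and removed digitally.  Voxels are classified against a
   material → HU lookup table (at 120 kVp: air −1000±10, low-attenuation
   gas −900±25, fat −89±10, soft tissue/polyp +54±5, tagging contrast
   ≥ +130 HU; at other tube voltages the interval centres are recomputed
   from attenuation ratios, `HU = 1000·(μ_t − μ_w)/μ_w`).  The EC sequence
   removes tagged voxels, deletes the air–contrast partial-volume layer,
   corrects pseudo-enhancement of nearby tissue, and median-filters
   residual speckle inside the lumen only — soft tissue is preserved
   bit-exactly.

3. **Polyp measurement.**  Each endoluminal structure is thinned to a
   skeleton; skeleton points on the colon boundary are removed, leaving
   the structure's medial axis rooted at the wall.  At every axis point a
   unit normal is built by Gram–Schmidt orthogonalization against the
   local tangent and the chord of the structure along it is measured by
   sub-voxel ray marching; the maximal chord is the width, the wall-to-tip
   extent of the axis the height.  A structure is a polyp if its height is
   under 6 mm (otherwise a haustral-fold candidate); polyps are sessile
   when height > 1.5 × width, else flat, and sized into the clinical
   1–5 mm / 6–9 mm / ≥10 mm bands.

Segmentations are scored with the volumetric overlap
`100·|A∩B| / |A∪B|`, detections with per-polyp confusion statistics, and
measurement agreement with a paired t-test.

## Worked example

```python
import numpy as np
from ctcpolyp import (PhantomConfig, generate_phantom, segment_colon,
                      electronic_cleanse, measure_structure, volumetric_overlap)

vol, truth = generate_phantom(PhantomConfig(seed=1))   # tagged phantom
seg = segment_colon(vol)
print(f"VOI overlap vs truth: {volumetric_overlap(seg.mask, truth.colon_region):.2f}%")

cleansed = electronic_cleanse(vol)
print(f"lumen median HU after cleansing: {np.median(cleansed.voxels[truth.lumen_mask]):.0f}")

for p in truth.polyps:
    m = measure_structure(p.mask, truth.boundary_mask, vol.spacing)
    print(f"polyp {p.polyp_id}: true (h={p.height_mm}, w={p.width_mm}) mm -> "
          f"measured (h={m.height_mm:.1f}, w={m.width_mm:.1f}) mm, "
          f"{m.kind}/{m.morphology}, {m.size_category}")
```

prints

```
VOI overlap vs truth: 96.29%
lumen median HU after cleansing: -1000
polyp 0: true (h=4.0, w=2.5) mm -> measured (h=3.4, w=2.5) mm, polyp/flat, 1-5mm
polyp 1: true (h=4.0, w=5.0) mm -> measured (h=4.4, w=4.4) mm, polyp/flat, 1-5mm
polyp 2: true (h=5.0, w=6.0) mm -> measured (h=5.8, w=5.2) mm, polyp/flat, 6-9mm
```

The phantom's colon is segmented with 96% volumetric overlap against
ground truth, cleansing restores the submerged lumen to air HU, and polyp
sizes recover to within about one voxel (0.7 mm in-plane here); polyp 0
sits on the sessile/flat borderline (4 mm vs the 1.5 × 2.5 = 3.75 mm
cut) and lands on either side depending on sub-voxel discretization.

## Command line

```bash
ctc phantom --config cfg.yaml --seed 1 --out phantom_dir/
ctc segment --in phantom_dir/dicom --out voi.nii.gz --lt 40 --ht 100
ctc cleanse --in phantom_dir/dicom --kvp 120 --out cleansed.nii.gz
ctc measure --in cleansed.nii.gz --voi voi.nii.gz --out report.json
ctc evaluate --pred report.json --truth phantom_dir/truth.json
ctc stats --confusion 54,3,6,14
```

## Layout

```
src/ctcpolyp/volume_io.py     CT volumes, HU conversion, DICOM/NIfTI I/O
src/ctcpolyp/phantom.py       synthetic CTC phantom + ground truth
src/ctcpolyp/segmentation.py  smoothing, Canny, CCL, scan-line stitching
src/ctcpolyp/cleansing.py     kVp lookup table + electronic cleansing
src/ctcpolyp/measurement.py   skeleton, medial axis, widths, classification
src/ctcpolyp/evaluation.py    overlap, confusion stats, paired t-test
src/ctcpolyp/cli.py           `ctc` command line
docs/methods.md               models, parameters, limitations
```
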