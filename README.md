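# lymphseg

Automated detection, segmentation, measurement and N-staging of pelvic
lymph nodes on diffusion-weighted MRI (DWI)-like volumes.

On high-b-value DWI, lymph nodes appear as compact bright blobs; the
standard radiologic criterion flags a node as suspicious for metastasis
when its **short diameter exceeds 0.8 cm**, and a patient is staged **N1**
if at least one suspicious node is present, **N0** otherwise. `lymphseg`
implements the full reading chain a radiologist would otherwise perform:

1. **3D U-Net segmentation** — an encoder/decoder with skip connections,
   two (conv 3×3×3 → instance norm → ReLU) blocks per level, channel
   doubling, 2×2×2 max pooling and transposed-convolution upsampling, a
   sigmoid voxel-probability head, trained with the soft Dice loss
   `L = 1 − (2Σpt + ε)/(Σp + Σt + ε)` under Adam (initial learning rate
   10⁻⁴) with light geometric augmentation (skew/shear 0–5°, translation
   ±10%). The network is pure numpy (BLAS-backed convolutions) and trains
   at desk scale on one CPU.
2. **Lesion extraction** — clusters of contiguous foreground voxels
   (26-connectivity by default) become individual nodes; each node's
   volume comes from its voxel count and its short diameter from the
   smallest edge of the **minimum-volume oriented bounding box** of its
   voxel centers (padded by one voxel extent), all in physical mm.
3. **Suspicious-node filtering and structured reporting** — nodes with
   short diameter > 0.8 cm are counted, the largest node's measurements
   are recorded, and the N0/N1 stage is emitted as a structured report.
4. **Evaluation** — the seven segmentation metrics (Dice, PPV, TPR,
   volumetric similarity, Hausdorff, average and Mahalanobis distance),
   overlap-based lesion-wise detection (precision/recall/F1), patient-level
   sensitivity/specificity/AUC, Cohen's kappa, Pearson correlation and
   Bland–Altman agreement.

Because no public dataset accompanies this problem, a **phantom module**
generates DWI-like volumes with known ground truth: ellipsoidal bright
nodes (0.3–2 cm short diameter), bright tubular distractors mimicking
vessels and bowel, partial-volume blur and Gaussian noise, on an
anisotropic grid (default 32×96×96 voxels at 3×1.5×1.5 mm). Every stage of
the pipeline is testable end to end against these phantoms.

## Worked example

```python
import numpy as np
from lymphseg import (PhantomSpec, generate_phantom, label_components,
                      build_report, render_report)

vol, mask, truths = generate_phantom(PhantomSpec(seed=3))
lesions = label_components(mask)
for t, l in zip(sorted(truths, key=lambda t: tuple(t.center)),
                sorted(lesions.lesions, key=lambda l: tuple(l.obb.center))):
    print(f"truth {t.short_diameter_cm:.2f} cm -> measured "
          f"{l.short_diameter_cm:.2f} cm")
print(render_report(build_report(lesions, cutoff_cm=0.8), format="text"))
```

prints

```
truth 1.10 cm -> measured 1.20 cm
truth 0.68 cm -> measured 0.60 cm
truth 1.36 cm -> measured 1.50 cm
truth 0.50 cm -> measured 0.45 cm
Pelvic lymph node structured report
Suspicious nodes (short diameter > 0.8 cm): 2
Largest node: short diameter 1.50 cm, volume 2.072 cm3
N-stage: N1
```

i.e. all four generated nodes are recovered with short diameters within
one voxel (3 mm slice thickness) of ground truth, the two nodes above the
0.8 cm cutoff are flagged, and the patient is staged N1.

The same pipeline is available from the shell:

```sh
lymphseg phantom generate --n-nodes 4 --seed 3 \
    --out-image dwi.nii.gz --out-mask truth.nii.gz --truth-json truth.json
lymphseg unet train --config train.yaml --train-dir data/train \
    --val-dir data/val --out-weights model.npz
lymphseg pipeline run --image dwi.nii.gz --weights model.npz --out-dir out/
```

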