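# wbcseg

Segmentation of white blood cells (leukocytes) in stained blood-smear
micrographs, for researchers building automated differential counts and
leukemia screening tools.  The hard part of the problem is that immature
leukocytes have rough borders and frequently touch or overlap, so a
semantic segmenter alone merges neighbors into single blobs.

The package implements a two-stage pipeline:

1. **Pre-segmentation** — a UNet++ (nested encoder–decoder with dense
   skip pathways) whose encoder levels embed neural-ODE blocks produces a
   per-pixel WBC probability map.  A residual block
   `g_{t+1} = g_t + F(g_t, ρ_t)` is the one-step Euler discretization of
   `dg/dt = F(g, t, ρ)`; the ODE blocks integrate that field over a unit
   time span (RK4 by default) and reduce exactly to the residual form at a
   single unit Euler step.  Deep-supervised 1×1 conv + sigmoid heads
   `φ(u) = 1/(1+e^{-u})` are trained with mean binary cross-entropy
   `−(1/M) Σ [ξ log p + (1−ξ) log(1−p)]`.
2. **Marker-controlled watershed** — Sobel gradient, opening/closing by
   reconstruction (disc radius 3), foreground markers from regional
   maxima, background markers from the distance-transform watershed
   ridge, minima imposition, and seeded flooding separate touching cells
   into instances, one instance per marker.

Evaluation uses the confusion-matrix metrics DSM (Dice), PA, MPA, IU and
MIU, with per-dataset means, quartiles and box plots.  Because the
clinical datasets (ALL_IDB1/2) require registration, a synthetic
blood-smear generator with pixel-perfect semantic and instance ground
truth makes every stage testable offline; see `docs/methods.md` for what
it does and does not emulate.

The network runs on a small self-contained numpy autodiff engine
(`wbcseg.nn`) — no deep-learning framework is required.

## Worked example

Separate two overlapping synthetic cells (centers 30 px apart, radius
20 px) and score the result against ground truth:

```python
import numpy as np
from scipy import ndimage as ndi
from wbcseg import watershed, metrics

yy, xx = np.mgrid[0:128, 0:128]
cells = (((yy-64)**2 + (xx-49)**2 <= 400) |
         ((yy-64)**2 + (xx-79)**2 <= 400))
prob = np.clip(ndi.gaussian_filter(cells.astype(float), 1.0), 0, 1)

labels = watershed.separate_cells(prob)
print("instances found:", labels.max())
print("pixels per instance:", [int((labels == k).sum()) for k in (1, 2)])

report = metrics.evaluate_dataset([labels], [cells.astype(int)])
for name, value in report.means.items():
    print(f"{name}: {value:.4f}")
```

Output:

```
instances found: 2
pixels per instance: [1179, 1150]
dsm: 0.9983
pa: 0.9995
mpa: 0.9994
iu: 0.9966
miu: 0.9980
```

The merged blob is split into two instances of nearly equal area along
the geometric bisector, and the binarized result agrees with the ground
truth on 99.95% of pixels (the deficit is the one-pixel-wide soft edge).

## Command line

The `wbcseg` entry point chains the stages (YAML config optional; flags
win):

```sh
wbcseg simulate --n 100 --seed 1 --out data/
wbcseg train    --manifest data/manifest.csv --out run/      # Adam 1e-4, 30 epochs, 80/20
wbcseg segment  --checkpoint run/checkpoint.npz --images data/scene_0000.png --out seg/
wbcseg evaluate --pred seg/ --truth data/ --out eval/        # CSV + box plot + summary JSON
```

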