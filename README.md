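# massdelim

Delimitation of benign and malignant breast masses in B-mode ultrasound
images, for researchers working on classical (non-deep-learning) lesion
segmentation and for anyone needing a deterministic, parameter-light
baseline to compare against.

Ultrasound speckle makes boundary delineation hard: the noise is
multiplicative and non-Gaussian, and malignant masses have irregular,
ill-defined margins. `massdelim` implements a three-stage pipeline:

1. **Nonlocal Means denoising** — each pixel becomes a weighted average of
   search-window pixels, `w(i,j) ∝ exp(−‖x(N_i)−x(N_j)‖²/h²)` with per-pixel
   normalization `Σ_j w(i,j) = 1`, smoothing speckle while preserving edges.
2. **Intuitionistic fuzzy superpixels** — intensities are mapped to triples
   (μ, ν, π) of membership, non-membership (Sugeno generator
   ν = (1−μ)/(1+(e^λ−1)μ)), and hesitancy π = 1−μ−ν; grid-seeded local fuzzy
   c-means then minimizes `J = Σ_l Σ_k u_lk^γ d(x_l, v_k)` over 2S×2S
   candidate windows, producing ~K edge-adherent superpixels.
3. **DBSCAN over superpixel centroids** — centroids within radius δ with at
   least ϑ neighbors form core points; density-connected cores merge into
   tissue regions with no cluster count required. The darkest (hypoechoic)
   cluster, largest-component-filtered and hole-filled, is the mass mask.

Segmentations are scored with the Jaccard similarity coefficient (JSC),
Dice measure (DM), Hausdorff distance (HD, pixels), and misclassification
ratio (MCR, percent). A synthetic phantom generator (hypoechoic masses
under unit-mean Gamma speckle, with exact ground-truth masks) makes every
stage testable without clinical data.

## Worked example

```python
import numpy as np
from massdelim import (PhantomSpec, generate_phantom, phantom_suite_config,
                       run_pipeline, evaluate_masks)

# an irregular ("malignant-like") mass under 16-look speckle
spec = PhantomSpec(height=256, width=256, mass_shape="blob", semi_axes=(30, 40),
                   boundary_roughness=0.35, speckle_looks=16, seed=7)
image, truth = generate_phantom(spec)

result = run_pipeline(image, phantom_suite_config())
report = evaluate_masks(result.mask, truth)
print(f"superpixels: {result.report['n_superpixels']}, "
      f"clusters: {result.report['n_clusters']}, "
      f"mask area: {result.report['mask_area']} px")
print(f"JSC={report.jsc:.3f}  DM={report.dm:.3f}  HD={report.hd:.2f} px  MCR={report.mcr:.3f}%")
```

prints

```
superpixels: 1893, clusters: 2, mask area: 3841 px
JSC=0.996  DM=0.998  HD=1.00 px  MCR=0.023%
```

i.e. the pipeline found two tissue regions (mass and background), and the
recovered mass overlaps the ground truth at Jaccard 0.996 with a worst-case
boundary error of one pixel. `phantom_suite_config()` differs from the
package defaults only in the NLM filtering degree, matched to the phantoms'
speckle level via `suggest_h` (see `docs/methods.md`).

The same pipeline is available from the shell:

```bash
massdelim phantom --n 20 --out-dir suite/ --seed 1          # images + masks + manifest
massdelim segment suite/phantom_000.png --out mask.png      # one image -> mass mask
massdelim evaluate suite/manifest.csv --out metrics.csv     # pipeline + metrics CSVs
massdelim denoise input.png --out denoised.png --h 250
massdelim superpixels input.png --out labels.png --boundaries overlay.png
```

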