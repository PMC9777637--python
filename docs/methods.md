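# Methods

`massdelim` delimits hypoechoic breast masses in B-mode ultrasound with a
classical three-stage pipeline — speckle denoising, intuitionistic-fuzzy
superpixel over-segmentation, and density-based superpixel clustering —
followed by overlap/boundary metrics. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
phantoms do and do not demonstrate.

## Nonlocal Means denoising

Ultrasound speckle is multiplicative and non-Gaussian, so the first stage is
the edge-preserving Nonlocal Means filter: each pixel becomes a weighted
average of the pixels in a square search window, with weights

    w(i, j) ∝ exp(−‖x(N_i) − x(N_j)‖² / h²),

normalized per pixel to sum to 1. `N_k` is the (2r+1)×(2r+1) patch centered
on k (mirror padding at borders). The patch distance is the plain
(unweighted) squared Euclidean norm; no Gaussian kernel and no noise-variance
offset are applied, which is why `skimage`'s NLM variant is *not* used — its
weights are patch-size-normalized and variance-shifted and would not satisfy
the oracle equivalence the tests enforce.

Parameters (all user-overridable):

- `patch_radius = 3` (7×7 patches) and `search_radius = 10` (21×21 window).
  The windowed sum is the standard tractable realization; `full_search=True`
  forces the literal sum over every pixel and is only practical for small
  images.
- `h = 10` on the [0, 255] scale as a conservative default. Because the
  patch distance is an *unnormalized* SSD, the useful scale of `h` grows
  with patch size and noise: between two patches of the same homogeneous
  region E‖·‖² = 2σ²P (P patch pixels), so `suggest_h` returns
  `h = σ·√(2P)`. For the 16-look phantoms (σ ≈ 25–40 gray levels)
  `phantom_suite_config()` uses h ≈ 248; cross-edge distances at contrast
  ~100 are then still ~8× larger than h², so edges survive.

The windowed implementation decomposes the SSD field per search offset into
a shifted squared difference plus a box filter, which is arithmetically
identical (to ~1e−15) to the naive quadruple loop; the tests assert 1e−9
agreement on random images.

## Intuitionistic fuzzy transform

Each denoised intensity is mapped to a triple (μ, ν, π): membership by
global min–max normalization, non-membership by the Sugeno-type generator
ν = (1−μ)/(1+(e^λ−1)μ), hesitancy π = 1−μ−ν. λ ∈ [0, 1] (default 0.5, the
midpoint of its admissible range) controls how much "uncertainty mass" is
carved out at intermediate intensities; λ = 0 reduces to an ordinary fuzzy
set with π ≡ 0 (the implementation uses `expm1` so this holds bit-exactly).
Constant images are rejected with an explicit error rather than silently
mapped: the min–max denominator vanishes and no membership is defined.
Distances in this domain are the squared Euclidean norm over the triple.

## Superpixels by local IFCM

Seeds are placed at the centers of a regular grid with step
S = round(√(MN/K)) (K defaults to 1000); the effective seed count
⌈M/S⌉·⌈N/S⌉ may differ slightly from K. Each pixel competes only among
centroids whose seed lies within a 2S×2S window around it — the SLIC-style
localization — and the fuzzy c-means functional

    J = Σ_l Σ_k u_lk^γ · d(x_l, v_k)

is minimized by alternating the exact update equations for U (exponent
1/(γ−1)) and for the prototypes (u^γ-weighted means of the *member pixels'*
triples). Because the candidate structure is fixed and both updates are
exact minimizers, J is non-increasing across iterations; the tests assert
this on every run. Defaults: γ = 2, `max_iter` = 10, `tol` = 1e−4 on the
largest prototype component movement. Ten sweeps rarely reach `tol` but are
enough for labels to stabilize; non-convergence is logged, not raised.

Numerical choices:

- The distance carries no spatial term; locality comes only from the
  windows, so boundaries lock onto intensity edges.
- Hard labels are the per-pixel membership argmax, ties to the lowest
  centroid id. A pixel whose squared distance to some candidate is ≤ 1e−15
  is treated as coincident with it and assigns full membership to the
  *spatially nearest* such centroid (ties again to lowest id). The spatial
  tie-break matters only in exactly-flat regions, where all converged
  prototypes agree to within float rounding: it yields a clean SLIC-like
  tiling there instead of an id-ordered collapse, and it makes K = L with
  zero iterations the identity labeling.
- A connectivity pass then absorbs fragments smaller than S²/4 pixels into
  the adjacent superpixel with the most similar mean triple (ties: larger
  region, then lower id). Similarity-based absorption was chosen over
  size-based absorption because the largest neighbor of a boundary sliver
  is often on the *other* side of the edge; merging by similarity provably
  cannot undo edge adherence. Every surviving connected component becomes
  its own compactly-numbered superpixel, so labels always form connected
  regions and sizes sum to the pixel count.

## Density-based clustering of superpixels

Each superpixel is summarized by its centroid: the mean (μ, ν, π) triple,
by default concatenated with (row/M, col/N)·0.5. DBSCAN with Euclidean
distance then groups centroids: core if ≥ ϑ centroids (self included) lie
within δ; clusters are the transitive closure of core–core δ-reachability;
non-core centroids within δ of a core are border and adopt the cluster of
their first core neighbor in ascending id (deterministic); the rest is
noise. Defaults δ = 0.12, ϑ = 4, tuned on the speckle phantoms and
documented as such: δ must exceed the residual post-denoising IFS spread of
same-tissue centroids (~0.05) while staying below the mass/background
separation (~0.4 in μ alone); the 0.5-weighted coordinates keep remote
look-alike tissue from merging outright without breaking chains of adjacent
same-tissue centroids (adjacent centroid spacing contributes only ~0.016).

The mass cluster is the non-noise cluster with the lowest size-weighted mean
raw intensity — masses are hypoechoic — overridable by cluster id or
"largest". Border superpixels of the chosen cluster are included by default
(`--strict-exclude-border` keeps cores only, which leaves jagged
under-segmentation but is available as the stricter reading). The union of
the chosen superpixels is reduced to its largest connected component and
hole-filled, matching the single-mass output convention of the annotated
datasets this pipeline targets.

## Metrics

JSC = |X∩Y|/|X∪Y|, DM = 2|X∩Y|/(|X|+|Y|), MCR = 100·|X≠Y|/L, and the
symmetric Hausdorff distance over full foreground pixel coordinate sets
(pixel units, 0-based (row, col); `boundary=True` restricts to boundary
pixels). Conventions real data never hits: two empty masks give
JSC = DM = 1 and MCR = 0; HD raises on an empty mask. HD is computed with
`scipy.spatial.distance.directed_hausdorff`; tests check it against an
all-pairs max–min oracle.

## Synthetic phantoms: what they emulate, what they do not

A phantom is a two-level template — hypoechoic mass (default 55) on a
brighter background (default 160) — multiplied pixelwise by unit-mean
Gamma(L, 1/L) noise, the fully-developed L-look intensity speckle model
(CV = 1/√L; default L = 16, i.e. 25% speckle, "moderate"); a unit-mean
Rayleigh amplitude option is included. The ground truth is the exact
rasterized geometry, computed before noise is drawn. Benign phantoms are
smooth ellipses; malignant phantoms perturb the elliptical radius with
random harmonics of order 2–7 (1/j amplitude decay, total perturbation
clipped at ±45%) at roughness 0.35 — markedly irregular margins, the
clinical hallmark of malignancy. The bundled 20-image suite randomizes
semi-axes U(22, 45) px, center jitter ±10%, mass intensity U(40, 70), and
background U(140, 180) at 256×256.

These phantoms exercise the pipeline's contracts, determinism, and noise
behavior. They do **not** model PSF convolution, depth attenuation,
shadowing, heterogeneous tissue texture, or multiple/absent masses —
passing on phantoms therefore shows the machinery is correct under the
stated noise model, not that clinical-grade accuracy transfers to real
scans, where intensity overlap between mass and tissue is far larger.

## Problem sizes and reproducibility

Every stage is deterministic: fixed inputs and configuration reproduce the
output mask bit-identically (asserted end-to-end). The test suite and the
acceptance script work at 64×64 (superpixel invariants, 100 images),
256×256 (end-to-end suite, 20 images), and ≤16×16 (oracle equivalences) —
sizes chosen so every oracle can be brute-forced and the whole suite runs
in a few minutes on one core. `scripts/acceptance.py --seed S --out F`
regenerates the suite from the given seed and reports grouped mean
JSC/DM/HD/MCR plus the NLM MSE reduction.

## Known limitations

- One mass per image by construction (largest-component retention).
- The darkest-cluster heuristic fails on anechoic artifacts darker than the
  mass (e.g. acoustic shadows); `--select-cluster` exists for that reason.
- With the spec-level default h = 10 the NLM stage barely smooths strong
  speckle (weights collapse); match h to the noise with `suggest_h`.
- DBSCAN defaults assume mass/background contrast well above the residual
  post-denoising spread; very low-contrast lesions may come out as a single
  cluster or as noise.
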