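# npgtv — non-local patch graph total variation denoising

`npgtv` removes additive Gaussian noise from single-channel 2-D images —
micrographs, tomographic slices, or any grayscale photograph — while
preserving edges, textures and fine repetitive structure that classical
local total-variation (TV) denoisers tend to smooth away. It is usable both
as a Python library and as a small command-line tool, e.g. as a
preprocessing stage ahead of segmentation or particle picking.

## The method

The observation model is `u0 = u + z`, with `z` i.i.d. zero-mean Gaussian
noise of standard deviation σ (quoted in gray levels on the 8-bit scale).
Denoising proceeds in two stages:

1. **Non-local patch graph.** Every pixel becomes a graph node whose feature
   is its vectorized s×s intensity patch concatenated with its center
   coordinates scaled by a spatial-constraint weight λ:
   `v'_i = (v_i, λ·i_row, λ·i_col)`. Each node is joined to its K nearest
   feature-space neighbors (exact Euclidean KNN, symmetrized by union) with
   Gaussian-kernel weights `w(i,j) = exp(−d²(i,j)/σ_k²)`. At λ = 0 the graph
   is purely intensity-based and fully non-local; large λ makes it local.

2. **Constrained graph-TV recovery.** With the graph total variation
   `‖f‖_TV = Σ_i [Σ_{j∈N_i} W_ij (f(i)−f(j))²]^{1/2}`, the clean image is
   estimated as

       argmin_u ‖u‖_TV   s.t.   ‖u − u0‖₂ ≤ ε,

   solved by Douglas–Rachford splitting: the fidelity-ball indicator
   contributes a radial projection, the TV term a proximal map computed by
   an accelerated dual projected-gradient scheme, and the two are alternated
   through the relaxed reflection update until the relative change of the
   iterate falls below tolerance. The graph is built once — never rebuilt
   across iterations.

Default parameters adapt to the noise level: patch size 5 for σ ≤ 15 and 9
above, K = 5, λ = 0.05, kernel bandwidth `σ_k² = 0.2·s²·(σ/255)²`, and
fidelity radius `ε = (σ/255)·√n` (the expected noise-field norm).

Quality is reported as PSNR (`10·log10(255²/MSE)`, peak 255) and SSIM.

## Worked example

```bash
python examples/denoise_phantom.py
```

generates a 64×64 piecewise-constant phantom, contaminates it with σ = 25
noise, and denoises it with default parameters:

```
noisy input : PSNR  20.88 dB  SSIM 0.2825
NPGTV       : PSNR  33.34 dB  SSIM 0.9731  (200 iterations)
grid TV     : PSNR  26.72 dB  SSIM 0.9337
```

PSNR rises by about 12 dB over the noisy input (roughly a 16-fold reduction
in mean squared error), and the non-local graph beats the purely local
grid-TV baseline — run through the identical solver — by more than 6 dB
because patch similarity links distant pixels of the same region, so region
interiors are averaged without blurring their shared boundaries. SSIM close
to 1 indicates the region structure is essentially restored.

The same run from the shell:

```bash
npgtv simulate --kind piecewise --size 64 --regions 4 --noise-std 25 --seed 7 \
               --out noisy.png --clean clean.png
npgtv denoise  --in noisy.png --out denoised.png --noise-std 25
npgtv evaluate --ref clean.png --test denoised.png
```

Every `simulate`/`denoise` run writes a `<output>.run.json` snapshot of all
resolved settings, sufficient to replay the run exactly.

Other examples: `examples/graph_total_variation.py` (the discrete operators
and smoothness functionals), `examples/prox_and_solver.py` (proximal maps,
closed forms and solver limits), `examples/quality_metrics.py` (PSNR/SSIM).

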