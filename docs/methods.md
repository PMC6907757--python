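# Methods

## Model and assumptions

The denoiser assumes additive i.i.d. zero-mean Gaussian noise on a
single-channel image with intensities stored in [0, 1]. Noise levels are
quoted on the 8-bit scale (σ gray levels out of 255) and divided by 255
internally; the "dB" phrasing sometimes attached to such levels in the
literature is treated as a standard-deviation label, not a decibel quantity.
The noise level is an input — the package does not estimate it from the
image.

The prior is graph-signal smoothness: pixels are graph nodes, and the graph
total variation

    ‖f‖_TV = Σ_i ‖∇_i f‖₂,    ‖∇_i f‖₂ = [Σ_{j∈N_i} W_ij (f(i) − f(j))²]^{1/2}

is minimized subject to the fidelity ball ‖u − u0‖₂ ≤ ε. The constrained
form is scale-invariant in the weights (rescaling W rescales the objective
but not the minimizer), which makes it robust to the absolute magnitude of
the Gaussian-kernel weights.

The edge derivative is implemented as `sqrt(W_ij)·(f(j) − f(i))`. With that
convention the local variation equals the Euclidean norm of the edge
derivatives at a node, so the three quantities (derivative, local
variation, TV) are mutually consistent; the alternative convention with
W_ij appearing linearly in the derivative would break that identity. Only
the local-variation/TV formulas affect the solver.

## Graph construction

- Patch features: overlapping s×s patches at stride 1, boundary patches
  completed by numpy `symmetric` (edge-including mirror) padding — the
  MATLAB `padarray('symmetric')` convention. The feature vector appends
  λ·row, λ·col of the patch center.
- `coord_mode`: `raw` (default) multiplies λ onto 0-based pixel indices,
  the literal augmented-feature formula; `normalized` divides indices by
  the image extent first, which keeps λ·coordinate within the gray range
  for any image size. Both are provided because the two readings circulate;
  nothing downstream depends on which is chosen, only the λ scale does.
- KNN is exact. The brute-force backend (default up to 10⁴ nodes) sorts
  each row of the full distance matrix with a stable sort, which realizes
  the deterministic tie-break "ascending node index" exactly; the cKDTree
  backend is exact in distances and used above that size. Identically-zero
  feature columns are stripped before the distance computation (a
  mathematical no-op) so that the λ = 0 graph is bitwise identical to an
  intensity-only patch graph. An approximate-NN backend could be plugged in
  for very large images but is deliberately not shipped: tests and results
  use exact search only.
- Directed KNN edges are symmetrized by union, preserving minimum degree K
  and connectivity; self-matches are excluded.
- Kernel bandwidth: σ_k² = 0.2 · s² · (σ/255)², i.e. 20% of the per-patch
  summed noise variance. This reading of the "20% of the sum of the noise
  variance" rule is uncertain, so σ_k is always user-overridable; for σ = 0
  a fallback bandwidth of 0.1 is used since the formula degenerates.
- The 4-/8-connected unit-weight lattice (`grid_graph`) feeds the same
  solver to give the classical-TV baseline; it is the local degenerate case
  of the patch graph.

## Solver

Douglas–Rachford splitting on f₁ = ‖·‖_TV, f₂ = indicator of the ball:

    x_n     = P_ball(y_n)
    y_{n+1} = y_n + λ_n · (prox_{γ f₁}(2x_n − y_n) − x_n)

starting at y₀ = u0, stopping when ‖y_{n+1} − y_n‖/‖y_{n+1}‖ < tol (absolute
change if the denominator vanishes) or after `max_iter` iterations. The
returned signal is the ball projection of the final y — the feasible
iterate — rather than y itself, which need not satisfy the constraint at
truncation. A garbled fixed-point identity in the source literature is
resolved to the standard DRS identity prox_{f₂}y = prox_{f₁}(2·prox_{f₂}y − y).

The TV proximal map has no closed form. It is computed on the dual: with D
the per-node stacked weighted difference operator (rows −√W_ij, +√W_ij; one
row per directed edge, grouped by owning node), the dual problem maximizes
⟨Dᵀq, y⟩ − ½‖Dᵀq‖² over q whose per-node blocks lie in balls of radius γ.
FISTA-accelerated projected gradient with step 1/‖D‖² (operator norm from
50 power iterations, inflated by 10⁻⁷ for safety) solves it, and the primal
is recovered as u = y − Dᵀq. Because the primal objective is 1-strongly
convex, the duality gap certifies both objective error and iterate distance;
iteration stops when gap ≤ inner_tol·(1 + |primal|). A primal-dual
(Chambolle–Pock) variant was evaluated first but recovers the primal only
at O(1/k) after the dual has converged; the dual formulation reaches the
two-node closed form to machine precision in tens of iterations.

Defaults (the literature reports none): γ = 0.1, λ_n = 1.0, relax margin
0.01, tol = 10⁻⁴, max_iter = 200, inner_iter = 50, inner_tol = 10⁻⁶.
γ rescales the prox subproblem but not the fixed point; λ_n in [0.5, 1.5]
changes the path, not the limit (tested). The fidelity radius, when not
given, is ε = τ·(σ/255)·√n with τ = 1: E‖z‖₂² = n·(σ/255)² for the noise
model, so the ball just encloses the clean image in expectation.

Parameter policy: patch size 5 for σ ≤ 15 (the boundary value 15 itself
takes the small patch), 9 above; K = 5; λ = 0.05, the midpoint of the
recommended [0.01, 0.1] range. The final image is clipped to [0, 1]; the
optimizer itself is unconstrained in range.

## Synthetic data

The generator emulates the Gaussian-contamination setting on three phantom
families: `piecewise` (Voronoi cells with distinct constant levels — the
cartoon model where TV regularization is exact), `ramp` (smooth gradient),
and `texture` (band-limited sinusoidal fields standing in for repetitive
fine structure). Noisy outputs are clipped to [0, 1], a choice the source
setting leaves open. What the phantoms do **not** emulate: natural-image
patch statistics, correlated or signal-dependent noise (Poisson,
detector artifacts), and rich oriented textures — so passing tests
demonstrate correctness of the machinery and strong denoising on
cartoon-like content, not benchmark-grade performance on photographs.
Published benchmark comparisons on standard test images (Cameraman, Lena,
Barbara, …) are not reproduced: the images are copyrighted and the per-image
tuning and noise seeds behind such tables are unreported.

The study condition used by `scripts/acceptance.py` and the end-to-end
tests is a 64×64, 4-region piecewise phantom at σ = 25 — small enough to
run the exact-KNN path and a full solve in seconds, large enough for stable
PSNR statistics.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng(seed)`; unseeded
  noise models are rejected, and every pipeline run is bit-reproducible.
- ε = 0 collapses the ball to {u0}: the solver returns u0 exactly. γ = 0
  makes the TV prox the identity. Kernel weights that underflow to zero are
  dropped rather than stored (reachable only with extreme bandwidths).
- Metric conventions: PSNR always uses peak 255; MSE = 0 is reported as
  infinite PSNR with a flag, not an error. Global SSIM uses unbiased
  (n−1) variance/covariance estimators and c₁ = (0.01·255)², c₂ =
  (0.03·255)²; windowed SSIM (the default) averages 11×11 Gaussian-weighted
  windows (σ = 1.5) via scikit-image.
- Image I/O quantizes with round-half-up; 8-bit round trips are accurate to
  half a quantization step (1/510).

## Limitations

- Complexity is dominated by the exact KNN (quadratic in pixel count on the
  brute path); megapixel images need the kd-tree backend or an external
  approximate-NN step, and memory for the full patch-feature matrix.
- The method needs the noise level as input and assumes it homogeneous.
- Single-channel only; color handling is out of scope.
- The DRS outer loop with the default iteration caps yields an approximate
  constrained minimizer; tight-accuracy studies should raise `max_iter`,
  `inner_iter` and lower the tolerances (the oracle tests do).
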