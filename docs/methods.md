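# Methods

## Overview

`pointscape` converts co-registered multi-temporal raster imagery into
marked spatial point patterns and analyses them with marked point process
statistics. The chain is: patch tiling → temporal label propagation →
CNN patch classification → patch-centre point pattern → summary-function
estimation against Monte Carlo null models. This note records the models,
the estimators, the defaults and the design decisions, and what the
synthetic generator does and does not establish.

## Coordinate and tiling conventions

All geometry is in **pixel units**: Cartesian frame with the origin at the
raster's top-left corner, x along columns, y along rows (y increases
downward), windows half-open [0, X) × [0, Y). Point process statistics are
orientation-invariant, so the downward y-axis is harmless. A scene tiles
into floor(H/w)·floor(W/w) disjoint w×w patches; trailing rows/columns not
filling a full patch are **dropped, not padded**, keeping all patches
identically sized and the grid regular. Patches never overlap — an
overlapping stride would manufacture artefactual short-range point
structure. The centre of cell (i, j) is (j·w + w/2, i·w + w/2), the
centroid of the patch's pixel footprint under the half-open convention.

No physical scale is attached: source imagery metadata on metres-per-pixel
is often inconsistent, so all distances are pixels and any physical scale
is a display-time factor supplied by the user.

## Synthetic scene series (the stated world)

The generator emulates the one property the augmentation scheme relies on:
*a series of co-registered images of one landscape, each differently
affected by sensing conditions, with an immutable underlying class map.*

- **Class map**: either `voronoi` (each grid cell takes the class of its
  nearest of L·k random sites; compact patchy regions) or
  `smoothed-threshold` (Gaussian-smoothed white noise cut at L−1 equal
  quantiles; diffuse gradients). Both appear in real mosaics. If a feasible
  draw misses a class it is retried a bounded number of times.
- **Rendering**: each patch is its class's mean color plus i.i.d. Gaussian
  texture noise (default sd 10 on a 0–255 intensity scale). Default
  palette: six well-separated colors standing for forest, water, field,
  residence, sand, bare soil.
- **Replicate perturbation**: affine intensity change (multiplicative gain,
  sd 0.05; additive offset, sd 8), white noise (sd 8), optional Gaussian
  blur (off by default). Defaults are "moderate": clearly visible, far from
  destroying class separability. This minimal family emulates
  illumination/atmospheric variation without modelling it physically —
  no radiative transfer, clouds, seasonal phenology, co-registration error,
  or spatially correlated noise.
- **Reproducibility**: one config seed feeds a `SeedSequence` split into
  independent streams per scene.

A green test on this world shows the pipeline's logic and estimators are
correct, and that label propagation helps when replicates differ by
label-preserving perturbations. It does **not** establish performance on
real satellite imagery, where class textures overlap and perturbations are
structured.

## Temporal label propagation

Every labeled reference cell contributes one identically labeled patch per
scene: n labeled cells and k replicates yield exactly n·(k+1) patches.
Split assignment is **per grid cell** (largest-remainder rounding of the
fractions over the shuffled cell list), so the (k+1) near-identical
temporal copies of a cell can never straddle train/test — per-patch
assignment would trivially inflate test accuracy. Pseudo-labeling of
additional scenes uses the classifier's argmax with an optional
`min_confidence` threshold (default none: pure argmax); pseudo-labeled
patches carry a `provenance` flag so they are never confused with manual
or propagated labels.

## Patch classifier

A LeNet-style CNN adapted to small inputs: 3×3 conv (16 filters, ReLU,
same padding) → 2×2 max-pool → 3×3 conv (32, ReLU) → 2×2 max-pool →
dense 64 (ReLU) → softmax(L). Minimal input size is 4 (two 2× poolings).
Training protocol: Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), batch size 256,
30 epochs, learning rate 1e-3 (the conventional Adam default, exposed in
the spec). Patch intensities are standardized per channel with
training-set statistics stored in the model. Class imbalance is handled by
plain empirical risk; per-class recall is reported so imbalance is
visible. Ties in argmax and top-k resolve toward the lowest class index
(stable sort).

The network is implemented directly in NumPy (im2col convolution, explicit
backprop) so the package has no deep-learning framework dependency; at
10×10 patches it trains ~3,000 patches × 30 epochs in ~10 s on one CPU.
Wider architectures can be substituted through the same duck interface;
on the synthetic benchmark a doubled-width variant changes test accuracy
by well under 5 percentage points, consistent with large-scale features
dominating such imagery.

## Point patterns and their estimators

Replacing each classified patch by its centre point produces a **lattice**
pattern: nearest-neighbour distances are exactly w, so Clark–Evans R ≈ 2
and K̂ steps at r = w. This is inherent to the construction, documented,
and the reason summary functions should be read at r > w; the scientific
content lives in the marks.

Estimators (n points, window area |W|, pair weights e(u,v)):

- **K̂(r) = |W|/(n(n−1)) Σ_{u≠v} 1(d ≤ r) e(u,v)**. Corrections: `none`
  (e ≡ 1), `translation` (e = |W|/((X−|dx|)(Y−|dy|)), unbiased on
  rectangles), `toroidal` (wrap-around distances, for exact tests on
  synthetic data). Default: translation.
- **K̂_ij** sums ordered pairs (u ∈ type i, v ∈ type j) normalised by
  |W|/(n_i n_j); for i = j it reduces exactly to K̂ of the sub-pattern;
  symmetric corrections give K̂_ij = K̂_ji.
- **ĝ(r) = |W| Σ k_h(d − r) e / (2πr · n(n−1))** with the Epanechnikov
  kernel. The pair-intensity normalisation uses n(n−1)/|W|² (not (n/|W|)²)
  so the CSR expectation is exactly 1 conditional on n.
- **Bandwidth**: Stoyan's rule h = 0.15/√λ̂ for g, p_lm and k_mm, always
  recorded in the output.
- **Ĵ = (1−Ĝ)/(1−F̂)**. Ĝ is the Hanisch border-corrected
  nearest-neighbour cdf (cumulative sum of positive weights ⇒ monotone by
  construction, unlike the reduced-sample form); F̂ is the reduced-sample
  empty-space cdf on a ≥100×100 regular dummy grid. Values with F̂ = 1
  are reported as NaN, never interpolated. J is intrinsically noisy where
  1−G is tiny; read it at small r.
- **Clark–Evans**: R = d̄_obs·2√λ̂, z = (d̄_obs − d̄_exp)/se with
  se = 0.26136/√(nλ̂); no Donnelly adjustment — the toroidal metric is the
  recommended way to remove edge bias in tests.
- **p̂_lm(r)**: kernel-weighted ratio over ordered pairs
  Σ 1(m_u = l, m_v = m) k_h(d−r) / Σ k_h(d−r). This form guarantees
  Σ_{l,m} p̂_lm = 1 wherever the denominator is positive, and symmetry
  p̂_lm = p̂_ml for the symmetric kernel. Independent marking gives
  p_l·p_m.
- **k̂_mm(r)**: kernel-weighted mean pair product of numeric marks,
  normalised by the mean product **over all distinct pairs** (not the
  squared mean mark) — this makes the constant-mark identity k̂_mm ≡ 1
  exact at finite n. A zero mean pair product is a validation error.
- **Envelopes**: pointwise rank-th extremes over n_sim seeded simulations;
  `CSR` resimulates uniform locations conditioned on n (marks discarded,
  hence refused for mark statistics), `random_labeling` permutes marks on
  fixed locations.

### Numerical evaluation

Kernel sums are evaluated exactly — no distance binning. The Epanechnikov
kernel is quadratic in d, so Σ w·k_h(d−r) over the pairs in [r−h, r+h]
follows from prefix sums of w, w·d, w·d² on the distance-sorted pair list:
O((n² + m) log n²) total rather than O(n²·m), and equal to the naive
double loop to ≤1e-10 (verified against independent loop-written oracles
on every statistic). K̂ uses the same sorted-prefix machinery with
indicator weights, making monotonicity in r structural.

Degenerate inputs: empty mark selections yield valid empty patterns with a
warning; empty kernel denominators and the F̂ = 1 tail are NaN; K and
mark statistics require n ≥ 2; r grids are validated against half the
shorter window side.

## Null models

Poisson (and the conditional CSR-given-n variant), Matérn cluster
(parents on the ρ-dilated window so the offspring process is stationary
inside W; expected retained count κμ|W|), simple sequential inhibition
(exact, fast; chosen over Strauss/MCMC since only the qualitative
repulsion regime is needed), and mark randomisation (permute / i.i.d.).
All are deterministic under a fixed seed and produce points strictly
inside their windows; CSR passes its own Clark–Evans test at the nominal
5% rate.

## Known limitations

- Real-imagery accuracies are not reproducible here: reference data of
  that kind are not redistributable, and the synthetic world is easier
  than Landsat-class imagery. Published per-dataset patch counts also
  imply a non-integer replication factor, so dataset sizes are exposed as
  explicit parameters (k, filtering) rather than matched.
- The classifier is CPU-scale by design; no transfer learning or
  compound-scaled architectures (plug-in interface only).
- Estimators are homogeneous only; no inhomogeneous K/g, no model fitting
  (Gibbs/cluster likelihoods), no spatio-temporal statistics.
- Sub-patch point placement is out of scope: one point per patch, at its
  centre.
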