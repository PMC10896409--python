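# Methods

## Model

A profiled section is a graph G = (V, E): one node per spot, an edge when
either spot is among the other's K nearest neighbours in physical space
(union symmetrisation; Euclidean distance; distance ties broken by spot
index). K defaults to `round(ratio_neighbors · √n)` with
`ratio_neighbors = 1` — for a lattice this connects each spot to roughly
its √n nearest ring, which keeps the graph's diameter and the spectral
resolution balanced as sections grow. The combinatorial Laplacian
L = D − A is symmetric positive semi-definite; its eigenvalues are the
frequencies of the tissue and its orthonormal eigenvectors the Fourier
modes. The smoothness identity μₖᵀLμₖ = λₖ (total variation of a mode
equals its eigenvalue) is what justifies reading eigenvalue order as
frequency order.

Expression is preprocessed gene-wise by depth normalisation (counts per
million by default) and a natural `log(1 + x)` transform; genes expressed
in fewer than 10 spots are dropped. The graph uses only the coordinates, so
normalisation and graph construction commute.

A gene's spatial signal f is represented by its Fourier coefficients
f̂ = Uᵀf. The zero-frequency modes (one per connected component; eigenvalue
0 within 1e−8) carry only per-component means and are excluded from all
spatial statistics.

## SVG detection

Two complementary statistics:

**GFTscore** = Σₖ e^(−λₖ) · w̃ₖ over nonzero frequencies, where
w̃ₖ = |f̂ₖ| / Σᵢ|f̂ᵢ| (absolute values; the normalisation is over nonzero
frequencies as well). The score is scale-invariant, lies in (0, 1), and
decreases as energy moves to higher frequencies. Genes are ranked by score
and the cutoff y_z is the Kneedle knee of the descending score curve
(convex shape, decreasing direction, sensitivity S = 6); if no knee exists
the 90th percentile is used, with a warning.

**Band test.** The spectrum is split into a low- and a high-frequency band
by applying Kneedle to the ascending eigenvalue curve. That curve is
S-shaped on spot graphs — a steep shoulder of low frequencies, a long
plateau near the degree bulk, and a convex rise into the extreme tail — so
the low-band scan uses the concave shape in the increasing direction (it
finds the early shoulder; on a Visium-scale lattice of 2 704 spots it
yields 149 low-frequency modes, the right order for such sections) and the
high-band scan uses the convex shape on the reversed, decreasing curve (the
tail elbow). Fallback is ⌈n/10⌉ per band with a warning, and the bands are
clipped to stay disjoint. A one-sided Wilcoxon rank-sum test then asks
whether the gene's low-band |FC| stochastically exceed its high-band |FC|;
p-values use the exact null distribution for band totals up to 60 (the
data are continuous so ties are absent, and at these sizes the normal
approximation has a measurable lattice bias) and the tie- and
continuity-corrected normal approximation above that. Benjamini–Hochberg
adjustment across genes gives q-values.

A gene is an SVG when GFTscore > y_z **and** q < α (default 0.05). Genes
with no energy outside the zero modes get score 0, p = 1, and are excluded
from the Kneedle curve.

Under the null of i.i.d. Gaussian spot signals, f̂ = Uᵀf is again i.i.d.
Gaussian, the two bands are exchangeable, and the rank-sum p-value is
uniform — the calibration the test suite checks by simulation. The test's
power depends on how much of the low band a pattern can populate: a
pattern with feature scale ℓ fills modes up to index ≈ n·(unit/ℓ)², so
near-one-dimensional patterns (straight stripes, linear gradients) occupy
only O(√m) of the first m modes of a two-dimensional section and are
systematically hard for a median-rank comparison even when their GFTscore
is high. This is a known limitation, inherited from the test's design.

## Signal enhancement

The denoised signal minimises ‖f\* − f‖² + c·f\*ᵀLf\*; the closed form is
f\* = U(I + cΛ)⁻¹Uᵀf, i.e. coefficient-wise shrinkage by 1/(1 + cλₖ).
Defaults c = 0.005 and `ratio_fms = 15` (truncation to the first
`round(ratio_fms·√n)` coefficients before the inverse transform) follow the
Visium regime; `keep_all=True` disables truncation and reproduces the exact
minimiser, which the tests verify against a dense linear solve. The filter
never increases energy, preserves the component means when untruncated, and
produces smoothness that is non-increasing in c. Outputs may contain small
negative values (the filter is linear); clipping at zero is opt-in, never
silent.

## FTU identification

SVGs are embedded by their low-frequency FC vectors and clustered by
Louvain community detection on a cosine-similarity KNN gene graph
(k = min(15, n_svg − 1), union-symmetrised, edge weights clipped at zero,
fixed RNG seed). For each gene cluster, the pseudo-expression of a spot is
the sum of log1p expression over the cluster's genes; a 1-D 2-means with
deterministic min/max initialisation splits the spots and the high-mean
side is the cluster's FTU. The Louvain resolution is scanned over a grid
(0.2 to 3.0 in steps of 0.2 by default) and the resolution minimising the
mean pairwise overlap 2·Σ_{k<l}|Sₖ∩Sₗ|/(m(m−1)) is kept (ties go to the
smaller resolution; resolutions yielding fewer than two clusters are
skipped). FTUs may overlap — polyfunctional regions are allowed — the
objective only discourages redundant partitions.

## Frequency features for external methods

Four standalone building blocks, deliberately free of any host framework's
training loop: (i) `spot_fc_features` transforms the spot cosine-similarity
matrix XXᵀ into the frequency domain and keeps the first n_fc rows
(default 1000, capped at n) for concatenation onto an expression matrix;
(ii) `fc_cost_matrix`/`fuse_costs` build a cosine-distance cost between
annotation and spot FC profiles and blend it with a base optimal-transport
cost as βC + (1−β)C_update (default β = 0.8); (iii)
`frequency_similarity_terms` returns gene- and spot-level cosine-similarity
sums in the frequency domain (with the full basis the gene term provably
equals its vertex-domain counterpart — orthonormal transforms preserve
inner products — which the tests assert numerically); (iv)
`spreading_entropy` is the Shannon entropy of f̂ₖ²/‖f̂‖² summed over
channels: 0 for a one-hot spectrum, log n_fc for uniform spread.

## Synthetic data: what it emulates and what it does not

The generator produces a Visium-like lattice (optional jitter and
offset rows), planted mean surfaces, per-spot log-normal depth factors
(σ = 0.3, stressing the CPM step), and Poisson or negative-binomial counts
(variance μ + μ²/dispersion), all driven by one seeded generator so
datasets are bit-reproducible.

The benchmark's study conditions model **deeply expressed regional
markers**: planted baselines are log-uniform on 20–40 counts with 10–16×
enrichment inside the pattern, and null genes are constant with baselines
log-uniform on 20–100 counts (spot totals ≈ 3 × 10⁴, the depth of a well-
sequenced section). Planted kinds default to multifocal hotspots (7–10
Gaussian foci, radius 1.2–1.7 lattice units — a marker of a cell
population scattered over niches) with a minority of curved belts
(sinusoidal centerline — a curved layer). Two deliberate design points:

* The kind mix excludes linear gradients by default. Gradients are
  spatially organised but concentrate in fewer than five modes, which the
  median-rank band test cannot distinguish from noise at desk-scale
  section sizes; including them would measure that known limitation, not
  detection quality. `pattern_surface` still provides gradients for users
  who want them.
* With 500 genes, 50 strong markers measurably modulate spot totals, and
  depth normalisation transfers that modulation to every other gene — the
  deepest "null" genes then genuinely vary spatially (a compositional
  effect that real panels dilute across ~15 000 genes). The planted mass
  is therefore kept small enough that this modulation stays below the
  null genes' shot-noise floor.

Passing tests on this generator show the pipeline recovers smooth,
k-bandlimited, marker-strength patterns under Poisson noise and depth
variation; they do not speak to segmentation artefacts, spot-size
diffusion, gene–gene correlation beyond shared surfaces, or shallow
(<5 counts) expression regimes, where the log-CPM discreteness dominates.

The FTU fixture plants two disjoint sharp circular compartments (discrete
boundaries, like germinal centers) with 20 member genes each; truth is the
compartment spot set.

## Numerical choices

* Eigendecomposition: dense symmetric (`eigh`) up to n = 5000; above that,
  the lowest and highest eigenpairs via an iterative solver, and the band
  test operates on those partial bands. Eigenvector signs follow a
  largest-|entry|-positive convention (ties to the lowest index) so output
  is bit-identical across runs.
* Zero-eigenvalue tolerance 1e−8; eigenvalues within it are floored at 0.
* Kneedle is implemented directly (unit-square normalisation, canonical
  concave-increasing mapping, difference curve, first local maximum whose
  drop exceeds S·mean-x-step); the x-axis is the index, not the eigenvalue.
* 2-means initialises centers at the min and max, making the FTU spot
  split deterministic and invariant to increasing affine transforms.
* SSIM uses global min-max rescaling of each image to [0, 1], dense 8×8
  sliding windows (stride 1), sample (ddof = 1) variance and covariance,
  stabilizers C1 = (0.01)², C2 = (0.03)², C3 = C2/2, and unit exponents;
  variance and covariance share one code path so `ssim(img, img)` is
  exactly 1.
* Benchmark problem sizes (20×20 and 15×15 lattices, 500 and 300 genes,
  10 000 null draws for calibration) are chosen so the full suite and the
  acceptance script run in seconds on one CPU while keeping every band and
  test in its asymptotically meaningful regime.

## Known limitations

* Spectra, and therefore FC vectors, are not comparable across different
  sections (different graphs, different mode spaces); no cross-sample
  alignment is attempted.
* The band test is weak against patterns that are strongly bandlimited to
  a handful of modes (gradients, straight thin stripes) and at small
  section sizes generally; the GFTscore ranks such genes highly but the
  q-value gate may still exclude them.
* Depth normalisation is compositional: strong spatial markers induce
  weak inverse patterns in all other genes. This is a property of the data
  model, not of the detector, and appears in real sections as well.
* The partial-eigendecomposition path for n > 5000 approximates the band
  test's view of the spectrum by its two ends; mid-spectrum coefficients
  are unavailable there by design.
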