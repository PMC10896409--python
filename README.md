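# sgft — spatial graph Fourier transform toolkit

`sgft` analyses spatial omics data (spot-based transcriptomics such as
Visium, or protein images summarised per pixel) in the **frequency domain of
the tissue itself**. The spots of a section, with their (x, y) positions,
define a K-nearest-neighbour graph; the eigenvectors of its Laplacian
**L = D − A** are the tissue's Fourier modes (FMs) μ₁, μ₂, …, μₙ and the
eigenvalues λ₁ ≤ λ₂ ≤ … ≤ λₙ are their frequencies. A gene's expression
vector f over the spots becomes a vector of Fourier coefficients (FCs)

    f̂ = Uᵀ f,    U = [μ₁ … μₙ],

and spatial organisation becomes a spectral property: a spatially coherent
gene is (approximately) *k-bandlimited* — its energy concentrates in the
low-frequency modes — while a spatially random gene spreads energy evenly.

Everything the package does builds on that representation:

* **Spatially variable genes (SVGs)** — each gene gets a
  `GFTscore = Σₖ e^(−λₖ) · |f̂ₖ| / Σ|f̂|` (zero-frequency mode excluded); the
  Kneedle inflection point of the ranked score curve gives a cutoff, and a
  one-sided Wilcoxon rank-sum test of low-band vs high-band |FC| with
  Benjamini–Hochberg FDR control gives a q-value. A gene is an SVG when it
  clears both.
* **Signal enhancement** — the closed-form minimiser of
  ‖f\* − f‖² + c·f\*ᵀLf\* is the low-pass filter
  f\* = U (I + cΛ)⁻¹ Uᵀ f, optionally truncated to the first
  `round(ratio_fms·√n)` coefficients before the inverse transform.
* **Functional tissue units (FTUs)** — SVGs are Louvain-clustered on their
  low-frequency FC vectors; each cluster maps to a spot set through its
  pseudo-expression and a deterministic 1-D 2-means split, and the Louvain
  resolution is chosen to minimise the mean pairwise FTU overlap.
* **Frequency features for other methods** — FC feature augmentation of a
  spot-similarity matrix, fused cosine-distance transport costs
  (βC + (1−β)C_update), frequency-domain cosine similarity terms for
  alignment objectives, and the spreading entropy of squared-normalised FCs
  as a bandlimitedness regulariser.
* **Synthetic data with ground truth** and the benchmarking metrics
  (Jaccard/precision/recall/F1/Tversky, ARI, windowed SSIM) used to
  evaluate all of the above.

## Worked example

Simulate a 15×15 section with 20 planted spatial genes among 200, call
SVGs, and score the calls against the ground truth:

```bash
sgft simulate --out-dir demo --nx 15 --ny 15 --n-svg 20 --n-null 180 --seed 7
sgft svg      --expr demo/expression.tsv --coords demo/coords.tsv --out demo/svg.tsv
sgft evaluate --predicted demo/svg.tsv --truth demo/truth.tsv --out demo/metrics.tsv
```

which prints

```
wrote 200 genes x 225 spots to demo
18/200 genes called SVG -> demo/svg.tsv
jaccard=0.900 recall=0.900 -> demo/metrics.tsv
```

`demo/svg.tsv` records, per gene, the GFTscore, its rank, the band-test
p-value and q-value, and the SVG call, under a `#` header listing the run
parameters (K = 15 neighbours, Kneedle sensitivity S = 6, 28 low- and 22
high-frequency modes, α = 0.05, score cutoff 0.0147). 18 of the 20 planted
genes are recovered with no false positives (precision 1.0, recall 0.9).

The same steps are available as library calls:

```python
import sgft

ds    = sgft.make_benchmark(n_svg=20, n_null=180, grid=(15, 15), seed=7)
expr  = sgft.normalize(sgft.filter_genes(ds.raw, min_spots=10))
graph = sgft.build_knn_graph(expr.coords)
basis = sgft.eigendecompose(sgft.laplacian(graph))
table = sgft.identify_svgs(expr, graph, basis)       # pandas DataFrame
```

`sgft enhance`, `sgft ftu` and `sgft features` expose the low-pass filter,
the FTU pipeline and the FC feature matrix the same way; every run writes a
JSON manifest with all parameters so results can be reproduced exactly.

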