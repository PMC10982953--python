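# spotdecon

Cell-type deconvolution and spatially aware simulation of spatial
transcriptomics (ST) data via graph co-embedding.

Sequencing-based ST platforms (10X Visium and kin) measure expression
at spots that each cover several cells, so every spot is a cell-type
mixture; imaging-based platforms resolve single cells but detect few
genes. `spotdecon` addresses both limits with one self-supervised
model, for computational biologists who have an scRNA-seq reference
and an ST slide from the same tissue:

* **Deconvolution** — estimate, for every spot, the fraction of each
  reference cell type it contains.
* **Gene recovery** — predict the spatial distribution of transcripts
  the ST panel did not measure.
* **Simulation** — generate benchmark ST data with exact per-spot
  ground truth, either structure-free (pooled pseudo-spots) or
  preserving the spatial expression pattern of a reference slide.

## Model

Let S ∈ ℝ^{n×g} be the ST counts (spots × genes) and C ∈ ℝ^{m×g} the
per-type reference profiles (sums of library-normalized cells over the
top-200 one-vs-rest marker genes per type). The goal is a
row-stochastic mapping matrix M ∈ ℝ^{n×m}, M_ij ≥ 0, Σ_j M_ij = 1,
with M·C ≈ S. The pipeline:

1. **Co-embedding.** X = [C; S] is encoded into a shared
   30-dimensional latent space by a variational autoencoder trained on
   the ELBO (Gaussian reconstruction, closed-form KL to 𝒩(0, I));
   downstream steps use the posterior mean.
2. **Link graph.** Mutual k-nearest-neighbor edges (k = 20, Euclidean
   latent distance) between spots and between types and spots — never
   type–type — weighted by w_ij = 1 − d_ij / max(d).
3. **Co-GCN.** A two-layer graph convolution
   Y = softplus(Â·relu(Â X W⁽⁰⁾)·W⁽¹⁾) with
   Â = D̃^{−1/2}(A+I)D̃^{−1/2}; the spot block of Y, row-normalized, is
   M. Training minimizes
   L = (1/g)·Σ_genes[(1−PCC)+(1−COSSIM)](MC, S)
     + (1/n)·Σ_spots[(1−PCC)+(1−COSSIM)](MC, S),
   i.e. the model supervises itself on how well M·C reconstructs S.
4. **Recovery.** M·C_full, with C_full over all reference genes,
   predicts genes absent from training; a 10-fold cross-validation
   over ST genes quantifies that capability.

Evaluation uses the standard deconvolution metric suite — PCC, scalar
SSIM, cosine similarity, RMSE, Jensen–Shannon divergence (base 2) per
spot or gene, and the average rank score (ARS) across methods — plus a
spatial-expression-correlation statistic that measures how expression
similarity between spots decays with distance.

See `docs/methods.md` for assumptions, parameter defaults and
numerical choices.

## Worked example

Plant known structure, pool cells into pseudo-spots, deconvolve, and
compare with the known composition:

```python
import spotdecon as sd

cfg = sd.SyntheticConfig(seed=7)          # 5 types x 600 cells x 1500 genes
sc = sd.make_synthetic_scrna(cfg)
sim = sd.simulate_regular(sc, n_spots=200, seed=11)

mapping = sd.deconvolve(sc, sim.to_spatial(), sd.RunConfig(seed=3))
print(mapping.to_frame().head(3).round(3))

table = sd.evaluate_deconvolution(
    mapping.to_frame(),
    sim.proportions.loc[mapping.spot_ids, mapping.type_names])
print(table.loc["mean"].round(3))
```

Output (about a minute on one core):

```
       type0  type1  type2  type3  type4
spot0  0.056  0.069  0.396  0.420  0.059
spot1  0.158  0.193  0.237  0.224  0.188
spot2  0.316  0.187  0.072  0.199  0.225
PCC       0.889
SSIM      0.869
COSSIM    0.977
RMSE      0.054
JSD       0.044
Name: mean, dtype: float64
```

Each row of the mapping is one spot's estimated cell-type composition
(rows sum to 1): spot0 is roughly a type2/type3 mixture. The summary
row says the estimates correlate with the known truth at mean per-spot
PCC 0.889 with mean RMSE 0.054 — each spot's composition is recovered
to within a few percentage points per type.

The same API simulates spatially structured slides
(`sd.simulate_spatial`, hexagonal binning of VAE-placed cells), adds
neighbor-diffusion noise (`sd.add_neighbor_noise`), blurs
single-cell-resolution slides into bins (`sd.blur_bins`), and
cross-validates gene recovery (`sd.crossval_gene_recovery`).

A `spotdecon` command-line tool wraps the library
(`deconvolve`, `recover-genes`, `simulate-regular`, `simulate-spatial`,
`add-noise`, `blur`, `evaluate`, `make-synthetic`); every subcommand
takes a YAML config plus `--seed`/`--out` and writes its artifacts,
resolved config and log into the output directory. Inputs may be h5ad,
an MTX + genes/barcodes triplet, or dense CSV/TSV.

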