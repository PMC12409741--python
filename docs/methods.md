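# Methods

This note describes what `fclatent` computes and the conventions it commits
to. Everything here is implemented in the package and exercised by the test
suite; equations are stated in the package's own notation.

## 1. Synthetic cortex and BOLD cohort (`fclatent.synthetic`)

**Mesh.** Each hemisphere is a unit sphere sampled with a Fibonacci spiral
plus a small seeded angular jitter, giving `n_per_hemisphere` well-separated
vertices. A polar cap containing `round(medial_wall_fraction * n)` vertices
per hemisphere is flagged as the medial wall and excluded from every
analysis; the remaining vertices are the *cortex*.

**Parcellation.** Seeded parcel centers per hemisphere induce a Voronoi
partition of the cortex into contiguous parcels. Parcels are grouped into
networks (labels `Net0`, `Net1`, ...); a configurable number of parcels may
be left unassigned (label `"None"`), mirroring atlases in which some parcels
carry no network membership. Every network receives at least one parcel.

**BOLD model.** Each network has one latent time course per (subject,
session); the series at a vertex of network *k* is

```
x_v(t) = gamma_s * w * course_k(t) + noise_sd * eps_v(t)
```

with `w` the within-network weight, `gamma_s` a per-subject FC-strength
scalar, and iid Gaussian vertex noise. Two planted individual effects make
the cohort scientifically useful:

- **Trait (identity):** a fraction `p_swap` of each subject's parcels is
  reassigned to a different network. The reassignment is drawn once per
  subject and persists across sessions, so subjects are re-identifiable.
- **Covariate (strength):** `gamma` may vary across subjects (e.g. linearly
  in a planted age), shifting overall FC magnitude.

Randomness is organized with splittable seed streams: each subject owns an
independent stream spawned from the cohort seed, so enlarging the cohort
never perturbs earlier subjects, and regenerating with the same spec is
bit-identical.

## 2. Seed-based FC profiles (`fclatent.fc`)

An FC profile is the vector of Pearson correlations between one seed time
series and every cortical vertex. Seeds may be a single vertex, a parcel
(unweighted mean of member series), or a network (elementwise mean of its
parcels' profiles). Zero-variance target vertices are flagged and assigned
0; a zero-variance seed is an error. Training sets draw
`ceil(fraction * n_cortex)` vertex seeds per subject from per-subject seeded
streams; every profile carries provenance (subject, session, seed vertex).

## 3. Sphere-to-grid reformatting (`fclatent.reformat`)

Each hemisphere is resampled onto an `H x W` grid uniform in azimuth
`a = atan2(y, x)` and in `s = sin(elevation)` (equal-area vertically). Pixel
centers follow the half-offset convention

```
a_j = -pi + (j + 0.5) * 2*pi / W,     s_i = -1 + (i + 0.5) * 2 / H.
```

Both directions are nearest-neighbour: a pixel takes the value of the
nearest vertex of its hemisphere (invalid, and exactly 0, if that vertex is
on the medial wall); a vertex reads back the pixel of its containing cell,
with azimuth wrapped modulo `W`. Because azimuth is periodic, all
convolutions pad circularly along width and with zeros along height. When
the grid is dense relative to the mesh (roughly `H*W >= 4x` the vertex
count) each cortex vertex owns its own cell and `from_grid(to_grid(v)) == v`
holds exactly; a jittered mesh can occasionally place two vertices in one
cell, which costs exactly those vertices and nothing else.

## 4. The beta-VAE (`fclatent.vae`, `fclatent._nn`)

**Architecture.** Per hemisphere, the encoder applies a stride-2 convolution
with an 8x8 kernel, then the two hemisphere feature maps are combined (by
channel concatenation, or optionally summation) and passed through four more
stride-2 convolutions with 4x4 kernels and ReLU activations. A fully
connected layer outputs `2N` numbers per sample: the posterior mean `mu` and
log-variance (clipped to ±15) of an `N`-dimensional Gaussian. The decoder
mirrors the encoder with transposed convolutions that are exact adjoints of
the forward convolutions, ending in one 8x8 transposed convolution per
hemisphere.

**Loss.** With `sigma = exp(logvar / 2)` and `z = mu + sigma * eps`,
`eps ~ N(0, I)`:

```
L = sum over valid pixels of (x - x_hat)^2
  + beta * 0.5 * sum_d (mu_d^2 + sigma_d^2 - 1 - ln sigma_d^2),
```

averaged over the batch. The KL term is the closed form for Gaussian
posterior against a standard-normal prior (verified in tests against
numerical integration). Medial-wall pixels are excluded from the
reconstruction term.

**Training.** The whole network — convolutions via im2col, their adjoints,
backpropagation, and Adam — is implemented in NumPy inside the package and
verified against central finite differences (worst relative gradient error
below 1e-4 across sampled parameters of every layer type). The learning
rate decays by `lr_decay_factor` (default 10x) every `lr_decay_every`
epochs. The full-scale preset uses a 192x192 grid, channels
(32, 64, 128, 256, 512), batch 128, lr 1e-4, 50 epochs with decay every 20;
`VAEConfig.small()` is a desk-scale preset (32x32 grid, narrow layers,
batch 32, lr 1e-3, 10 epochs) used by the examples and tests. Shuffling and
the reparameterization draws come from seeded streams, so training is
bit-reproducible on a given machine. Models serialize to a single `.npz`
(JSON config + weight tensors + loss trace) and reload bit-exactly.

## 5. Latent analyses (`fclatent.analysis`)

- **Silhouette.** Per sample, `SI = (b - a) / max(a, b)` with `a` the mean
  distance to own-network samples (self excluded) and `b` the smallest mean
  distance to another network. Correlation distance (`1 - r`) is used for
  vertex-space FC profiles, Euclidean distance for latent embeddings.
  Per-network means get percentile 95% confidence intervals by
  bootstrapping subjects (default 1000 draws).
- **Dispersion.** Mean squared Euclidean distance of a parcel's embeddings
  to their centroid (mean, not sum, so values compare across sample
  counts); the SNR is the inter-subject / intra-subject ratio.
- **Fingerprinting.** A session barcode is either the strictly lower
  triangle of a symmetric connectome or the concatenated latent means of
  all parcels. The similarity matrix is the Pearson correlation of
  session-1 vs session-2 barcodes; accuracy averages the two argmax
  identification directions, and exact ties are counted.
- **Subclustering.** Seeded k-means (default k=2, 10 restarts) over a
  network's per-subject parcel embeddings, with an optional per-parcel
  cluster-probability table; centroids can be pushed through the decoder.
- **Trait correlation.** Pearson r of each (parcel, latent dimension)
  against each trait, with Benjamini–Hochberg linear step-up FDR applied
  within each (dimension, trait) family across parcels (missing scores
  dropped pairwise).
- **Covariate prediction.** Ridge regression over 15 log-evenly spaced
  regularization strengths in [1e-8, 1e3]; each of `n_repeats` seeded
  repeats draws an 80/20 split, picks the strength by 5-fold CV on the
  training portion, refits, and scores Pearson r on the held-out fifth.
  Epsilon-insensitive SVR is available behind `model="svr"`.
- **Density maps.** 2-D histograms of latent points, Gaussian-smoothed and
  normalized to total mass 1, so cohort maps on a shared grid subtract
  cleanly.

## 6. I/O and pipeline (`fclatent.io`, `fclatent.cli`)

Meshes, cohorts, profiles and resampling maps are HDF5 with a `kind`
attribute for content-based dispatch; parcellations and embeddings are TSV;
surfaces and decoded vertex maps export to GIFTI (`.surf.gii` /
`.func.gii`) per hemisphere. `run_pipeline` chains
simulate → fc → reformat → train → embed from a validated JSON config
(unknown keys rejected) and writes a manifest with a SHA-256 hash of every
artifact; rerunning the same config reproduces the embeddings exactly. The
`fclatent` command line is a thin wrapper over these functions.
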