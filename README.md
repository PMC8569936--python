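# tomo3d

Analysis pipeline for **RNA tomography (tomo-seq)**: genome-wide expression
profiling by RNA-seq of serial cryosections cut along three orthogonal
planes, reconstructed into a 3D "digital expression" model of the specimen.
The approach suits large embryos and organ explants — for example the
embryonic head of the catshark *Scyliorhinus canicula*, where a
section-based method resolves broad territories (forebrain subdivisions,
left–right asymmetries, midline domains) without needing cellular
resolution.

The package takes per-plane count tables (genes × sections, with ERCC
spike-in rows) and a binary volume mask, and provides:

- **Detection and normalization** (`tomo3d.profiles`) — the "≥ 4 reads in
  ≥ 2 sections" detection filter, and per-section normalization against the
  total spike-in count, which removes section-to-section capture
  variability.
- **3D reconstruction** (`tomo3d.reconstruction`) — digitization of a
  grayscale mask stack to section resolution, harmonization of the three
  plane totals (the series come from different specimens), and per-gene
  reconstruction by **iterative proportional fitting (IPF)**: starting
  uniform on the mask, each plane's slabs are rescaled in turn so their
  sums match that plane's 1D trace, until all three marginals agree.
- **Spatial screens** (`tomo3d.spatial`) — **Moran's I** over the 26-voxel
  (3×3×3 cube) neighborhood with analytic (Cliff–Ord randomization
  variance) or permutation inference, the five-sector classification of the
  (I, p) plane, and all-pairs **Pearson correlation** over in-mask voxels
  for co-expression ranking.
- **Synthetic phantoms** (`tomo3d.synthetic`) — head-like masks, planted
  territory classes (blob, gradient, left-restricted, midline stripe,
  salt-and-pepper, uniform), and forward-simulated count tables with
  spike-ins and Poisson noise, retaining ground truth for validation.
- **Orchestration** (`tomo3d.pipeline`, `tomo3d` CLI) — YAML-configured
  end-to-end runs with checksummed manifests, and digital-section PNG
  export with additive color overlays.

## The statistics in brief

For gene *g* with normalized trace $m_p(s)$ along plane *p*, IPF iterates

$$x_v \leftarrow x_v \cdot \frac{m_p(s)}{\sum_{u \in \text{slab}_p(s)} x_u}
\quad \text{for } v \in \text{slab}_p(s),$$

cycling planes (transverse, horizontal, sagittal) until the worst marginal
mismatch, relative to the gene's total, falls below `tol` (default 1e-6).

Regionalization is screened with Moran's index over in-mask voxels,

$$I = \frac{N}{W}\,
\frac{\sum_{ij} w_{ij}(x_i-\bar x)(x_j-\bar x)}{\sum_i (x_i-\bar x)^2},$$

with binary 26-neighbor weights ($W = \sum_{ij} w_{ij}$), expectation
$E[I] = -1/(N-1)$, and a one-sided upper-tail p-value. The default screen
keeps genes with $I > 0.1$ whose p-value underflows to zero, flagging genes
with total digital expression below 100 as unreliable.

## Worked example

```python
from tomo3d import (SimulationConfig, make_dataset, normalize_by_spikein,
                    reconstruct_all, build_weights, coexpression_ranking)
from tomo3d.spatial import moran_screen_table

config = SimulationConfig(shape=(30, 33, 34), noise_model="poisson", seed=0)
truth, tables = make_dataset(
    config, {"blob": 5, "midline_stripe": 2, "salt_and_pepper": 5}
)
profiles = {plane: normalize_by_spikein(table)[0] for plane, table in tables.items()}
model = reconstruct_all(truth.mask, profiles)
screen = moran_screen_table(model, build_weights(truth.mask))
print(screen[["I", "neg_log_p", "total_digital_expression", "passes"]].round(3))
ranking = coexpression_ranking(model, "midline_stripe_001", cor_min=0.4)
print(ranking.to_frame().round(3))
```

prints

```
                         I  neg_log_p  total_digital_expression  passes
gene
blob_001             0.992        inf                  9946.917    True
blob_002             0.980        inf                 10026.418    True
blob_003             0.956        inf                 10066.663    True
blob_004             0.948        inf                  9999.710    True
blob_005             0.998        inf                  9968.352    True
midline_stripe_001   0.917        inf                 10006.912    True
midline_stripe_002   0.939        inf                  9968.795    True
salt_and_pepper_001  0.215        inf                 10097.661    True
salt_and_pepper_002  0.165        inf                 10048.392    True
salt_and_pepper_003  0.263        inf                  9958.418    True
salt_and_pepper_004  0.226        inf                 10025.479    True
salt_and_pepper_005  0.300        inf                  9923.589    True
                    gene    Cor
rank
1     midline_stripe_002  0.966
```

Compact territories reconstruct with very high autocorrelation (I ≈ 0.95),
and the second midline gene is correctly retrieved as the top co-expression
partner of the first (Cor = 0.966, above the 0.4 screening threshold).
Note the salt-and-pepper genes: their *reconstructions* also show modest
positive I (≈ 0.2), because three 1D marginals cannot encode dispersed
single-voxel structure — IPF returns a nearly flat field whose residual
slab-level fluctuations autocorrelate. Dispersal is only distinguishable on
volumes that actually resolve it (see `docs/methods.md`); screened on the
ground-truth fields, the same salt-and-pepper genes give I ≈ 0 and fail the
screen while every blob gene passes.

A command-line interface mirrors the library
(`tomo3d simulate | normalize | reconstruct | screen | correlate | export |
run-all`); see `tomo3d --help`.

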