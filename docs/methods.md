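# Methods

This note documents the models, conventions, numerical choices, and known
limitations of the package. It describes what the code computes; every
empirical statement here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Coordinate and sectioning conventions

Volumes are arrays indexed `(sagittal, horizontal, transverse)`, i.e.
(left→right, dorsal→ventral, posterior→anterior). Section ids are 1-based
in those orientations; the default grid is (30, 33, 34) sections — a
catshark-head-scale experiment with 18 µm sections, so voxels are 18 µm
cubes at the intersection of one section from each plane. A count table
stores one row per gene plus one row per ERCC spike-in species
(ids prefixed `ERCC-`), with columns `section_001…section_NNN`.

## Detection and spike-in normalization

A gene is *detected* in a plane when at least `min_sections` (default 2)
sections carry at least `min_reads` (default 4) raw reads; detection
precedes normalization and the model-wide gene list is the union over
planes. Normalized values are

    value(g, s) = counts(g, s) / spikein_total(s) × scale_reference,

where `spikein_total(s)` sums the spike-in rows in section *s* and
`scale_reference` is the plane's mean spike-in total. Dividing by the
spike-in total removes per-section capture efficiency exactly (spike-in
input is constant per section); the plane-level rescale merely keeps
magnitudes commensurable with raw counts and cancels in every downstream
shape-dependent statistic. Only the *total* spike-in count is consumed;
species identities are irrelevant to normalization.

Sections whose spike-in total is zero cannot be normalized. They become
*missing* (NaN), not zero — zeros would fabricate expression troughs — and
are excluded from reconstruction updates; if more than 20% of a plane's
sections are affected the table is rejected outright. Plane-level QC
reports per-section spike-in totals and the output/input recovery ratio
when the input amount is declared.

## Mask digitization

A grayscale confocal stack is binarized (Otsu by default, or a fixed
threshold), block-averaged down to one voxel per section triple,
re-binarized at 0.5 occupancy, and reduced to its largest connected
component. On a synthetic ellipsoid at 4× section resolution this
preserves the volume fraction to within 5% (asserted in tests). A
degenerate (empty) mask is an explicit error at every stage.

## Harmonization and iterative proportional fitting

The three section series come from three different specimens, so one
gene's plane totals differ. Before fitting, each plane with a positive
total is rescaled to the arithmetic mean of the positive totals (the
*common total*). The arithmetic mean was chosen over the geometric mean
because it remains defined when a plane total is zero. A plane with zero
total for a gene carries no shape information and is excluded from the fit
(flagged in the convergence report); a gene silent in all three planes
yields an all-zero volume flagged `skipped`.

Reconstruction initializes x_v = 1 on in-mask voxels (the maximum-entropy
start: no spatial prior beyond the mask) and cycles planes in the fixed
order transverse, horizontal, sagittal. For each section the in-slab
voxels are multiplied by `m_p(s) / M_p(s)` where `M_p(s)` is the current
slab sum. Conventions for degenerate slabs:

- `m_p(s) = 0`: the slab is zeroed, permanently (multiplicative updates
  cannot revive it; supports intersect).
- `M_p(s) = 0` with `m_p(s) > 0`: an *infeasibility event* is counted and
  the slab stays zero. This is expected with inconsistent replicate
  specimens and is reported, not raised.
- missing sections: excluded from updates and from the convergence check.

Iteration stops when the worst |M_p(s) − m_p(s)| over active planes and
valid sections, normalized by the common total, drops below `tol`
(default 1e-6), or after `max_iter` (default 200) cycles. The
per-cycle discrepancy history is recorded; on feasible inputs it is
non-increasing near convergence (asserted in tests). The stopping rule and
its constants are this package's choices; with them, 50-gene phantom
batches on the default grid converge in a few cycles and marginals match
inputs to < 1e-5 of the total. For exactly separable truths (outer
products on a cuboid) the uniform start converges to the independence
solution, which is the truth itself, to ~1e-15 relative. Reversing the
plane update order moves converged volumes by less than 100·tol.

## Moran's I screen

Weights are binary and symmetric: w_ij = 1 when voxel *j* lies in the
3×3×3 cube centered on *i* (both in-mask, i ≠ j), giving 1–26 neighbors
per voxel. Row-standardized weights are available as an option — index
bands shift slightly between styles, so the style in use is recorded with
the results — but binary symmetric is the default and the one all reported
numbers use.

Inference is one-sided (upper tail): the screen targets positive
autocorrelation, i.e. regionalized expression. The analytic test uses the
Cliff–Ord randomization (permutation-moment) variance with the sample
kurtosis correction, then a normal approximation; the permutation test
uses p = (1 + #{I_perm ≥ I_obs})/(1 + n_perm). `-ln(p)` is reported as
infinite when p underflows to exactly zero at double precision — the
"null p-value" regime that, with I > 0.1, defines the default screen.
No multiple-testing correction is applied by default (the screen reports
raw p-values plus an index threshold); a Benjamini–Hochberg option exists.

Calibration, measured on a 6³ mask: null p-values from permuted fields are
KS-uniform, and on smooth fields (white noise filtered with a Gaussian of
σ = 1 voxel, the scale of the 3×3×3 neighborhood) the analytic p agrees
with a 20,000-draw permutation p within Monte-Carlo error. A caveat found
during validation: for *weakly* smoothed fields in the moderate-significance
regime (p ~ 0.005–0.02) the normal approximation deviates from the
permutation reference by several Monte-Carlo standard errors at N ≈ 216.
Genome-scale screens operate at N ≈ 10⁴ voxels where the approximation is
far tighter, and the default screen only consumes the underflow regime; for
borderline p-values the permutation method is the reference.

Constant fields (e.g. a strictly uniform gene, or an all-zero volume) have
an undefined index; they are reported `unscreenable`, never silently
dropped, and constancy is tested on the values themselves (`ptp == 0`)
rather than on the centered sum of squares, which can be a nonzero
rounding residue. Genes with total digital expression below 100 are
flagged low-expression: with so little mass the index estimate is
unreliable.

Sector classification of the (I, −ln p) plane follows five bands used to
sample genes of increasing regionalization: sectors 1–3 are index bands
alone (0.01 < I < 0.02, 0.06 < I < 0.07, 0.09 < I < 0.1), sectors 4 and 5
require p-underflow with 0.1 < I < 0.2 and 0.6 < I < 0.7. The sector-2
band is interpreted as a positive-index band (its printed source carries a
stray minus sign that would contradict the ordering of the sectors by
increasing autocorrelation).

## Co-expression ranking

Pearson correlations between gene pairs are computed over **in-mask voxels
only**: out-of-mask voxels are structurally zero for every gene and would
inflate every correlation. Pairs involving a constant gene are undefined
and reported missing. Rankings exclude the reference gene, default to the
Cor ≥ 0.4 screening threshold, and are invariant under per-gene positive
affine rescaling of volumes (Pearson invariance; asserted in tests).

## Synthetic phantoms: what they emulate, and what not

The generator reproduces the statistical structure the pipeline assumes:
a connected head-like mask (union of ellipsoids inscribed in the grid so
every section contains tissue, in-mask fraction validated in [0.10,
0.90]); six territory classes; per-section expected counts proportional to
slab sums of the truth, scaled so each gene's plane total equals
`mean_depth` (default 10⁴ reads per gene per plane) and multiplied by
per-section capture efficiencies; an 8-species spike-in ladder at fixed
relative abundances with 5 000 expected reads per section; and optional
Poisson counting noise. With `noise_model="none"` tables hold exact
real-valued expectations so that slab mass is conserved to machine
precision — rounding would break the conservation properties the
reconstruction tests rely on.

Territory classes: *blob* — a connected region grown voxel-by-voxel to a
target fraction of the mask, with amplitude decaying to half at the
territory edge (graded boundaries, as in real expression domains);
*gradient* — a linear ramp along a random axis and direction;
*left_restricted* — a squared-cosine peak whose center and width are
jittered per gene but whose support provably stays within 3× the peak
fraction of the left–right axis; *midline_stripe* — a jittered
squared-cosine stripe about the sagittal midline; *salt_and_pepper* —
independent Bernoulli voxels (single-cell-scale dispersal, the class
spatial autocorrelation is designed to reject); *uniform* — constant on
the mask (and deliberately unscreenable). Poisson was chosen over
negative binomial for counting noise: each section pools thousands of
cells, making overdispersion secondary; the noise model is a single
extension point. `embryo_jitter` applies a small random affine warp per
plane to emulate non-identical replicate specimens; its default is 0
because the magnitude of real inter-embryo variation is not characterized.

What the phantoms do **not** emulate: sequence-level artifacts (mapping,
barcodes, UMIs), RNA degradation, section loss, imperfectly orthogonal
sectioning planes, and mask/specimen mismatch. Passing phantom-recovery
tests therefore validates the algorithmic chain, not robustness to those
experimental artifacts.

## Screening dispersal: truth fields versus reconstructions

Three 1D marginals cannot encode dispersed single-voxel structure. The
IPF reconstruction of a salt-and-pepper gene is necessarily a nearly flat
field whose residual slab-level fluctuations (inherited from the binomial
noise of the true marginals) are themselves spatially structured — entire
slabs share a multiplicative factor — so its Moran's I lands around
0.2–0.3 regardless of how small the fluctuations are (the index is
scale-free). Class-separation validation of the screen is therefore
performed on volumes that resolve the pattern (the ground-truth fields,
via `model_from_truth`): there, blob genes score I ≈ 0.9 with underflowed
p while salt-and-pepper genes score I ≈ 0 and never pass the I > 0.1 cut.
On real reconstructions, an elevated index certifies regionalized
*digital* expression; distinguishing true dispersal from flat expression
requires data at the voxel scale, which is a structural limit of
three-plane tomography, not of the statistic.

## Problem sizes used in validation

Validation runs use the default (30, 33, 34) grid (~13 000 in-mask voxels)
for reconstruction and screening experiments, 50-gene batches for marginal
consistency, 20-gene batches for blob recovery (5 Poisson replicates),
random masks up to 6³ against O(N²) brute-force oracles (100 instances),
20 000-draw permutation tests on 6³ masks for calibration (50 fields, plus
500 permuted null genes for KS uniformity), and 10 replicate phantoms for
the planted co-expression experiment. These sizes make the full validation
suite run in well under a minute while keeping every estimate's
Monte-Carlo error far below the decision thresholds it is compared to.
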