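# Methods

## Problem and pipeline

The package segments 2-D multimodal MR brain-tumor slices. Per modality
the pipeline is: anisotropic-diffusion denoising → Dirichlet-process
mixture (DPM) clustering with a Markov-random-field (MRF) label prior,
sampled by collapsed Gibbs → selection of the tumor cluster. The two
modalities are then fused: the T1C tumor cluster is the enhancing core
(GTV), edema is the FLAIR tumor region minus the core
(V_edema = {x ∈ V_FLAIR : x ∉ V_T1C}), and the whole tumor is their
disjoint union (CTV = GTV + edema). Composite masks use 0 = background,
1 = edema, 2 = core.

## Denoising

Perona–Malik diffusion, explicit scheme on the 4-neighborhood:
I_s ← I_s + (Δt/4) Σ_p c(|I_p − I_s|)(I_p − I_s). Conductivities:
exponential exp(−(x/q)²) (default) or rational 1/(1+(x/q)²). The 1/4
normalization is fixed for all sites and missing neighbors (boundary or
outside the brain mask) contribute zero flux; since c is even and
pairwise gradients are antisymmetric, fluxes cancel in pairs, so the
pixel sum is conserved exactly and the scheme obeys a discrete maximum
principle for Δt ≤ 1/4.

Defaults: q = 10% of the image dynamic range (intensity units), Δt =
0.25, 10 steps. These are configuration defaults chosen to suppress the
default phantom's noise level while keeping class edges (which exceed q
several-fold); all are exposed in the config/CLI.

## Mixture model

Intensities are univariate; each cluster is Gaussian with unknown mean
and variance under a conjugate normal–inverse-gamma base measure
NIG(μ0, κ0, a0, b0). Cluster parameters are integrated out, so a
cluster's predictive density given its sufficient statistics (n, Σx,
Σx²) is a Student-t with df = 2a_n, location μ_n, and scale²
= b_n(κ_n+1)/(a_n κ_n) under the standard conjugate updates. The n = 0
case is the prior predictive of the "zero component" that creates new
clusters.

Hyperparameter defaults are data-driven: μ0 = mean and b0 = variance of
the unmasked intensities, κ0 = 0.01 (weak mean coupling), a0 = 2 (prior
expected cluster variance equals b0). α = 1 by default and is fixed per
run, not resampled.

## MRF-constrained conditional and sampling

The full conditional of site i over K existing clusters plus one new
cluster multiplies three factors: the CRP mass (n_k or α over
n − 1 + α), the MRF factor exp(λ Σ_{l∈∂(i)} ω_il δ(k, S_l)) on the
4-neighborhood (8 configurable, unit weights), and the collapsed
predictive. A brand-new label matches no neighbor, so its MRF factor is
exactly 1. λ ≥ 0; λ = 0 reduces the conditional to the plain DPM case
(verified to 1e−12 in tests).

A sweep visits the unmasked sites in fixed raster order (random-scan is
a config option), detaches the site, samples from the conditional, and
re-attaches; empty clusters are removed and labels compacted at sweep
end. All randomness flows from a single integer seed, so runs are
bit-reproducible.

**Initialization.** The chain starts with every site in its own cluster
and forms clusters by merging. The alternative single-cluster start is
available (`init="single"`) but is pathological for this sampler: the
probability of opening a new cluster at any one site is at most
α/(n−1+α) times a broad prior-predictive ratio, and the MRF factor
further suppresses a label that matches no neighbor by about e^(4λ), so
nucleation out of one cluster is rare and newly created singleton
clusters are usually reabsorbed in the next sweep. In practice the
single-cluster chain can make no progress at all at image sizes, while
the per-site start reaches a stable labeling in about ten sweeps on the
default phantom.

**Burn-in rule.** The chain is considered stable when the number of
changed assignments per sweep is below 1% of the number of sites for 3
consecutive sweeps (window configurable); the hard cap is 200 sweeps.
The reported segmentation is the label field at the terminating sweep (a
single-sample estimate; posterior aggregation across sweeps is out of
scope). Note the rule measures label churn, not posterior convergence —
for posterior summaries (e.g. the modal cluster count) run the full 200
sweeps and aggregate over the second half of the trace.

**Cost functions.** The label prior uses the binary (Potts-style) cost
−λ Σ ω_il δ(S_i, S_l). The quadratic pairwise-difference cost
Σ ||θ_i − θ_l||² over neighbor parameters is implemented
(`quadratic_cost`) as the continuous-parameter alternative but is not
used by the default pipeline.

## Tumor-cluster selection and fusion

The tumor cluster of a segmentation is chosen by `brightest_mean` (the
cluster with the highest mean intensity inside the brain mask; ties break
to the lowest label index), motivated by contrast enhancement in T1C and
lesion hyperintensity in FLAIR. Clusters smaller than 0.1% of the
labelled area are not eligible: a single-sample Gibbs labelling routinely
contains transient singleton clusters of extreme noisy pixels, which
would otherwise win the mean ranking, while a tumor is a spatially
extended region (if nothing qualifies, the guard is dropped). A `seeded`
strategy (cluster containing a given pixel) is available when the
brightest-cluster heuristic does not apply. No morphological
post-processing is applied by default.

## Metrics

TP/TN/FP/FN are counted pixelwise (optionally restricted to an
evaluation mask; the default is the whole grid, with brain-mask
restriction available as a flag). DSC, Jaccard, sensitivity and
specificity follow the standard definitions; a zero denominator yields
NaN with a warning rather than a silent 0. DSC = 2J/(1+J) holds whenever
both are defined.

## Synthetic phantom

The generator emulates a co-registered FLAIR/T1C slice pair: a disk
brain on dark background, two concentric normal-tissue classes, and a
concentric-disk lesion (core disk inside an edema ring). Class means
(FLAIR: background 5, tissues 70/110, edema 200, core 200; T1C: 5,
80/110, edema 120, core 220) follow the clinical contrast pattern — the
lesion is uniformly FLAIR-hyperintense (edema and core share the top
mean, as FLAIR separates them poorly), and only the core enhances in
T1C. Noise is Rician: A → sqrt((A+n1)² + n2²) with independent
N(0, σ²) draws; the default σ is 5% of the modality's dynamic range,
which leaves adjacent tissue classes ≥ 4σ apart before denoising. The
brain disk is the image mask; background is excluded from clustering.
Ground-truth masks are the exact noiseless disks.

What the phantom does not emulate: anatomy (piecewise-constant disks
instead of cortical structure), bias fields, partial-volume effects,
infiltrative lesion boundaries, and 3-D continuity. Passing tests
therefore demonstrate the correctness of the algorithmic contracts and
behavior under controlled contrast/noise, not clinical performance.

## Numerical choices

* Sufficient statistics are maintained incrementally (count, sum, sum of
  squares) and compacted on cluster deletion; tests verify they equal a
  from-scratch recomputation — exactly on integer-valued intensities
  (where double arithmetic is exact, as for 8/16-bit data) and to 1e−9
  relative on arbitrary floats, since exact equality is not attainable
  in floating point for mixed magnitudes.
* The posterior b_n is computed via the compact form
  b0 + (Σx² + κ0μ0² − κ_n μ_n²)/2 and floored at 1e−300 to guard the
  rare cancellation below zero.
* Per-component Student-t parameters are cached and refreshed on
  attach/detach, making a sweep a handful of vector operations per site;
  the conditional is sampled in log space after subtracting the maximum.
* PNG intensity output is quantized to 16 bits; label PNGs hold at most
  256 labels (NIfTI for more).
* 3-D NIfTI volumes are sliced along the first axis via `slice_index`.

## Problem sizes used in the test suite

Contract tests use 2×2 to 64×64 grids; the end-to-end recovery check
runs the full pipeline on the default 128×128 phantom (noisy and
noiseless); CRP exactness uses 200,000 sequential draws at n = 8 against
the exact Ewens distribution over all 4,140 set partitions; mixture
recovery uses 20 chains of 200 sweeps on 300 points; the smoothing study
uses a 48×48 phantom, 10 seeds, λ ∈ {0, 0.5, 1, 2}.

## Known limitations

* Single-site Gibbs updates: no split–merge moves, so label-space mixing
  relies on the merging dynamics of the per-site initialization.
* One scalar intensity per pixel; modalities are clustered
  independently rather than jointly.
* λ and α are fixed per run, not estimated.
* The burn-in heuristic can fire during a long metastable plateau; the
  200-sweep cap bounds the cost but not the bias of a single-sample
  labeling.
* 2-D only; volumes are processed slice by slice.
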