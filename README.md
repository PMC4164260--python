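# dpmseg

Nonparametric brain-tumor segmentation for multimodal MR slices.

Gliomas appear with different contrast in different MR modalities: the
enhancing tumor core lights up in contrast-enhanced T1 (T1C), while the
surrounding edema is hyperintense together with the core in FLAIR.
`dpmseg` segments each modality with a Dirichlet-process mixture model
(so the number of tissue classes is inferred, not fixed in advance),
regularized by a Markov-random-field smoothness prior on the labels, and
fuses the two segmentations into tumor-core, edema, and whole-tumor
(CTV = GTV + edema) masks. It is aimed at method development and
benchmarking: a synthetic phantom generator with exact ground truth makes
the whole pipeline runnable and testable without any external data.

## Model

Pixel intensities x_i are modeled as a Dirichlet-process mixture

    x_i ~ F(· | θ_i),   θ_i ~ M(θ_i | θ_-i) · P(θ_i),   P ~ DP(α G0),

with F a Gaussian with unknown mean and variance, G0 the conjugate
normal–inverse-gamma base measure, and α the concentration parameter.
Integrating out the random measure gives the Chinese-restaurant-process
conditional: a pixel joins an existing cluster k with prior mass
n_k / (n − 1 + α) and opens a new cluster with mass α / (n − 1 + α).
The MRF factor M uses the Potts-style binary cost

    H(S_i | S_-i) = −λ Σ_{l ∈ ∂(i)} ω_il δ(S_i, S_l),

so exp(−H) multiplies the prior by e^λ per neighbor already carrying the
candidate label; λ = 0 is the unconstrained DP mixture. Inference is
collapsed Gibbs sampling with the cluster parameters integrated out
analytically (Student-t predictives). Before clustering, each image is
denoised with Perona–Malik anisotropic diffusion, which smooths
homogeneous regions while preserving edges stronger than the contrast
parameter q.

The chain is considered burned in once the number of changed label
assignments per sweep stays below 1% of the number of sites for three
consecutive sweeps (cap: 200 sweeps).

Evaluation uses the standard overlap scores: DSC = 2TP/((FP+TP)+(TP+FN)),
Jaccard = TP/(FP+TP+FN), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP).

## Worked example

```python
import numpy as np
from dpmseg import (PhantomSpec, make_phantom, PipelineConfig,
                    run_pipeline)

# a 128x128 co-registered FLAIR/T1C pair with 5% Rician noise
phantom = make_phantom(PhantomSpec(shape=(128, 128), noise_sigma=0.05,
                                   seed=0))
result = run_pipeline(phantom.t1c, phantom.flair, PipelineConfig(seed=0),
                      truth=phantom.truth)
for region, rep in result.metrics.items():
    print(f"{region:6s} DSC={rep.dsc:.4f} Jaccard={rep.jaccard:.4f}")
print("T1C clusters:", result.t1c.labels.n_clusters,
      "sweeps:", len(result.t1c.trace))
```

Output:

```
core   DSC=1.0000 Jaccard=1.0000
edema  DSC=0.9991 Jaccard=0.9981
whole  DSC=0.9993 Jaccard=0.9987
T1C clusters: 4 sweeps: 9
```

The core mask is recovered perfectly and the edema ring to within a few
boundary pixels; the sampler settled on 4 intensity classes for the T1C
slice after 9 Gibbs sweeps. On a noiseless phantom the recovery is exact.

The clustering is also available as a scikit-learn-style estimator:

```python
from dpmseg import DPMRFSegmenter
seg = DPMRFSegmenter(alpha=1.0, lam=1.0, random_state=0)
labels = seg.fit_predict(phantom.t1c)   # 2-D label array, -1 = masked
```

## Command line

Every stage is a subcommand: `dpmseg simulate | denoise | segment |
fuse | evaluate | run`. For example

```sh
dpmseg simulate --out-dir work --size 128 --seed 0
dpmseg run --flair work/flair.png --t1c work/t1c.png \
    --mask-path work/brain_mask.png \
    --truth-core work/truth_core.png --truth-edema work/truth_edema.png \
    --out-dir work/result --seed 0
```

writes the composite mask (0 = background, 1 = edema, 2 = core), the
per-modality label fields and chain traces, and a JSON run log with the
overlap metrics.

## Scope

2-D slices only (volumes are handled slice by slice); no registration,
skull stripping, or bias-field correction. See `docs/methods.md` for the
model details, parameter defaults, and known limitations.
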