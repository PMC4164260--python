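"""Synthetic co-registered FLAIR/T1C tumor phantoms with exact ground truth.

The phantom is a disk "brain" on a dark background containing two normal
tissue classes (a concentric inner/outer split standing in for white and
gray matter) and a concentric-disk lesion: a tumor core disk inside an
edema ring.  Modality contrast follows clinical MR appearance: on T1C
the enhancing core is the brightest class; on FLAIR both core and edema
are hyperintense (they share the top mean, as FLAIR does not separate
them well).  Ground-truth masks are the exact noiseless disks.

Magnitude MR noise is Rician: each noiseless amplitude A is replaced by
sqrt((A + n1)^2 + n2^2) with n1, n2 ~ N(0, sigma^2) independent.  For
A >> sigma this approaches additive Gaussian noise; at A = 0 it is
Rayleigh with mean sigma * sqrt(pi / 2).

Geometry is deliberately analytic (disks) so that ground truth is exact
and every downstream contract can be tested without external data.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fusion import TumorMasks, compose_tumor_masks, edema_mask
from .image_io import IntensityImage

__all__ = ["PhantomSpec", "Phantom", "add_rician_noise", "make_phantom"]

# per-modality class means: background, tissue-1 (outer), tissue-2 (inner),
# edema, core.  FLAIR: lesion (edema + core) brightest; T1C: core brightest.
DEFAULT_TISSUE_MEANS = {
    "flair": {"background": 5.0, "tissue1": 70.0, "tissue2": 110.0,
              "edema": 200.0, "core": 200.0},
    "t1c": {"background": 5.0, "tissue1": 80.0, "tissue2": 110.0,
            "edema": 120.0, "core": 220.0},
}


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, contrast, and noise of one synthetic slice pair.

    noise_sigma is the Rician sigma as a fraction of each modality's
    dynamic range (max minus min class mean); 0.05 means 5%.
    """

    shape: tuple[int, int] = (128, 128)
    tissue_means: dict = dataclasses.field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_TISSUE_MEANS.items()})
    core_radius: float = 12.0
    edema_radius: float = 22.0
    center: tuple[float, float] | None = None
    brain_radius: float | None = None
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center is None:
            self.center = ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)
        if self.brain_radius is None:
            self.brain_radius = 0.45 * min(self.shape)
        if not 0 < self.core_radius < self.edema_radius:
            raise ValueError("need 0 < core_radius < edema_radius")
        if self.edema_radius > min(self.shape) / 2:
            raise ValueError("edema_radius exceeds half the grid size")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclasses.dataclass
class Phantom:
    """A co-registered FLAIR/T1C slice pair plus exact ground-truth masks."""

    flair: IntensityImage
    t1c: IntensityImage
    truth: TumorMasks


def add_rician_noise(image: IntensityImage, sigma: float,
                     rng: np.random.Generator | int | None = None
                     ) -> IntensityImage:
    """Corrupt an image with Rician magnitude noise of scale ``sigma``.

    sigma is in absolute intensity units here; sigma = 0 returns the
    input pixels unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return IntensityImage(pixels=image.pixels.copy(), mask=image.mask,
                              spacing=image.spacing)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n1 = rng.normal(0.0, sigma, image.shape)
    n2 = rng.normal(0.0, sigma, image.shape)
    noisy = np.hypot(image.pixels + n1, n2)
    return IntensityImage(pixels=noisy, mask=image.mask, spacing=image.spacing)


def _disk(shape, center, radius) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _noiseless_modality(spec: PhantomSpec, means: dict,
                        regions: dict) -> np.ndarray:
    img = np.full(spec.shape, means["background"], dtype=np.float64)
    img[regions["tissue1"]] = means["tissue1"]
    img[regions["tissue2"]] = means["tissue2"]
    img[regions["edema"]] = means["edema"]
    img[regions["core"]] = means["core"]
    return img


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the phantom pair; noise uses independent substreams of ``seed``.

    The brain disk becomes the image mask (background excluded from
    clustering); ground truth is the exact noiseless core disk and edema
    ring.
    """
    brain = _disk(spec.shape, spec.center, spec.brain_radius)
    inner = _disk(spec.shape, spec.center, 0.6 * spec.brain_radius) & brain
    whole = _disk(spec.shape, spec.center, spec.edema_radius) & brain
    core = _disk(spec.shape, spec.center, spec.core_radius) & brain
    edema = edema_mask(whole, core)
    regions = {
        "tissue1": brain & ~inner,
        "tissue2": inner & ~whole,
        "edema": edema,
        "core": core,
    }
    truth = compose_tumor_masks(core, edema)
    ss = np.random.SeedSequence(spec.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(2)]
    images = {}
    for stream, modality in zip(streams, ("flair", "t1c")):
        means = spec.tissue_means[modality]
        clean = _noiseless_modality(spec, means, regions)
        dyn = max(means.values()) - min(means.values())
        img = IntensityImage(pixels=clean, mask=brain)
        images[modality] = add_rician_noise(img, spec.noise_sigma * dyn, stream)
    return Phantom(flair=images["flair"], t1c=images["t1c"], truth=truth)
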