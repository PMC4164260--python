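"""Multimodal fusion: per-modality segmentations -> tumor core / edema / CTV.

The enhancing tumor core (GTV) comes from the contrast-enhanced T1 (T1C)
segmentation; FLAIR hyperintensity covers core plus surrounding edema.
Edema is the set difference

    V_edema = { x in V_FLAIR : x not in V_T1C }

and the clinical tumor volume is CTV = GTV + edema.  In saved composite
masks the convention is 0 = background, 1 = edema, 2 = tumor core.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .image_io import IntensityImage, LabelField

__all__ = [
    "TumorMasks",
    "select_target_cluster",
    "edema_mask",
    "compose_tumor_masks",
    "composite_labels",
]


@dataclasses.dataclass
class TumorMasks:
    """Binary core (GTV), edema, and whole-tumor (CTV) masks on one grid.

    Invariants: core and edema are disjoint; whole == core | edema.
    """

    core: np.ndarray
    edema: np.ndarray
    whole: np.ndarray

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=bool)
        self.edema = np.asarray(self.edema, dtype=bool)
        self.whole = np.asarray(self.whole, dtype=bool)
        if not (self.core.shape == self.edema.shape == self.whole.shape):
            raise ValueError("mask shapes differ")
        if np.any(self.core & self.edema):
            raise ValueError("core and edema masks overlap")
        if not np.array_equal(self.whole, self.core | self.edema):
            raise ValueError("whole mask must equal core | edema")


def select_target_cluster(labels: LabelField | np.ndarray,
                          image: IntensityImage | np.ndarray,
                          strategy: str = "brightest_mean",
                          seed_pixel: tuple[int, int] | None = None,
                          min_fraction: float = 0.001) -> np.ndarray:
    """Pick the tumor cluster from a segmentation.

    ``brightest_mean`` selects the cluster with the highest mean intensity
    inside the brain mask (ties break toward the lowest label index) —
    appropriate for contrast enhancement (T1C core) and FLAIR
    hyperintensity.  Clusters smaller than ``min_fraction`` of the labelled
    area are not eligible (a single-sample Gibbs labelling routinely
    carries transient singleton clusters of extreme noisy pixels, and a
    tumor is a region, not a pixel); if no cluster qualifies the size
    guard is dropped.  ``seeded`` selects the cluster containing
    ``seed_pixel``.
    """
    lab = labels.labels if isinstance(labels, LabelField) else np.asarray(labels)
    img = image if isinstance(image, IntensityImage) else IntensityImage(np.asarray(image, dtype=float))
    if lab.shape != img.shape:
        raise ValueError("labels and image shapes differ")
    if strategy == "seeded":
        if seed_pixel is None:
            raise ValueError("seeded strategy requires seed_pixel")
        r, c = seed_pixel
        if lab[r, c] < 0:
            raise ValueError(f"seed pixel {seed_pixel} is masked out")
        return lab == lab[r, c]
    if strategy != "brightest_mean":
        raise ValueError(f"unknown strategy {strategy!r}")
    valid = (lab >= 0) & img.valid_mask()
    used = np.unique(lab[valid])
    if used.size == 0:
        raise ValueError("no labelled pixels to select from")
    sizes = {int(k): int(np.count_nonzero(valid & (lab == k))) for k in used}
    min_size = min_fraction * int(valid.sum())
    eligible = [k for k in used if sizes[int(k)] >= min_size]
    if not eligible:
        eligible = list(used)
    best, best_mean = None, -np.inf
    for k in eligible:  # ascending label order => lowest index wins ties
        m = float(img.pixels[valid & (lab == k)].mean())
        if m > best_mean:
            best, best_mean = k, m
    return lab == best


def edema_mask(flair_tumor: np.ndarray, t1c_tumor: np.ndarray) -> np.ndarray:
    """Pixelwise set difference: FLAIR tumor minus T1C tumor (core)."""
    f = np.asarray(flair_tumor, dtype=bool)
    t = np.asarray(t1c_tumor, dtype=bool)
    if f.shape != t.shape:
        raise ValueError(f"shape mismatch {f.shape} vs {t.shape}")
    return f & ~t


def compose_tumor_masks(core: np.ndarray, edema: np.ndarray) -> TumorMasks:
    """Build TumorMasks with whole = core | edema; inputs must be disjoint."""
    core = np.asarray(core, dtype=bool)
    edema = np.asarray(edema, dtype=bool)
    return TumorMasks(core=core, edema=edema, whole=core | edema)


def composite_labels(masks: TumorMasks) -> np.ndarray:
    """Composite integer mask: 0 background, 1 edema, 2 tumor core."""
    out = np.zeros(masks.core.shape, dtype=np.int64)
    out[masks.edema] = 1
    out[masks.core] = 2
    return out
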