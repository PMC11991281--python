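"""Canopy/background classification for DSZ imagery.

Workflow: SLIC superpixels -> per-superpixel means of a small set of
vegetation indices -> Otsu binarization of those means, optionally clamped
by per-index lower/upper limits -> optional manual per-superpixel override.
Classifying whole superpixels (instead of raw pixels) suppresses the
salt-and-pepper noise that plain per-pixel thresholding produces in
centimeter-resolution canopy imagery.

Defaults follow the sensor family: RGB scenes use RGBVI and VARI with SLIC
compactness 20 (Lab color space); 5-band scenes use EVI and RVI with
compactness 0.05 (Euclidean distance in raw reflectance space, whose scale
is far below Lab's).  Multiple indices are combined conservatively: a
superpixel is canopy only if it passes every index's threshold.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import slic as _skimage_slic

from .indices import get_index, compute_index_map
from .scene import Scene

logger = logging.getLogger(__name__)

DEFAULTS = {
    "CI": {"compactness": 20.0, "seg_indices": ("RGBVI", "VARI")},
    "MI": {"compactness": 0.05, "seg_indices": ("EVI", "RVI")},
}


class DegenerateInputError(ValueError):
    pass


@dataclass
class SegmentationConfig:
    """Knobs of the canopy-classification workflow.

    ``n_superpixels`` defaults to pixel_count/400 (~20x20 px superpixels,
    ~16 cm patches at 0.8 cm/px).  ``lower_limit``/``upper_limit`` map index
    name -> value and clamp the canopy class beyond the Otsu split.
    ``manual_overrides`` maps superpixel label -> True (canopy) / False.
    """

    n_superpixels: int | None = None
    compactness: float | None = None
    seg_indices: tuple[str, ...] | None = None
    lower_limit: dict[str, float] = field(default_factory=dict)
    upper_limit: dict[str, float] = field(default_factory=dict)
    manual_overrides: dict[int, bool] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in set(self.lower_limit) & set(self.upper_limit):
            if not self.lower_limit[name] < self.upper_limit[name]:
                raise ValueError(f"lower_limit >= upper_limit for {name!r}")

    def resolved(self, scene: Scene) -> "SegmentationConfig":
        fam = DEFAULTS[scene.family]
        n_px = scene.shape[0] * scene.shape[1]
        return SegmentationConfig(
            n_superpixels=self.n_superpixels or max(2, n_px // 400),
            compactness=self.compactness if self.compactness is not None else fam["compactness"],
            seg_indices=tuple(self.seg_indices or fam["seg_indices"]),
            lower_limit=dict(self.lower_limit),
            upper_limit=dict(self.upper_limit),
            manual_overrides=dict(self.manual_overrides),
            seed=self.seed,
        )

    def hash(self) -> str:
        payload = json.dumps(
            {k: (sorted(v.items()) if isinstance(v, dict) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SuperpixelMap:
    """SLIC output: a dense label grid plus per-label statistics."""

    labels: np.ndarray
    pixel_counts: dict[int, int]
    index_means: dict[str, dict[int, float]]

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.pixel_counts)


def slic_segment(scene: Scene, config: SegmentationConfig) -> SuperpixelMap:
    """SLIC superpixels with per-label means of the configured indices.

    Contiguity is enforced (orphan fragments are merged), so every label is
    one connected region; label means are computed over valid (finite) index
    pixels only.
    """
    cfg = config.resolved(scene)
    h, w = scene.shape
    if h < 16 or w < 16:
        raise ValueError("scene must be at least 16x16 px")
    n_px = h * w
    if not 2 <= cfg.n_superpixels <= n_px:
        raise ValueError(f"n_superpixels must be in [2, {n_px}]")
    if scene.family == "CI":
        img = scene.stack() / 255.0
        labels = _skimage_slic(img, n_segments=cfg.n_superpixels,
                               compactness=cfg.compactness, convert2lab=True,
                               enforce_connectivity=True, min_size_factor=0.01,
                               start_label=0, channel_axis=-1)
    else:
        img = scene.stack()
        # low compactness makes clusters ragged; keeping small connected
        # fragments as their own superpixels (tiny min_size_factor) beats
        # force-merging them into a possibly different-class neighbor
        labels = _skimage_slic(img, n_segments=cfg.n_superpixels,
                               compactness=cfg.compactness, convert2lab=False,
                               enforce_connectivity=True, min_size_factor=0.01,
                               start_label=0, channel_axis=-1)
    ids, counts = np.unique(labels, return_counts=True)
    pixel_counts = dict(zip(ids.tolist(), counts.tolist()))
    index_means: dict[str, dict[int, float]] = {}
    flat = labels.ravel()
    for name in cfg.seg_indices:
        imap = compute_index_map(scene, get_index(name)).ravel()
        valid = np.isfinite(imap)
        sums = np.bincount(flat[valid], weights=imap[valid], minlength=ids.max() + 1)
        ns = np.bincount(flat[valid], minlength=ids.max() + 1)
        with np.errstate(invalid="ignore"):
            means = sums / ns
        index_means[name] = {int(i): float(means[i]) for i in ids}
    return SuperpixelMap(labels=labels, pixel_counts=pixel_counts, index_means=index_means)


def otsu_threshold(values) -> float:
    """Threshold maximizing between-class variance, computed exactly over
    the empirical value distribution.

    Candidate thresholds are midpoints between consecutive distinct values;
    the returned threshold separates the two classes strictly.  Ties go to
    the lowest threshold (stable).
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size < 2 or v[0] == v[-1]:
        raise DegenerateInputError("Otsu needs at least 2 distinct values")
    uniq, cnt = np.unique(v, return_counts=True)
    n = v.size
    cum_n = np.cumsum(cnt)
    cum_s = np.cumsum(cnt * uniq)
    total = cum_s[-1]
    # split after unique value j: lower class = uniq[:j+1]
    w0 = cum_n[:-1] / n
    w1 = 1.0 - w0
    mu0 = cum_s[:-1] / cum_n[:-1]
    mu1 = (total - cum_s[:-1]) / (n - cum_n[:-1])
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    j = int(np.argmax(var_between))
    return float((uniq[j] + uniq[j + 1]) / 2.0)


def classify_canopy(spx: SuperpixelMap, config: SegmentationConfig,
                    seg_indices: tuple[str, ...] | None = None) -> np.ndarray:
    """Binary canopy mask from superpixel index means.

    A superpixel is canopy iff, for every segmentation index, its mean is
    above the Otsu threshold AND inside the configured [lower, upper] limits
    (vegetation is the high side of all default indices).  Manual overrides
    are applied last and logged.
    """
    names = tuple(seg_indices or config.seg_indices or spx.index_means.keys())
    ids = spx.label_ids
    canopy = {i: True for i in ids}
    for name in names:
        means = spx.index_means[name]
        vec = np.array([means[i] for i in ids])
        finite = np.isfinite(vec)
        if finite.sum() < 2 or np.nanmin(vec) == np.nanmax(vec):
            raise DegenerateInputError(f"superpixel means of {name} are degenerate")
        thr = otsu_threshold(vec[finite])
        lo = config.lower_limit.get(name, -np.inf)
        hi = config.upper_limit.get(name, np.inf)
        for i, m in zip(ids, vec):
            ok = np.isfinite(m) and m > thr and lo <= m <= hi
            canopy[i] = canopy[i] and ok
    for lab, cls in config.manual_overrides.items():
        if lab not in canopy:
            raise KeyError(f"manual override references nonexistent superpixel {lab}")
        logger.info("manual override: superpixel %d -> %s", lab, "canopy" if cls else "background")
        canopy[lab] = bool(cls)
    mask = np.isin(spx.labels, [i for i in ids if canopy[i]]).astype(np.uint8)
    if mask.sum() == 0:
        warnings.warn("canopy mask is empty after thresholds/limits", stacklevel=2)
    return mask


def segment_canopy(scene: Scene, config: SegmentationConfig | None = None,
                   return_details: bool = False):
    """End-to-end Fig-style canopy classification: SLIC -> Otsu -> overrides.

    Deterministic given (scene, config); ``return_details`` adds the
    superpixel map and a manifest (config hash, class pixel counts) so the
    same hyperparameters can be audited across repeat surveys of a site.
    """
    config = (config or SegmentationConfig()).resolved(scene)
    spx = slic_segment(scene, config)
    mask = classify_canopy(spx, config)
    if not return_details:
        return mask
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_superpixels": len(spx.label_ids),
        "canopy_px": int(mask.sum()),
        "background_px": int(mask.size - mask.sum()),
        "seg_indices": list(config.seg_indices),
    }
    return mask, spx, manifest


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
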