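"""Synthetic plantation scenes and physiology with planted, recoverable structure.

The field protocol this emulates: 2 m x 2 m designed square zones (DSZs) are
photographed at ~0.8 cm/px by visible-light (R, G, B digital numbers) and
five-band multispectral (blue, green, red, red-edge, NIR reflectance) UAV
sensors, while leaf area index (LAI), photochemical reflectance index (PRI)
and PSII quantum yield (PhiPSII) are measured on the ground.  Every generator
here is fully seeded so downstream stages (segmentation, index extraction,
ranking, regression) can be tested against known ground truth.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

MULTISPECTRAL_BANDS = ("blue", "green", "red", "red_edge", "nir")
RGB_BANDS = ("R", "G", "B")

#: physically plausible envelopes for the three physiological parameters
#: (field ranges observed across elevations and farming methods; PhiPSII
#: has a theoretical ceiling of ~0.85)
PARAMETER_RANGES = {
    "LAI": (0.13, 10.37),
    "PRI": (-0.077, 0.0766),
    "PhiPSII": (0.0729, 0.8648),
}

ELEVATIONS = ("low", "mid", "high")
FARMING_METHODS = ("CFM", "AFM")
SEASONS = ("spring", "summer", "autumn", "winter")


class SceneError(ValueError):
    """Invalid scene construction or band access."""


@dataclass
class Scene:
    """Multiband raster for one DSZ.

    ``bands`` maps band name to a 2-D array: reflectance in [0, 1] for the
    multispectral family, digital numbers in [0, 255] for RGB.
    ``truth_mask`` (optional) is the generator's canopy ground truth, 1 = canopy.
    """

    bands: dict[str, np.ndarray]
    resolution_cm_per_px: float = 0.8
    truth_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.bands:
            raise SceneError("scene has no bands")
        names = frozenset(self.bands)
        if names == frozenset(MULTISPECTRAL_BANDS):
            self.family = "MI"
        elif names == frozenset(RGB_BANDS):
            self.family = "CI"
        else:
            raise SceneError(f"unrecognized band set {sorted(names)}")
        shapes = {b: np.asarray(g).shape for b, g in self.bands.items()}
        if len(set(shapes.values())) != 1:
            raise SceneError(f"band grids differ in shape: {shapes}")
        self.bands = {b: np.asarray(g, dtype=float) for b, g in self.bands.items()}
        lo, hi = (0.0, 1.0) if self.family == "MI" else (0.0, 255.0)
        for b, g in self.bands.items():
            if g.ndim != 2:
                raise SceneError(f"band {b!r} is not 2-D")
            if g.min() < lo or g.max() > hi:
                raise SceneError(f"band {b!r} outside [{lo}, {hi}]")
        if self.resolution_cm_per_px <= 0:
            raise SceneError("resolution must be positive")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask)
            if self.truth_mask.shape != self.shape:
                raise SceneError("truth_mask shape differs from bands")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise SceneError(f"scene has no band {name!r}; available: {sorted(self.bands)}") from None

    def stack(self, order: tuple[str, ...] | None = None) -> np.ndarray:
        """(H, W, C) array in canonical band order."""
        order = order or (MULTISPECTRAL_BANDS if self.family == "MI" else RGB_BANDS)
        return np.stack([self.band(b) for b in order], axis=-1)

    def to_tiff(self, path) -> None:
        import tifffile

        order = MULTISPECTRAL_BANDS if self.family == "MI" else RGB_BANDS
        arr = np.stack([self.band(b) for b in order], axis=0).astype(np.float32)
        tifffile.imwrite(path, arr, metadata={"bands": list(order),
                                              "resolution_cm_per_px": self.resolution_cm_per_px})

    @classmethod
    def from_tiff(cls, path, family: str | None = None) -> "Scene":
        import tifffile

        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        order = meta.get("bands")
        if order is None:
            order = list(MULTISPECTRAL_BANDS) if arr.shape[0] == 5 else list(RGB_BANDS)
        res = float(meta.get("resolution_cm_per_px", 0.8))
        return cls(bands=dict(zip(order, arr)), resolution_cm_per_px=res)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Binary canopy mask as an 8-bit PNG (canopy = 255)."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask_png(path) -> np.ndarray:
    import imageio.v3 as iio

    return (np.asarray(iio.imread(path)) > 0).astype(np.uint8)


@dataclass
class SpectraConfig:
    """Per-class band means/sds used to paint canopy vs background pixels.

    Defaults give the strong vegetation/soil contrast the segmentation
    workflow assumes: canopy NIR 0.45 vs background 0.20, canopy red 0.05 vs
    background 0.15 (NDVI ~0.8 vs ~0.14).
    """

    family: str = "MI"
    canopy: dict[str, float] = field(default_factory=dict)
    background: dict[str, float] = field(default_factory=dict)
    sd: float = 0.015

    def __post_init__(self) -> None:
        if self.family not in ("MI", "CI"):
            raise ValueError("family must be 'MI' or 'CI'")
        if self.family == "MI":
            canopy = {"blue": 0.04, "green": 0.08, "red": 0.05, "red_edge": 0.30, "nir": 0.45}
            background = {"blue": 0.10, "green": 0.12, "red": 0.15, "red_edge": 0.18, "nir": 0.20}
        else:
            canopy = {"R": 60.0, "G": 110.0, "B": 50.0}
            background = {"R": 150.0, "G": 130.0, "B": 105.0}
            if not self.canopy and self.sd == 0.015:
                self.sd = 8.0
        canopy.update(self.canopy)
        background.update(self.background)
        self.canopy, self.background = canopy, background

    @property
    def band_names(self) -> tuple[str, ...]:
        return MULTISPECTRAL_BANDS if self.family == "MI" else RGB_BANDS

    def separable(self) -> bool:
        """At least one band separates the classes by more than 2 pooled sds."""
        return any(
            abs(self.canopy[b] - self.background[b]) > 2.0 * self.sd for b in self.band_names
        )


def generate_scene(
    canopy_fraction: float,
    spectra_config: SpectraConfig | None = None,
    size_px: tuple[int, int] = (128, 128),
    seed: int = 0,
    resolution_cm_per_px: float = 0.8,
) -> Scene:
    """Seeded synthetic DSZ image with a known canopy mask.

    Canopy shape comes from region growth: blobs grow outward from random
    seed points through a smooth random speed field, and the growth front is
    cut at the quantile that yields ``canopy_fraction``; a median filter then
    smooths blob boundaries.  This produces spatially contiguous canopy
    patches rather than i.i.d. pixel noise, so superpixel segmentation faces
    realistic geometry.
    """
    h, w = size_px
    if h < 32 or w < 32:
        raise ValueError("scene must be at least 32x32 px")
    if not 0.0 < canopy_fraction <= 1.0:
        raise ValueError("canopy_fraction must be in (0, 1]")
    spectra = spectra_config or SpectraConfig()
    if not spectra.separable():
        warnings.warn("class spectra overlap; segmentation indices may not separate classes",
                      stacklevel=2)
    rng = np.random.default_rng(seed)

    if canopy_fraction >= 1.0:
        mask = np.ones((h, w), dtype=np.uint8)
    else:
        n_blobs = max(3, int(round(canopy_fraction * h * w / 900)))
        seeds = rng.integers(0, (h, w), size=(n_blobs, 2))
        seed_img = np.ones((h, w), dtype=bool)
        seed_img[seeds[:, 0], seeds[:, 1]] = False
        arrival = ndimage.distance_transform_edt(seed_img)
        # smooth noise warps the growth front so blobs are irregular
        noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
        noise *= 0.35 * arrival.std() / max(noise.std(), 1e-12)
        arrival = arrival + noise
        mask = (arrival <= np.quantile(arrival, canopy_fraction)).astype(np.uint8)
        mask = ndimage.median_filter(mask, size=3)

    # real calibrated reflectance has a positive floor; clipping to it keeps
    # ratio indices (RVI = nir/red) bounded, as they are on field imagery
    lo, hi = (0.01, 1.0) if spectra.family == "MI" else (0.0, 255.0)
    bands = {}
    for b in spectra.band_names:
        grid = np.where(
            mask > 0,
            rng.normal(spectra.canopy[b], spectra.sd, size=(h, w)),
            rng.normal(spectra.background[b], spectra.sd, size=(h, w)),
        )
        bands[b] = np.clip(grid, lo, hi)
    return Scene(bands=bands, resolution_cm_per_px=resolution_cm_per_px, truth_mask=mask)


# ---------------------------------------------------------------------------
# leaf-level forward formulas

@dataclass
class LeafReading:
    """One leaf-clip reading: paired 531/570 nm reflectance and the
    light-adapted fluorescence pair (Fm', Fs)."""

    R531: float
    R570: float
    Fm_prime: float
    Fs: float

    def __post_init__(self) -> None:
        if not (0.0 < self.R531 < 1.0 and 0.0 < self.R570 < 1.0):
            raise ValueError("R531 and R570 must lie in (0, 1)")
        if self.Fm_prime <= 0:
            raise ValueError("Fm_prime must be positive")
        if not 0.0 <= self.Fs <= self.Fm_prime:
            raise ValueError("Fs must satisfy 0 <= Fs <= Fm_prime")


def pri_from_reflectance(reading: LeafReading) -> float:
    """PRI = (R531 - R570) / (R531 + R570), in [-1, 1].

    531 nm tracks the xanthophyll-cycle de-epoxidation state; 570 nm is the
    reference wavelength.
    """
    denom = reading.R531 + reading.R570
    if denom <= 0:
        raise ZeroDivisionError("R531 + R570 must be positive")
    return (reading.R531 - reading.R570) / denom


def phipsii_from_fluorescence(reading: LeafReading) -> float:
    """PhiPSII = (Fm' - Fs) / Fm', the fraction of absorbed light driving
    PSII photochemistry, in [0, 1]."""
    if reading.Fm_prime <= 0:
        raise ValueError("Fm_prime must be positive")
    if reading.Fs > reading.Fm_prime:
        raise ValueError("Fs exceeds Fm_prime")
    return (reading.Fm_prime - reading.Fs) / reading.Fm_prime


# ---------------------------------------------------------------------------
# planted forward model

@dataclass
class TruthModel:
    """Planted linear (optionally monotone-warped) map from named indices to
    each physiological parameter, with per-parameter Gaussian noise.

    ``coefficients[param] = {"intercept": a, "weights": {index: w, ...},
    "nonlinearity": None | "softplus"}``.  Generated values are clipped to
    the physical envelopes in :data:`PARAMETER_RANGES`; every clip is logged.
    """

    coefficients: dict[str, dict]
    noise_sd: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        for p, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{p!r}] must be >= 0")

    @property
    def parameters(self) -> list[str]:
        return list(self.coefficients)

    def causal_features(self, param: str) -> list[str]:
        return list(self.coefficients[param]["weights"])

    def mean_response(self, param: str, features: pd.DataFrame) -> np.ndarray:
        spec = self.coefficients[param]
        y = np.full(len(features), float(spec.get("intercept", 0.0)))
        for name, w in spec["weights"].items():
            if name not in features.columns:
                raise KeyError(f"truth model references missing feature {name!r}")
            y = y + w * features[name].to_numpy(float)
        if spec.get("nonlinearity") == "softplus":
            y = np.logaddexp(0.0, y)
        return y

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"coefficients": self.coefficients, "noise_sd": self.noise_sd,
                       "seed": self.seed}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    @classmethod
    def default(cls, seed: int = 0) -> "TruthModel":
        """Two causal indices per parameter, scaled so that with the default
        feature distribution (indices ~ N(0.55, 0.15^2)) the noise sd equals
        half the signal sd (signal-to-noise ratio ~= 2)."""
        coeff = {
            "LAI": {"intercept": 0.4, "weights": {"NDVI": 6.0, "GNDVI": 3.0}},
            "PRI": {"intercept": -0.030, "weights": {"GNDVI": 0.060, "CIgreen_n": 0.030}},
            "PhiPSII": {"intercept": 0.05, "weights": {"NDRE": 0.45, "NDVI": 0.25}},
        }
        noise = {}
        for p, spec in coeff.items():
            signal_sd = 0.15 * float(np.hypot(*spec["weights"].values()))
            noise[p] = signal_sd / 2.0
        return cls(coefficients=coeff, noise_sd=noise, seed=seed)


def _clip_logged(values: np.ndarray, param: str) -> np.ndarray:
    lo, hi = PARAMETER_RANGES[param]
    n_clip = int(np.sum((values < lo) | (values > hi)))
    if n_clip:
        logger.info("clipped %d/%d %s values to [%g, %g]", n_clip, values.size, param, lo, hi)
    return np.clip(values, lo, hi)


def _leaf_averaged(param: str, targets: np.ndarray, noise_sd: float,
                   rng: np.random.Generator, n_leaves: int = 10) -> np.ndarray:
    """Emulate the field protocol: 10 leaf readings per DSZ, each pushed
    through the leaf-level forward formula, then averaged.

    Per-leaf targets get Gaussian noise of sd ``noise_sd`` (so the DSZ mean
    has sd ~ noise_sd / sqrt(10)); readings are constructed to realize each
    per-leaf value exactly, keeping the noiseless limit exact.
    """
    out = np.empty_like(targets, dtype=float)
    for i, t in enumerate(targets):
        leaf_vals = t + (rng.normal(0.0, noise_sd, n_leaves) if noise_sd > 0 else 0.0)
        vals = []
        for v in np.atleast_1d(leaf_vals):
            if param == "PRI":
                v = float(np.clip(v, -0.95, 0.95))
                reading = LeafReading(R531=0.05 * (1 + v), R570=0.05 * (1 - v),
                                      Fm_prime=1.0, Fs=0.5)
                vals.append(pri_from_reflectance(reading))
            else:  # PhiPSII
                v = float(np.clip(v, 0.0, 1.0))
                reading = LeafReading(R531=0.05, R570=0.05, Fm_prime=1.0, Fs=1.0 - v)
                vals.append(phipsii_from_fluorescence(reading))
        out[i] = float(np.mean(vals))
    return out


def generate_physiology(
    scene_features: pd.DataFrame,
    truth: TruthModel,
    n_dsz: int | None = None,
    seed: int = 0,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-DSZ physiological measurements from the planted model.

    ``scene_features`` has one row per DSZ and one column per named index.
    PRI and PhiPSII are produced by simulating 10 leaf readings per DSZ and
    averaging their formula-derived values; LAI gets a single canopy-analyzer
    noise draw.  Returns a DataFrame with metadata, parameters and features.
    """
    n = len(scene_features) if n_dsz is None else n_dsz
    if n < 3:
        raise ValueError("need at least 3 DSZs per site")
    if n != len(scene_features):
        raise ValueError("n_dsz must match the feature table length")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=scene_features.index.copy())
    if metadata is not None:
        out = metadata.copy()
    else:
        idx = np.arange(n)
        out["site_id"] = [f"S{i % 6 + 1:02d}" for i in idx]
        out["elevation_class"] = [ELEVATIONS[(i // 2) % 3] for i in idx]
        out["farming_method"] = [FARMING_METHODS[i % 2] for i in idx]
        out["season"] = [SEASONS[(i // 6) % 4] for i in idx]
    for param in truth.parameters:
        mean = truth.mean_response(param, scene_features)
        sd = truth.noise_sd[param]
        if param in ("PRI", "PhiPSII"):
            vals = _leaf_averaged(param, mean, sd, rng)
        else:
            vals = mean + (rng.normal(0.0, sd, n) if sd > 0 else 0.0)
        out[param] = _clip_logged(vals, param)
    return pd.concat([out, scene_features.reset_index(drop=True)], axis=1)


def generate_feature_table(
    n_rows: int,
    n_noise_features: int,
    truth: TruthModel | None = None,
    seed: int = 0,
    feature_mean: float = 0.55,
    feature_sd: float = 0.15,
) -> tuple[pd.DataFrame, TruthModel]:
    """Tabular fixture bypassing imagery: causal index columns carry the
    planted effects, noise columns are independent draws on the same scale.

    Returns ``(table, truth)`` so recovery tests can check rankings and
    refits against the planted coefficient map.
    """
    if n_rows < 30:
        raise ValueError("need n_rows >= 30")
    truth = truth or TruthModel.default(seed=seed)
    rng = np.random.default_rng(seed)
    causal = sorted({f for p in truth.parameters for f in truth.causal_features(p)})
    cols = {}
    for name in causal:
        cols[name] = rng.normal(feature_mean, feature_sd, n_rows)
    for j in range(n_noise_features):
        cols[f"noise_{j:02d}"] = rng.normal(feature_mean, feature_sd, n_rows)
    features = pd.DataFrame(cols)
    table = generate_physiology(features, truth, seed=seed + 1)
    return table, truth
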