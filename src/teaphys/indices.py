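"""Spectral index registry and zonal (per-DSZ) feature extraction.

19 color indices (CI) are computed from 3-band RGB imagery and 50
multispectral indices (MI) from the 5-band blue/green/red/red-edge/NIR
imagery.  Definitions live in a versioned JSON registry
(``data/index_registry.json``) so the exact formula set can be audited and
swapped without code changes.  A DSZ's feature value for an index is the
arithmetic mean of the per-pixel index over canopy pixels only; pixels where
a formula is undefined (zero denominator, negative square root) are marked
invalid and excluded from both numerator and pixel count — no epsilon
substitution, which would silently bias zonal means.
"""

from __future__ import annotations

import ast
import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .scene import Scene, SceneError

logger = logging.getLogger(__name__)

_ALLOWED_FUNCS = {"sqrt": np.sqrt, "abs": np.abs}
_CI_SYMBOLS = {"R", "G", "B", "r", "g", "b"}
_MI_SYMBOLS = {"B", "G", "R", "RE", "N"}

_BAND_TO_SYMBOL = {"blue": "B", "green": "G", "red": "R", "red_edge": "RE", "nir": "N"}


@dataclass(frozen=True)
class IndexDefinition:
    """A named spectral index: which bands it needs and its formula string."""

    name: str
    family: str  # "CI" or "MI"
    required_bands: frozenset[str]
    formula: str

    def __post_init__(self) -> None:
        if self.family not in ("CI", "MI"):
            raise ValueError(f"bad family {self.family!r}")
        allowed = (_CI_SYMBOLS if self.family == "CI" else _MI_SYMBOLS) | set(_ALLOWED_FUNCS)
        names = {n.id for n in ast.walk(ast.parse(self.formula, mode="eval"))
                 if isinstance(n, ast.Name)}
        if not names <= allowed:
            raise ValueError(f"{self.name}: formula uses unknown symbols {names - allowed}")


def load_registry(path=None) -> list[IndexDefinition]:
    """Load index definitions from the packaged JSON registry (or a file)."""
    if path is None:
        text = resources.files("teaphys").joinpath("data/index_registry.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)["indices"]
    defs = [IndexDefinition(d["name"], d["family"], frozenset(d["bands"]), d["formula"])
            for d in raw]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate index names in registry")
    return defs


def registry_by_family(defs: list[IndexDefinition] | None = None) -> dict[str, list[IndexDefinition]]:
    defs = defs if defs is not None else load_registry()
    out: dict[str, list[IndexDefinition]] = {"CI": [], "MI": []}
    for d in defs:
        out[d.family].append(d)
    return out


def get_index(name: str, defs: list[IndexDefinition] | None = None) -> IndexDefinition:
    for d in (defs if defs is not None else load_registry()):
        if d.name == name:
            return d
    raise KeyError(f"no index named {name!r} in registry")


def _namespace(scene: Scene, family: str) -> dict[str, np.ndarray]:
    if family == "CI":
        R = scene.band("R") / 255.0
        G = scene.band("G") / 255.0
        B = scene.band("B") / 255.0
        with np.errstate(divide="ignore", invalid="ignore"):
            total = R + G + B
            ns = {"R": R, "G": G, "B": B,
                  "r": R / total, "g": G / total, "b": B / total}
        return ns
    return {sym: scene.band(band) for band, sym in _BAND_TO_SYMBOL.items()
            if band in scene.bands}


def compute_index_map(scene: Scene, index: IndexDefinition) -> np.ndarray:
    """Per-pixel index values; undefined pixels are NaN (invalid), never
    epsilon-substituted."""
    if index.family == "CI":
        missing = set("RGB") - set(scene.bands)
    else:
        missing = index.required_bands - set(scene.bands)
    if missing:
        raise SceneError(f"index {index.name!r} needs missing band(s): {sorted(missing)}")
    ns = _namespace(scene, index.family)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = eval(compile(ast.parse(index.formula, mode="eval"), "<index>", "eval"),
                   {"__builtins__": {}}, {**_ALLOWED_FUNCS, **ns})
    out = np.asarray(out, dtype=float)
    if out.shape != scene.shape:  # constant formula edge case
        out = np.broadcast_to(out, scene.shape).copy()
    out[~np.isfinite(out)] = np.nan
    return out


def zonal_mean_index(index_map: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """Mean of the index over masked valid pixels, with the contributing
    pixel count.  Returns (nan, 0) when no valid canopy pixel exists."""
    index_map = np.asarray(index_map, dtype=float)
    sel = (np.asarray(mask) > 0) & np.isfinite(index_map)
    count = int(sel.sum())
    if count == 0:
        logger.warning("zonal mean over empty effective mask; feature flagged missing")
        return float("nan"), 0
    return float(index_map[sel].mean()), count


def compute_feature_vector(
    scene: Scene,
    mask: np.ndarray,
    registry_subset: list[IndexDefinition],
) -> pd.Series:
    """One zonal-mean value per index over the canopy mask.

    The whole subset must be band-compatible with the scene (a 3-band scene
    cannot serve MI formulas); per-index numerical failures degrade to NaN
    with a log entry rather than aborting the DSZ.
    """
    missing: dict[str, list[str]] = {}
    for d in registry_subset:
        need = set("RGB") if d.family == "CI" else set(d.required_bands)
        lack = need - set(scene.bands)
        if lack:
            missing[d.name] = sorted(lack)
    if missing:
        raise SceneError(f"scene lacks bands for indices: {missing}")
    values, counts = {}, {}
    for d in registry_subset:
        try:
            m = compute_index_map(scene, d)
            values[d.name], counts[d.name] = zonal_mean_index(m, mask)
        except Exception:  # degrade, don't abort the DSZ
            logger.exception("index %s failed; flagged missing", d.name)
            values[d.name], counts[d.name] = float("nan"), 0
    s = pd.Series(values, dtype=float)
    s.attrs["pixel_counts"] = counts
    return s


def extract_features(scene: Scene, mask: np.ndarray,
                     family: str | None = None) -> pd.Series:
    """Convenience wrapper: full CI or MI registry subset for the scene's
    sensor family."""
    fam = family or scene.family
    return compute_feature_vector(scene, mask, registry_by_family()[fam])
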