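"""Ground-truthed synthetic tissue scenes.

The generator emulates the statistical structure the downstream analysis
assumes: a tissue region containing many nuclei, per-cell expression classes
(no signal / X only / Y only / mixed) in table-like proportions, spot counts
per expressing cell, and a spatial regime in which the X homolog can be
enriched ventrally while the Y homolog stays homogeneously distributed.
Every scene carries its full ground truth (nucleus centers, per-cell class,
per-spot parent cell), so segmentation, spot detection, assignment,
classification and the spatial statistics are all testable without real
microscopy images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError

logger = logging.getLogger(__name__)

#: Canonical per-cell expression classes.
CLASS_LABELS = ("no_signal", "x_only", "y_only", "mixed")

#: Default class proportions; these follow the male spinal-cord sample with the
#: richest printed per-cell table (≈87% silent cells, balanced X/Y, ~1% mixed).
DEFAULT_PROPORTIONS = {
    "no_signal": 0.874,
    "x_only": 0.058,
    "y_only": 0.058,
    "mixed": 0.010,
}

_TISSUE_SHAPES = ("ellipse", "half_annulus", "full_frame")

# fixed sub-stream offsets, one per generation stage
_STAGE_PLACEMENT = 0
_STAGE_CLASSES = 1
_STAGE_SPOTS = 2
_STAGE_FALSE_POSITIVES = 3
_STAGE_NOISE = 4


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """One RNG sub-stream per stage, all keyed by the scene seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic tissue scene.

    Pixel units throughout; intensities are arbitrary fluorescence units.
    """

    image_height: int = 256
    image_width: int = 256
    tissue_shape: str = "ellipse"
    n_cells: int = 250
    nucleus_radius_mean: float = 4.0
    nucleus_radius_sd: float = 0.5
    min_nucleus_separation: float = 12.0
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    spots_per_expressing_cell_mean: float = 2.5
    ventral_x_enrichment: float = 1.0
    spot_scatter_sd: float = 3.0
    spot_amplitude: float = 200.0
    nucleus_amplitude: float = 100.0
    background_level: float = 10.0
    noise_sd: float = 0.0
    spot_sigma: float = 1.2
    false_positives_per_channel: float = 0.0
    expansion_distance: float = 20.0
    x_gene: str = "X"
    y_gene: str = "Y"
    seed: int = 0

    def __post_init__(self):
        if self.image_height < 1 or self.image_width < 1:
            raise ParameterError("image dimensions must be >= 1 pixel")
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.tissue_shape not in _TISSUE_SHAPES:
            raise ParameterError(
                f"tissue_shape must be one of {_TISSUE_SHAPES}, got {self.tissue_shape!r}"
            )
        props = dict(self.class_proportions)
        if set(props) != set(CLASS_LABELS):
            raise ParameterError(f"class_proportions must have keys {CLASS_LABELS}")
        if any(p < 0 for p in props.values()):
            raise ParameterError("class proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ParameterError("class_proportions must sum to 1 within 1e-9")
        if self.ventral_x_enrichment < 1.0:
            raise ParameterError("ventral_x_enrichment must be >= 1")
        if self.spots_per_expressing_cell_mean < 0:
            raise ParameterError("spots_per_expressing_cell_mean must be >= 0")
        if self.false_positives_per_channel < 0:
            raise ParameterError("false_positives_per_channel must be >= 0")
        object.__setattr__(self, "class_proportions", props)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SceneConfig":
        """Build a config from a flat mapping, rejecting unknown keys."""
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown scene config keys: {sorted(unknown)}")
        return cls(**data)

    def genes(self) -> tuple[str, str]:
        return (self.x_gene, self.y_gene)


@dataclass
class Scene:
    """A realized synthetic tissue with full ground truth."""

    config: SceneConfig
    tissue_mask: np.ndarray  # 2-D bool
    nuclei_centers: np.ndarray  # (n, 2) float, (row, col)
    nuclei_radii: np.ndarray  # (n,) float
    cell_classes: np.ndarray  # (n,) str, from CLASS_LABELS
    true_spots: pd.DataFrame  # columns row, col, gene, cell_id (1-based; -1 = false positive)

    @property
    def n_cells(self) -> int:
        return len(self.nuclei_centers)

    def ventral_border_row(self) -> float:
        """Row of the dorsal/ventral split: midpoint of the tissue bounding box."""
        rows = np.nonzero(self.tissue_mask.any(axis=1))[0]
        if len(rows) == 0:
            return (self.config.image_height - 1) / 2.0
        return (rows[0] + rows[-1]) / 2.0


def tissue_mask(config: SceneConfig) -> np.ndarray:
    """Binary tissue outline for the configured shape."""
    h, w = config.image_height, config.image_width
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    if config.tissue_shape == "full_frame":
        return np.ones((h, w), dtype=bool)
    if config.tissue_shape == "ellipse":
        a, b = (h - 1) / 2.0, (w - 1) / 2.0
        a, b = max(a, 0.5), max(b, 0.5)
        return ((rr - a) / a) ** 2 + ((cc - b) / b) ** 2 <= 1.0
    # half_annulus: an arch open toward the image bottom
    r0, c0 = float(h - 1), (w - 1) / 2.0
    outer = 0.95 * min(h - 1, (w - 1) / 2.0)
    outer = max(outer, 1.0)
    inner = 0.45 * outer
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    return (d2 <= outer**2) & (d2 >= inner**2)


def _place_hardcore(
    rng: np.random.Generator, mask: np.ndarray, n: int, sep: float, max_attempts: int
) -> np.ndarray:
    """Hard-core rejection sampling of ``n`` points inside ``mask``.

    Uses a uniform grid (cell size = sep) so each candidate only checks its
    3x3 neighborhood. Raises PlacementError when the attempt budget runs out.
    """
    if n == 0:
        return np.zeros((0, 2), dtype=float)
    h, w = mask.shape
    cell = max(sep, 1.0)
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    accepted: list[tuple[float, float]] = []
    sep2 = sep * sep
    attempts = 0
    batch = 1024
    while len(accepted) < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed {len(accepted)}/{n} nuclei after {attempts} attempts "
                f"(separation {sep}); enlarge the image or relax the separation"
            )
        m = min(batch, max_attempts - attempts)
        cand_r = rng.uniform(0, h, size=m)
        cand_c = rng.uniform(0, w, size=m)
        attempts += m
        inside = mask[np.minimum(cand_r.astype(int), h - 1), np.minimum(cand_c.astype(int), w - 1)]
        for r, c in zip(cand_r[inside], cand_c[inside]):
            gi, gj = int(r / cell), int(c / cell)
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for pr, pc in grid.get((gi + di, gj + dj), ()):
                        if (pr - r) ** 2 + (pc - c) ** 2 < sep2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                accepted.append((r, c))
                grid.setdefault((gi, gj), []).append((r, c))
                if len(accepted) == n:
                    break
    return np.asarray(accepted, dtype=float)


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Poisson(lam) conditioned on >= 1, sampled by CDF inversion."""
    if lam <= 0:
        raise ParameterError("zero-truncated Poisson requires a positive mean")
    from scipy import stats

    p0 = np.exp(-lam)
    u = p0 + (1.0 - p0) * rng.random(size)
    return stats.poisson.ppf(u, lam).astype(int)


def _sample_classes(
    rng: np.random.Generator, config: SceneConfig, centers: np.ndarray, border_row: float
) -> np.ndarray:
    """Per-cell class labels; x_only is up-weighted below the ventral border."""
    base = np.array([config.class_proportions[k] for k in CLASS_LABELS], dtype=float)
    ventral = base.copy()
    ventral[CLASS_LABELS.index("x_only")] *= config.ventral_x_enrichment
    ventral /= ventral.sum()
    n = len(centers)
    u = rng.random(n)
    is_ventral = centers[:, 0] >= border_row if n else np.zeros(0, dtype=bool)
    cum_base = np.cumsum(base)
    cum_vent = np.cumsum(ventral)
    idx = np.where(
        is_ventral,
        np.searchsorted(cum_vent, u, side="right"),
        np.searchsorted(cum_base, u, side="right"),
    )
    idx = np.minimum(idx, len(CLASS_LABELS) - 1)
    return np.array(CLASS_LABELS, dtype=object)[idx]


def _scatter_spots(
    rng: np.random.Generator,
    center: np.ndarray,
    k: int,
    sd: float,
    max_radius: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Gaussian spot displacements truncated to ``max_radius`` and the frame."""
    out = np.empty((k, 2), dtype=float)
    need = np.arange(k)
    while len(need):
        draw = center + rng.normal(0.0, sd, size=(len(need), 2))
        r2 = ((draw - center) ** 2).sum(axis=1)
        ok = (
            (r2 <= max_radius**2)
            & (draw[:, 0] >= 0)
            & (draw[:, 0] <= shape[0] - 1)
            & (draw[:, 1] >= 0)
            & (draw[:, 1] <= shape[1] - 1)
        )
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a ground-truthed scene; bit-reproducible for a given seed."""
    mask = tissue_mask(config)
    rng_place = _stage_rng(config.seed, _STAGE_PLACEMENT)
    centers = _place_hardcore(
        rng_place, mask, config.n_cells, config.min_nucleus_separation, 1000 * max(config.n_cells, 1)
    )
    radii = np.clip(
        rng_place.normal(config.nucleus_radius_mean, config.nucleus_radius_sd, len(centers)),
        1.0,
        None,
    )

    rows = np.nonzero(mask.any(axis=1))[0]
    border_row = (rows[0] + rows[-1]) / 2.0 if len(rows) else (config.image_height - 1) / 2.0
    classes = _sample_classes(_stage_rng(config.seed, _STAGE_CLASSES), config, centers, border_row)

    rng_spots = _stage_rng(config.seed, _STAGE_SPOTS)
    shape = (config.image_height, config.image_width)
    # truncation radius guarantees the parent nucleus is strictly nearest
    records: list[tuple[int, int, str, int]] = []
    for i in range(len(centers)):
        cls = classes[i]
        if cls == "no_signal":
            continue
        genes = {
            "x_only": (config.x_gene,),
            "y_only": (config.y_gene,),
            "mixed": (config.x_gene, config.y_gene),
        }[cls]
        max_r = radii[i] + config.expansion_distance
        if config.min_nucleus_separation > 0:
            max_r = min(max_r, max(1.0, config.min_nucleus_separation / 2.0 - 2.0))
        for gene in genes:
            k = int(_zero_truncated_poisson(rng_spots, config.spots_per_expressing_cell_mean, 1)[0])
            pos = _scatter_spots(rng_spots, centers[i], k, config.spot_scatter_sd, max_r, shape)
            for r, c in np.rint(pos).astype(int):
                records.append((r, c, gene, i + 1))

    rng_fp = _stage_rng(config.seed, _STAGE_FALSE_POSITIVES)
    if config.false_positives_per_channel > 0:
        tissue_pixels = np.argwhere(mask)
        for gene in config.genes():
            k = rng_fp.poisson(config.false_positives_per_channel)
            if k and len(tissue_pixels):
                pick = tissue_pixels[rng_fp.integers(0, len(tissue_pixels), k)]
                for r, c in pick:
                    records.append((int(r), int(c), gene, -1))

    spots = pd.DataFrame(records, columns=["row", "col", "gene", "cell_id"])
    spots = spots.astype({"row": int, "col": int, "cell_id": int})
    return Scene(
        config=config,
        tissue_mask=mask,
        nuclei_centers=centers,
        nuclei_radii=radii,
        cell_classes=classes,
        true_spots=spots,
    )


def render_images(scene: Scene) -> dict[str, np.ndarray]:
    """Render the scene into a nuclei channel plus one channel per gene.

    Nuclei are filled discs; spots are isotropic Gaussian bumps of amplitude
    ``spot_amplitude`` and width ``spot_sigma``. All channels receive the
    configured background level and (seeded) Gaussian noise.
    """
    cfg = scene.config
    h, w = cfg.image_height, cfg.image_width
    nuclei = np.zeros((h, w), dtype=float)
    for (r, c), rad in zip(scene.nuclei_centers, scene.nuclei_radii):
        r0, r1 = max(0, int(r - rad - 1)), min(h, int(r + rad + 2))
        c0, c1 = max(0, int(c - rad - 1)), min(w, int(c + rad + 2))
        rr, cc = np.mgrid[r0:r1, c0:c1]
        disc = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        nuclei[r0:r1, c0:c1][disc] = cfg.nucleus_amplitude

    channels = {"nuclei": nuclei}
    half = max(1, int(np.ceil(3 * cfg.spot_sigma)))
    for gene in cfg.genes():
        img = np.zeros((h, w), dtype=float)
        sub = scene.true_spots[scene.true_spots["gene"] == gene]
        for r, c in sub[["row", "col"]].to_numpy():
            if not (0 <= r < h and 0 <= c < w):
                warnings.warn(f"spot at ({r}, {c}) outside image bounds; clipped", stacklevel=2)
                logger.warning("spot at (%s, %s) outside image bounds; clipped", r, c)
                r, c = np.clip(r, 0, h - 1), np.clip(c, 0, w - 1)
            r0, r1 = max(0, r - half), min(h, r + half + 1)
            c0, c1 = max(0, c - half), min(w, c + half + 1)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            img[r0:r1, c0:c1] += cfg.spot_amplitude * np.exp(
                -((rr - r) ** 2 + (cc - c) ** 2) / (2 * cfg.spot_sigma**2)
            )
        channels[gene] = img

    rng_noise = _stage_rng(cfg.seed, _STAGE_NOISE)
    for name in channels:
        channels[name] = channels[name] + cfg.background_level
        if cfg.noise_sd > 0:
            channels[name] = channels[name] + rng_noise.normal(0.0, cfg.noise_sd, (h, w))
    return channels


def relabel_with_coin(scene: Scene, seed: int) -> Scene:
    """Return a copy whose spot labels are iid fair coin flips over positions.

    This is the exchangeable null for the spatial permutation test: positions
    and spot count are kept, each spot's gene is X or Y with probability 1/2
    independently of everything else.
    """
    rng = np.random.default_rng(seed)
    spots = scene.true_spots.copy()
    flips = rng.random(len(spots)) < 0.5
    spots["gene"] = np.where(flips, scene.config.x_gene, scene.config.y_gene)
    return replace(scene, true_spots=spots)
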