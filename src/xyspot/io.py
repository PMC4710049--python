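"""Readers, writers and run configuration.

Spot tables are CSV with header ``row,col,gene,cell_id`` (UNASSIGNED encoded
as -1); images and label masks are single-channel TIFF; run configuration is
YAML with strict (unknown-key-rejecting) validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, ConsistencyError
from .quant import SPOT_COLUMNS

logger = logging.getLogger(__name__)


def read_spot_table(path: str | Path, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a spot table CSV, validating header, types and gene labels.

    Malformed rows raise ConsistencyError naming the 1-based file line; an
    undeclared gene raises ConsistencyError listing the declared set.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != SPOT_COLUMNS:
        raise ConsistencyError(
            f"spot table must have header {','.join(SPOT_COLUMNS)}, got {list(df.columns)}"
        )
    out = pd.DataFrame(index=df.index)
    for col in ("row", "col", "cell_id"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ConsistencyError(f"malformed integer in column {col!r} at line {line}")
        out[col] = vals.astype(int)
    out.insert(2, "gene", df["gene"].astype(object))
    if genes is not None:
        unknown = set(out["gene"]) - set(genes)
        if unknown:
            raise ConsistencyError(
                f"unknown genes {sorted(unknown)}; declared set is {sorted(genes)}"
            )
    return out[SPOT_COLUMNS]


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    spots[SPOT_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_image(path: str | Path) -> np.ndarray:
    img = tifffile.imread(str(path))
    if img.ndim != 2:
        raise ConsistencyError(f"{path}: expected a single-channel 2-D image, got shape {img.shape}")
    return np.asarray(img)


def write_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(image))


def _check_keys(data: Mapping, allowed: Sequence[str], where: str) -> None:
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated parameters for the end-to-end pipeline.

    ``scene`` holds synthetic-scene parameters (the pipeline simulates its
    input when present); otherwise ``inputs`` must point at a spot table or at
    a nuclei image plus per-gene spot channels. Thresholds for spot detection
    are sample-specific and deliberately have no default.
    """

    schema_version: int = 1
    seed: int = 0
    x_gene: str = "X"
    y_gene: str = "Y"
    expansion_distance: float = 20.0
    min_area: float = 20.0
    tophat_radius: float = 4.0
    thresholds: dict[str, float] = dc_field(default_factory=dict)
    kernel_window: int = 150
    kernel_sd: float = 25.0
    n_rand: int = 100
    n_bins: int = 50
    cutoff: float = 0.8
    eps: float | None = None
    scene: Mapping[str, Any] | None = None
    inputs: Mapping[str, Any] | None = None
    landmarks: Mapping[str, Any] | None = None
    out_dir: str = "xyspot_out"

    _TOP_KEYS = (
        "schema_version", "seed", "x_gene", "y_gene", "expansion_distance",
        "min_area", "tophat_radius", "thresholds", "kernel_window", "kernel_sd",
        "n_rand", "n_bins", "cutoff", "eps", "scene", "inputs", "landmarks", "out_dir",
    )

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        _check_keys(data, cls._TOP_KEYS, "run config")
        cfg = cls(**{k: v for k, v in data.items()})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.schema_version != 1:
            raise ConfigError(f"unsupported schema_version {self.schema_version}")
        if self.scene is None and self.inputs is None:
            raise ConfigError("config needs either 'scene' (simulate) or 'inputs'")
        if self.inputs is not None:
            _check_keys(self.inputs, ("spot_table", "nuclei_image", "spot_images", "tissue_mask"),
                        "inputs")
            has_table = "spot_table" in self.inputs
            has_images = "nuclei_image" in self.inputs and "spot_images" in self.inputs
            if not (has_table or has_images):
                raise ConfigError(
                    "inputs need 'spot_table' or both 'nuclei_image' and 'spot_images'"
                )
            if has_images:
                for gene in (self.x_gene, self.y_gene):
                    if gene not in self.inputs["spot_images"]:
                        raise ConfigError(f"inputs.spot_images missing channel for {gene!r}")
                    if gene not in self.thresholds:
                        raise ConfigError(
                            f"no detection threshold configured for {gene!r}; "
                            "thresholds are sample-specific and required"
                        )
        if self.landmarks is not None:
            _check_keys(self.landmarks, ("left", "right"), "landmarks")
            for side in ("left", "right"):
                if side not in self.landmarks:
                    raise ConfigError(f"landmarks missing {side!r} pair")
        if self.n_rand < 2:
            raise ConfigError("n_rand must be >= 2")
        if not 0.5 < self.cutoff <= 1.0:
            raise ConfigError("cutoff must lie in (0.5, 1]")


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError("run config must be a mapping")
    return RunConfig.from_dict(data)
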