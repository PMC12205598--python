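"""Image and table IO, configuration, and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd


class UnsupportedImageError(ValueError):
    pass


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF or PNG (8/16-bit) as an integer array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise UnsupportedImageError(f"unsupported image format {suffix!r}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise UnsupportedImageError(f"unsupported bit depth {arr.dtype}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8/16-bit single-channel image losslessly (TIFF or PNG)."""
    path = Path(path)
    image = np.asarray(image)
    if image.dtype not in (np.uint8, np.uint16):
        raise UnsupportedImageError(f"unsupported bit depth {image.dtype}; cast to uint8/uint16")
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, image)
    else:
        raise UnsupportedImageError(f"unsupported image format {suffix!r}")


# stable CSV schemas; validated on read
SCHEMAS: dict[str, list[str]] = {
    "cells": [
        "cell_id", "protein", "background", "replicate", "field",
        "center_row", "center_col", "mean_raw_intensity",
    ],
    "scores": ["protein", "n_cells_wt", "n_cells_del", "score", "threshold", "flag_redistributed"],
    "abundance": [
        "protein", "score_wt", "score_del", "n_cells_wt", "n_cells_del",
        "log2fc", "p", "q", "abundance_class",
    ],
    "ppi_edges": ["gene_a", "gene_b", "system_type", "throughput", "study_id"],
    "gi_edges": ["gene_a", "gene_b", "epsilon", "p"],
    "localizations": ["protein", "compartments"],
}


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    if schema is not None:
        missing = [c for c in SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise ValueError(f"table missing schema columns {missing} for schema {schema!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if schema is not None:
        missing = [c for c in SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing schema columns {missing} for schema {schema!r}")
    return df


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written alongside pipeline outputs."""

    config: dict
    seed: int
    stages: list[str] = dc_field(default_factory=list)
    file_hashes: dict[str, str] = dc_field(default_factory=dict)
    started: float = dc_field(default_factory=time.time)
    version: str = "0.1.0"

    def record_file(self, path: str | Path) -> None:
        self.file_hashes[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "config": self.config,
            "seed": self.seed,
            "stages": self.stages,
            "file_hashes": self.file_hashes,
            "started": self.started,
            "finished": time.time(),
            "version": self.version,
        }
        path.write_text(json.dumps(payload, indent=2, default=str))


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
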