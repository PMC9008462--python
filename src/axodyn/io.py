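"""Readers/writers: multi-frame TIFF movies with key-value metadata
sidecars, and the CSV tables exchanged between pipeline stages."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .camera import CameraModel

__all__ = ["write_movie", "read_movie", "write_metadata", "read_metadata",
           "write_table", "read_table"]

_META_KEYS = ("pixel_size_um", "frame_interval_s", "gain", "offset",
              "read_noise")


def write_metadata(path, camera: CameraModel, extra: dict | None = None):
    """Key-value text sidecar describing the acquisition."""
    lines = [f"{k} = {getattr(camera, k)}" for k in _META_KEYS]
    for k, v in (extra or {}).items():
        lines.append(f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        try:
            out[key.strip()] = float(value)
        except ValueError:
            out[key.strip()] = value.strip()
    return out


def write_movie(path, movie: np.ndarray, camera: CameraModel | None = None,
                extra_meta: dict | None = None):
    """16-bit single-channel multi-frame TIFF plus ``<name>.meta.txt``."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie, dtype=np.uint16))
    if camera is not None:
        write_metadata(path.with_suffix(path.suffix + ".meta.txt"),
                       camera, extra_meta)


def read_movie(path):
    """Return ``(movie, metadata_dict)``; metadata may be empty."""
    path = Path(path)
    movie = tifffile.imread(path)
    if movie.ndim == 2:
        movie = movie[None]
    meta_path = path.with_suffix(path.suffix + ".meta.txt")
    meta = read_metadata(meta_path) if meta_path.exists() else {}
    return movie, meta


def write_table(path, df: pd.DataFrame):
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
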