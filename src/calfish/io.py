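"""Reading and writing the pipeline's file formats.

Wide-field movies are multi-page TIFFs with 340/385 nm frames interleaved
(page order configurable), confocal Z-stacks are one multi-page TIFF per
channel, ROIs are a label TIFF (pixel value = cell id), negative controls
and tables are CSV, transforms and run reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def write_movie(path, movie: np.ndarray, channel_order=("340", "385")) -> None:
    """Write a (t, 2, y, x) movie as an interleaved multi-page TIFF."""
    movie = np.asarray(movie)
    if movie.ndim != 4 or movie.shape[1] != 2:
        raise ValueError("movie must have shape (t, 2, y, x)")
    pages = movie.reshape(-1, *movie.shape[2:])
    tifffile.imwrite(path, pages, photometric="minisblack", metadata={
        "channel_order": list(channel_order), "n_frames": int(movie.shape[0])})


def read_movie(path, channel_order=("340", "385")) -> np.ndarray:
    """Read an interleaved movie TIFF back to (t, 2, y, x); ``channel_order``
    names the page interleave, e.g. ("385", "340") if the 385 nm frame of
    each pair was acquired first."""
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % 2:
        raise ValueError(f"movie TIFF has odd page count {pages.shape[0]}")
    movie = pages.reshape(-1, 2, *pages.shape[1:])
    order = [str(c) for c in channel_order]
    if order == ["385", "340"]:
        movie = movie[:, ::-1]
    elif order != ["340", "385"]:
        raise ValueError(f"channel_order must name 340 and 385, got {channel_order}")
    return movie


def write_stack(path, stack: np.ndarray, **metadata) -> None:
    data = np.asarray(stack)
    kwargs = {"photometric": "minisblack"} if data.ndim == 3 else {}
    tifffile.imwrite(path, data, metadata=metadata or None, **kwargs)


def read_stack(path) -> np.ndarray:
    data = tifffile.imread(path)
    return data[None] if data.ndim == 2 else data


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels).astype(np.int32))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_json(path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _config_to_dict(config) -> dict:
    from dataclasses import asdict, is_dataclass

    def conv(v):
        if is_dataclass(v) and not isinstance(v, type):
            return {k: conv(x) for k, x in asdict(v).items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, np.generic):
            return v.item()
        return v

    return conv(config)


def write_dataset(dataset, outdir) -> None:
    """Persist a synthetic dataset: TIFF images, CSV tables, YAML config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_movie(out / "widefield_movie.tif", dataset.movie)
    write_stack(out / "widefield_trans.tif", dataset.widefield_trans)
    write_labels(out / "roi_labels.tif", dataset.roi_labels)
    for name, stack in dataset.confocal.items():
        write_stack(out / f"confocal_{name}.tif", stack)
    write_stack(out / "confocal_trans.tif", dataset.confocal_trans)
    dataset.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    pd.DataFrame({"intensity": dataset.negative_controls}).to_csv(
        out / "negative_controls.csv", index=False)
    dataset.transform.save(out / "true_transform.json")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(dataset.config), fh, sort_keys=True)


def read_controls(path) -> np.ndarray:
    df = pd.read_csv(path)
    col = "intensity" if "intensity" in df.columns else df.columns[0]
    return df[col].to_numpy(dtype=float)
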