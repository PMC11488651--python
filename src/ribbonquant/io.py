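"""TIFF and CSV round-tripping for stacks, movies and ground truth."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def save_stack_tiff(path: str | Path, stack: dict[str, np.ndarray]) -> None:
    """Write a channel-keyed ``(z, y, x)`` stack dict as an ImageJ ZCYX TIFF."""
    names = list(stack)
    # ImageJ hyperstack order puts channels inside z: (z, c, y, x)
    data = np.stack([stack[ch] for ch in names], axis=1).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        metadata={"axes": "ZCYX", "Labels": names},
    )


def load_stack_tiff(path: str | Path, channels: list[str]) -> dict[str, np.ndarray]:
    """Read a ZCYX TIFF back into a channel-keyed dict."""
    data = tifffile.imread(path)
    if data.ndim == 3:  # single channel: (z, y, x)
        data = data[:, None]
    if data.shape[1] != len(channels):
        raise ValueError(f"TIFF has {data.shape[1]} channels, expected {len(channels)}")
    return {ch: data[:, i] for i, ch in enumerate(channels)}


def save_movie_tiff(path: str | Path, movie: np.ndarray) -> None:
    """Write a ``(t, z, y, x)`` movie as an ImageJ TZYX TIFF."""
    tifffile.imwrite(path, movie.astype(np.float32), imagej=True, metadata={"axes": "TZYX"})


def load_movie_tiff(path: str | Path) -> np.ndarray:
    movie = tifffile.imread(path)
    if movie.ndim != 4:
        raise ValueError(f"expected a 4-D movie, got shape {movie.shape}")
    return movie


def save_ground_truth(directory: str | Path, truth) -> None:
    """Write the tabular parts of a GroundTruthSynapses to CSV + mask TIFF."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.puncta.to_csv(directory / "puncta.csv", index=False)
    truth.per_cell.to_csv(directory / "per_cell.csv", index=False)
    tifffile.imwrite(directory / "mask.tif", truth.mask_labels)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
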