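"""CSV / TIFF input and output.

Coordinate CSVs carry a header ``x,y`` (or ``x,y,z``); a long-format file
``channel,x,y[,z]`` holds all channels at once, with channels labeled
A, B, C, ... in chain order.  Multi-channel images are multi-page TIFFs,
one page per channel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .matching import AbundanceCurve, ChainMatching, parse_structure
from .points import CHANNEL_LETTERS, PointCloudSet, channel_name


def read_channel_csvs(paths: list[str | Path], unit: str = "px",
                      pixel_size_nm: float | None = None) -> PointCloudSet:
    """One CSV per channel, in chain order, header ``x,y[,z]``."""
    clouds = []
    for path in paths:
        df = pd.read_csv(path)
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        if len(cols) < 2:
            raise ValueError(f"{path}: expected columns x,y[,z], got {list(df.columns)}")
        clouds.append(df[cols].to_numpy(dtype=float))
    return PointCloudSet(clouds, unit=unit, pixel_size_nm=pixel_size_nm)


def read_long_csv(path: str | Path, unit: str = "px",
                  pixel_size_nm: float | None = None) -> PointCloudSet:
    """Single long-format CSV with columns ``channel,x,y[,z]``."""
    df = pd.read_csv(path)
    if "channel" not in df.columns:
        raise ValueError(f"{path}: long format needs a 'channel' column")
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    labels = sorted(df["channel"].astype(str).unique())
    clouds = [df.loc[df["channel"].astype(str) == lab, cols].to_numpy(dtype=float)
              for lab in labels]
    return PointCloudSet(clouds, unit=unit, pixel_size_nm=pixel_size_nm)


def read_distance_matrix_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def write_structures_csv(path: str | Path, matching: ChainMatching,
                         clouds: PointCloudSet) -> None:
    """Matched structures, one row per involved particle."""
    rows = []
    chain_id = 0
    dim = clouds.dim
    for name, chains in sorted(matching.structures.items(),
                               key=lambda kv: (-len(kv[0]), kv[0])):
        j0, _ = parse_structure(name, matching.k)
        for chain in chains:
            for off, idx in enumerate(chain):
                j = j0 + off
                coord = clouds.clouds[j][idx]
                row = {"structure_type": name, "channel": channel_name(j),
                       "particle_index": idx, "x": coord[0], "y": coord[1],
                       "chain_id": chain_id}
                if dim == 3:
                    row["z"] = coord[2]
                rows.append(row)
            chain_id += 1
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curve_csv(path: str | Path, curve: AbundanceCurve) -> None:
    rows = []
    for i, t in enumerate(curve.t_grid):
        for name, count in curve.vectors[i].w.items():
            row = {"t": t, "structure": name, "count": count}
            if curve.relative is not None:
                row["relative"] = curve.relative[i][name]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_corrected_curve_csv(path: str | Path, corrected) -> None:
    rows = []
    for i, t in enumerate(corrected.t_grid):
        for j, name in enumerate(corrected.structures):
            rows.append({"t": t, "structure": name, "w": corrected.w[i, j],
                         "n_hat": corrected.n_hat[i, j],
                         "ci_low": corrected.lo[i, j],
                         "ci_high": corrected.hi[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_image_tiff(path: str | Path, images: list[np.ndarray]) -> None:
    tifffile.imwrite(path, np.stack(images).astype(np.float32),
                     photometric="minisblack")


def read_image_tiff(path: str | Path) -> list[np.ndarray]:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        return [arr]
    return [arr[i] for i in range(arr.shape[0])]


def write_manifest(path: str | Path, config: dict) -> None:
    """Echo the run configuration (incl. seed) so runs are reproducible."""
    import chainmatch

    payload = {"chainmatch_version": chainmatch.__version__, **config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
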