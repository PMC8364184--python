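"""Dataset serialization: multi-page TIFF sequences and CSV manifests.

Each image sequence is written as a multi-page TIFF (one 32-bit float page
per frame).  A dataset manifest is a CSV with one row per example: the
sequence path, the eight ground-truth velocity components, the per-axis
vestibular tuning widths, and the 128 noiseless vestibular input values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .training import Dataset

AXES = "xyzr"


def write_sequence_tiff(path, frames: np.ndarray) -> None:
    """Write an (H, W, T) sequence as a T-page float32 TIFF."""
    tifffile.imwrite(str(path), np.moveaxis(frames, -1, 0).astype(np.float32))


def read_sequence_tiff(path) -> np.ndarray:
    pages = tifffile.imread(str(path))
    return np.moveaxis(pages, 0, -1).astype(np.float32)


def export_dataset(dataset: Dataset, out_dir) -> Path:
    """Write sequences and a manifest.csv; returns the manifest path."""
    out = Path(out_dir)
    (out / "sequences").mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(dataset)):
        rel = f"sequences/seq{dataset.ids[i]:06d}.tif"
        write_sequence_tiff(out / rel, dataset.visual[i])
        row = {"id": int(dataset.ids[i]), "path": rel}
        for j, ax in enumerate(AXES):
            row[f"vis_v{ax}"] = dataset.vis_v[i, j]
            row[f"vest_v{ax}"] = dataset.vest_v[i, j]
            row[f"sigma_{ax}"] = dataset.sigma[i, j]
        flat = dataset.vest_profile[i].reshape(-1)
        for k, v in enumerate(flat):
            row[f"vest_{k:03d}"] = v
        rows.append(row)
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path) -> Dataset:
    """Load a dataset written by :func:`export_dataset`."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    visual = np.stack([read_sequence_tiff(base / p) for p in df["path"]])
    vest_cols = sorted(c for c in df.columns if c.startswith("vest_") and c[5:].isdigit())
    vest = df[vest_cols].to_numpy(dtype=np.float32).reshape(len(df), 4, -1)
    return Dataset(
        visual=visual,
        vest_profile=vest,
        vis_v=df[[f"vis_v{ax}" for ax in AXES]].to_numpy(),
        vest_v=df[[f"vest_v{ax}" for ax in AXES]].to_numpy(),
        sigma=df[[f"sigma_{ax}" for ax in AXES]].to_numpy(),
        ids=df["id"].to_numpy(),
    )
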