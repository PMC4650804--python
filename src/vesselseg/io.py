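"""Volume and result I/O: multi-page TIFF stacks, CSV tables, manifests."""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .volume import Tomogram


def read_volume(path, voxel_size_um: float = 1.0, axial_axis: int = 0) -> Tomogram:
    """Read a greyscale multi-page TIFF stack (one trans-axial slice per page).

    Integer data are promoted to float without rescaling.  TIFF carries no
    reliable isotropic-spacing metadata, so the voxel size is supplied by the
    caller.  Pages with inconsistent shapes raise an error naming the page.
    """
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError(f"unknown volume format {path.suffix!r}; expected a TIFF stack")
    with tifffile.TiffFile(path) as tif:
        shapes = [p.shape for p in tif.pages]
        if not shapes:
            raise ValueError(f"{path} contains no pages")
        for i, s in enumerate(shapes):
            if s != shapes[0]:
                raise ValueError(
                    f"inconsistent page shapes in {path}: page {i} is {s}, page 0 is {shapes[0]}"
                )
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    return Tomogram(arr.astype(np.float32), voxel_size_um, axial_axis)


def write_volume(path, vol: Tomogram | np.ndarray) -> None:
    arr = vol.values if isinstance(vol, Tomogram) else np.asarray(vol)
    tifffile.imwrite(path, arr, photometric="minisblack")


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint8), photometric="minisblack")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def contours_table(seg) -> pd.DataFrame:
    """Flatten a SegmentationResult into a per-(slice, row) contour table.

    Columns carry the unwrapped-frame boundary and outer-edge columns, the
    luminal radius, and the re-wrapped trans-axial (x, y) of the boundary.
    """
    rows = []
    n_rows = seg.boundary_cols.shape[1]
    row_idx = np.arange(n_rows, dtype=float)
    lumen_r = seg.lumen_radius_map()
    for z, tr in enumerate(seg.transforms):
        if tr is None:
            continue
        b = np.clip(seg.boundary_cols[z], 0.0, tr.n_cols - 1e-6)
        xy = tr.to_plane(row_idx, b)
        for r in range(n_rows):
            rows.append(
                {
                    "slice": z,
                    "row": r,
                    "boundary_col": seg.boundary_cols[z, r],
                    "outer_col": seg.outer_cols[z, r],
                    "lumen_radius_vox": lumen_r[z, r],
                    "x": xy[r, 0],
                    "y": xy[r, 1],
                }
            )
    return pd.DataFrame(rows)


def write_outputs(
    outdir,
    labels: np.ndarray,
    contours: pd.DataFrame,
    tables: dict[str, pd.DataFrame],
    log_text: str = "",
) -> dict:
    """Write labels, contours, tables and a run log; return a checksum manifest.

    The manifest (``manifest.json``) is written last and lists every output
    file with its SHA-256 checksum; if any write fails no manifest is left
    behind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    written: list[Path] = []
    try:
        p = outdir / "labels.tif"
        write_labels(p, labels)
        written.append(p)
        p = outdir / "contours.csv"
        contours.to_csv(p, index=False)
        written.append(p)
        for name, df in tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        p = outdir / "run.log"
        p.write_text(log_text)
        written.append(p)
        manifest = {f.name: _sha256(f) for f in written}
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception:
        if manifest_path.exists():
            manifest_path.unlink()
        raise
    return manifest
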