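"""Readers and writers for the formats shared by the command-line tools.

Color images: PNG/PPM (8-bit RGB).  Depth/disparity: 16-bit grayscale PNG
or whitespace-separated text matrices.  Label maps: 16-bit PNG.  Scan paths:
JSON (list of {frame, x, y, object_id, sal}) or CSV.  Fixations: CSV with
header ``image,subject,order,x,y`` in 0-based pixel coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .attention import FixationRecord, ScanPath


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    if img.dtype != np.uint8:
        img = (img / img.max() * 255).astype(np.uint8) if img.max() > 0 else img.astype(np.uint8)
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_depth(path: str | Path) -> np.ndarray:
    """16-bit PNG or plain-text matrix -> float depth map."""
    path = Path(path)
    if path.suffix.lower() in (".png", ".pgm", ".tif", ".tiff"):
        return iio.imread(path).astype(np.float64)
    return np.loadtxt(path, dtype=np.float64)


def write_depth(path: str | Path, depth: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(depth, dtype=np.float64)
        iio.imwrite(path, np.clip(np.rint(arr), 0, 65535).astype(np.uint16))
    else:
        np.savetxt(path, np.asarray(depth), fmt="%.6g")


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(labels, dtype=np.uint16))


def read_fixations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scanpath(path: str | Path, scan_path: ScanPath) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(scan_path.to_records(), indent=2))
    else:
        pd.DataFrame(scan_path.to_records()).to_csv(path, index=False)


def read_scanpath(path: str | Path) -> ScanPath:
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    return ScanPath(
        [
            FixationRecord(
                frame=int(r["frame"]),
                x=float(r["x"]),
                y=float(r["y"]),
                object_id=int(r["object_id"]),
                sal=float(r["sal"]),
            )
            for r in records
        ]
    )
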