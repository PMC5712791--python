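"""Image and tabular IO.

Images are read with tifffile/imageio and normalized to float64 in [0, 1]
by the source bit-depth maximum (255 or 65535). RGB(A) frames are collapsed
to luminance; multi-frame stacks are rejected.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import Circle, CircleSet

CIRCLE_COLUMNS = ["image", "row", "col", "radius", "fluorescent"]

# ITU-R BT.601 luminance weights for RGB collapse
_LUMA = np.array([0.299, 0.587, 0.114])


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale TIFF/PNG as a float image in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = (arr[..., :3].astype(np.float64) @ _LUMA).astype(arr.dtype)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        maxval = 255.0
    elif arr.dtype == np.uint16:
        maxval = 65535.0
    else:
        raise ValueError(
            f"{path}: unsupported dtype {arr.dtype}; 8- or 16-bit grayscale required"
        )
    return arr.astype(np.float64) / maxval


def write_image(image: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as 8- or 16-bit TIFF/PNG."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.clip(np.rint(np.asarray(image) * 255), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.clip(np.rint(np.asarray(image) * 65535), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean map as an 8-bit 0/255 PNG or TIFF."""
    write_image(np.asarray(mask, dtype=bool).astype(np.float64), path, bit_depth=8)


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0.5


def write_circles(circles: CircleSet, path: str | Path, image: str = "") -> None:
    """Write circles as CSV (``image,row,col,radius,fluorescent``).

    Rows are ordered by (row, col); coordinates are 0-based pixels.
    """
    circles.to_dataframe(image=image).to_csv(path, index=False)


def read_circles(path: str | Path) -> CircleSet:
    df = pd.read_csv(Path(path))
    missing = set(CIRCLE_COLUMNS[1:]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: circle CSV missing columns {sorted(missing)}")
    if df.empty:
        return CircleSet([])
    flu = df["fluorescent"]
    if flu.dtype == object:
        flu = flu.astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
    return CircleSet(
        [
            Circle(row=float(r), col=float(c), radius=float(rad), fluorescent=bool(f))
            for r, c, rad, f in zip(df["row"], df["col"], df["radius"], flu)
        ]
    )
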