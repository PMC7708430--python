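"""Readers and writers for the pipeline's on-disk formats.

Flat 8-bit images only: RGB sections as TIFF or PNG, label maps as
single-channel PNG with the fixed code table {0 background, 1 other,
2 acinar, 3 adm, 4 dysplasia}, binary masks as 0/255 PNG, tabular reports as
CSV, evaluation summaries as JSON.  Reads of higher bit depths fail unless
conversion is explicitly allowed.  Pyramidal WSI formats are out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image, PngImagePlugin

LABEL_CODE_COMMENT = "panseg labels: 0=background 1=other 2=acinar 3=adm 4=dysplasia"


def _to_uint8(arr: np.ndarray, allow_convert: bool) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if not allow_convert:
        raise ValueError(
            f"unsupported bit depth {arr.dtype}; pass allow_convert=True to rescale"
        )
    arr = arr.astype(np.float64)
    hi = arr.max() if arr.max() > 0 else 1.0
    return np.clip(np.rint(arr / hi * 255.0), 0, 255).astype(np.uint8)


def read_image(path, allow_convert: bool = False) -> np.ndarray:
    """Read an RGB image (TIFF or PNG) as HxWx3 uint8."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = _to_uint8(np.asarray(arr), allow_convert)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] > 3:
        arr = arr[:, :, :3]
    return arr


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("images are written as 8-bit; convert explicitly first")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image, photometric="rgb")
    else:
        Image.fromarray(image).save(path)


def read_label_map(path) -> np.ndarray:
    """Read a single-channel label PNG; validates the code range."""
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError("label maps must be single-channel")
    if arr.max(initial=0) > 4:
        raise ValueError("label map contains codes outside 0..4")
    return arr.astype(np.uint8)


def write_label_map(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.max(initial=0) > 4:
        raise ValueError("label map must be 2-D with codes 0..4")
    info = PngImagePlugin.PngInfo()
    info.add_text("Comment", LABEL_CODE_COMMENT)
    Image.fromarray(labels.astype(np.uint8), mode="L").save(path, pnginfo=info)


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG (any nonzero pixel is True)."""
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask).astype(bool)
    Image.fromarray((mask * np.uint8(255)), mode="L").save(path)
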