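"""Image and label-table input/output.

Speckle images are 8-bit grayscale PNG (or TIFF); RGB inputs are converted
to luminance with a warning, higher bit depths require an explicit flag.
Label tables are CSV with columns ``image_path, ra_nm, seed``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .simulate import SpeckleImage

__all__ = ["read_image", "write_image", "read_labelled_images", "write_dataset"]


def _center_crop(pixels: np.ndarray, roi: tuple[int, int]) -> np.ndarray:
    rows, cols = roi
    if rows > pixels.shape[0] or cols > pixels.shape[1]:
        raise ValueError(
            f"ROI {roi} larger than image {pixels.shape}")
    r0 = (pixels.shape[0] - rows) // 2
    c0 = (pixels.shape[1] - cols) // 2
    return pixels[r0:r0 + rows, c0:c0 + cols]


def read_image(path, *, roi: tuple[int, int] | None = None,
               allow_depth_conversion: bool = False,
               label: str | None = None,
               ra_nm: float | None = None) -> SpeckleImage:
    """Load an 8-bit grayscale speckle image.

    RGB images are converted to luminance (with a warning).  Images deeper
    than 8 bits raise unless ``allow_depth_conversion`` is set, in which
    case they are rescaled to 8 bits.  ``roi`` takes a centred crop.
    """
    path = Path(path)
    with Image.open(path) as img:
        if img.mode == "L":
            pixels = np.asarray(img)
        elif img.mode in ("RGB", "RGBA"):
            warnings.warn(
                f"{path.name}: converting {img.mode} input to luminance",
                stacklevel=2)
            pixels = np.asarray(img.convert("L"))
        elif img.mode in ("I", "I;16", "I;16B", "F"):
            if not allow_depth_conversion:
                raise ValueError(
                    f"{path.name}: bit depth {img.mode!r} is not 8-bit; pass "
                    "allow_depth_conversion=True to rescale")
            data = np.asarray(img, dtype=float)
            top = data.max() if data.max() > 0 else 1.0
            pixels = np.floor(data / top * 255.0 + 0.5).astype(np.uint8)
        else:
            raise ValueError(f"{path.name}: unsupported image mode {img.mode!r}")
    if roi is not None:
        pixels = _center_crop(pixels, roi)
    return SpeckleImage(pixels=pixels, label=label or path.stem, ra_nm=ra_nm)


def write_image(image: SpeckleImage | np.ndarray, path) -> None:
    """Write an image as 8-bit grayscale PNG."""
    pixels = image.pixels if isinstance(image, SpeckleImage) else np.asarray(image)
    Image.fromarray(pixels.astype(np.uint8), mode="L").save(path)


def write_dataset(images: Sequence[SpeckleImage], out_dir) -> Path:
    """Write images as PNGs plus a ``labels.csv`` sidecar; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for idx, image in enumerate(images):
        name = (image.label or f"img_{idx:03d}") + ".png"
        write_image(image, out_dir / name)
        records.append({"image_path": name,
                        "ra_nm": image.ra_nm,
                        "seed": image.seed})
    labels = out_dir / "labels.csv"
    pd.DataFrame.from_records(records).to_csv(labels, index=False)
    return labels


def read_labelled_images(images_dir, *, roi: tuple[int, int] | None = None
                         ) -> list[SpeckleImage]:
    """Load every image listed in ``<images_dir>/labels.csv``."""
    images_dir = Path(images_dir)
    labels = images_dir / "labels.csv"
    if not labels.exists():
        raise FileNotFoundError(f"no labels.csv in {images_dir}")
    table = pd.read_csv(labels)
    if "image_path" not in table.columns:
        raise ValueError("labels.csv must have an image_path column")
    images = []
    for _, row in table.iterrows():
        ra = float(row["ra_nm"]) if "ra_nm" in table.columns else None
        images.append(read_image(images_dir / row["image_path"], roi=roi,
                                 ra_nm=ra))
    return images
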