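"""Image, mask, and label-map I/O plus dataset assembly.

Conventions used throughout the package: pixel coordinates are row-major
with the origin at the top-left corner, 0-based.  Images are standardized
to 256x256x3 uint8 (bilinear resize, grayscale replicated across channels);
masks are standardized with a nearest-neighbor resize so labels stay
strictly binary.  A mask file either shares the image basename with a
``_mask`` suffix or lives under a parallel ``masks/`` directory.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

STANDARD_SIZE = 256

__all__ = [
    "SmearImage", "BinaryMask", "DatasetSplit", "STANDARD_SIZE",
    "read_image", "read_mask", "split_dataset",
    "write_label_map", "read_label_map",
    "write_probability_map", "read_probability_map",
    "write_manifest", "read_manifest", "find_mask_for",
]


@dataclass
class SmearImage:
    """A standardized 3-channel blood-smear micrograph."""

    pixels: np.ndarray  # HxWx3 uint8
    original_size: tuple[int, int] | None = None  # (height, width) on disk
    path: Path | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SmearImage pixels must be HxWx3")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """Per-pixel white-blood-cell labels (1 = WBC)."""

    pixels: np.ndarray  # HxW uint8 in {0, 1}
    path: Path | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryMask values must be strictly 0/1")


@dataclass
class DatasetSplit:
    """A deterministic train/validation partition of (image, mask) pairs."""

    train_pairs: list[tuple[Path, Path]]
    val_pairs: list[tuple[Path, Path]]
    seed: int
    ratio: float


def read_image(path, size: int = STANDARD_SIZE) -> SmearImage:
    """Read a PNG/TIFF/JPEG micrograph and standardize it.

    Arbitrary sizes are accepted and resized (bilinear); grayscale inputs
    are replicated to three channels.  The original size is recorded so
    outputs can be mapped back.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.width == 0 or im.height == 0:
                raise ValueError(f"zero-area image: {path}")
            original = (im.height, im.width)
            if im.mode not in ("RGB", "L"):
                im = im.convert("RGB")
            if (im.height, im.width) != (size, size):
                im = im.resize((size, size), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.uint8)
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return SmearImage(pixels=arr, original_size=original, path=path)


def read_mask(path, size: int = STANDARD_SIZE) -> BinaryMask:
    """Read a ground-truth mask; any pixel above half range maps to 1.

    RGB masks are reduced to luminance first; resizing is nearest-neighbor
    so no fractional labels appear.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode not in ("L", "I;16", "I"):
                im = im.convert("L")
            if (im.height, im.width) != (size, size):
                im = im.resize((size, size), Image.NEAREST)
            arr = np.asarray(im)
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise OSError(f"cannot read mask file {path}: {exc}") from exc
    half = (np.iinfo(arr.dtype).max / 2.0) if arr.dtype.kind in "ui" else 0.5
    return BinaryMask(pixels=(arr > half).astype(np.uint8), path=path)


def split_dataset(pairs, ratio: float, seed: int) -> DatasetSplit:
    """Deterministically shuffle and partition pairs into train/val.

    The train share is ``round(ratio * n)`` clamped so neither side is
    empty; the same seed always produces the identical partition.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    order = np.random.default_rng(seed).permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    n_train = int(np.clip(round(ratio * len(pairs)), 1, len(pairs) - 1))
    return DatasetSplit(train_pairs=shuffled[:n_train],
                        val_pairs=shuffled[n_train:],
                        seed=seed, ratio=ratio)


def write_label_map(label_map: np.ndarray, path) -> Path:
    """Save an instance label map losslessly as 16-bit single-channel TIFF."""
    arr = np.asarray(label_map)
    if arr.ndim != 2 or np.any(arr < 0):
        raise ValueError("label map must be a 2-D field of ids >= 0")
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances cannot be stored as uint16")
    path = Path(path)
    tifffile.imwrite(path, arr.astype(np.uint16))
    return path


def read_label_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int64)


def write_probability_map(prob_map: np.ndarray, path,
                          lossless: bool = False) -> Path:
    """Save a probability map: 8-bit PNG round(255*p), or 32-bit TIFF."""
    arr = np.asarray(prob_map, dtype=np.float64)
    if arr.ndim != 2 or arr.min(initial=0) < 0 or arr.max(initial=0) > 1:
        raise ValueError("probability map must be 2-D with values in [0, 1]")
    path = Path(path)
    if lossless:
        tifffile.imwrite(path, arr.astype(np.float32))
    else:
        Image.fromarray(np.round(arr * 255.0).astype(np.uint8)).save(path)
    return path


def read_probability_map(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path).astype(np.float64)
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return arr / 255.0


def write_manifest(pairs, path) -> Path:
    """Write a two-column CSV manifest (image_path, mask_path)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_path", "mask_path"])
        for img, msk in pairs:
            writer.writerow([str(img), str(msk)])
    return path


def read_manifest(path) -> list[tuple[Path, Path]]:
    path = Path(path)
    pairs: list[tuple[Path, Path]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                {"image_path", "mask_path"} - set(reader.fieldnames):
            raise ValueError(f"manifest {path} lacks image_path/mask_path columns")
        base = path.parent
        for row in reader:
            img = Path(row["image_path"])
            msk = Path(row["mask_path"])
            pairs.append((img if img.is_absolute() else base / img,
                          msk if msk.is_absolute() else base / msk))
    return pairs


def find_mask_for(image_path) -> Path:
    """Locate the mask paired with an image by the package's conventions."""
    image_path = Path(image_path)
    candidate = image_path.with_name(
        image_path.stem + "_mask" + image_path.suffix)
    if candidate.exists():
        return candidate
    parallel = image_path.parent.parent / "masks" / image_path.name
    if parallel.exists():
        return parallel
    raise FileNotFoundError(f"no mask found for image {image_path}")
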