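"""Image and dataset I/O.

All images are handled internally as 2-D float64 arrays with intensities in
[0, 1] ("grey images"); 8-bit greyscale is the on-disk representation. RGB
inputs are collapsed to grey by an unweighted channel mean (configurable via
``rgb_weights``). Datasets are ordered lexicographically by path so that seeded
splits are reproducible across platforms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

CLASSES = ("fracture", "healthy")

SUPPORTED_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def validate_grey_image(img: np.ndarray, min_side: int = 1) -> np.ndarray:
    """Check the grey-image contract: 2-D, finite, intensities in [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"grey image must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < min_side or arr.shape[1] < min_side:
        raise ValidationError(
            f"image shape {arr.shape} smaller than required {min_side}x{min_side}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("image contains non-finite values")
    if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
        raise ValidationError(
            f"intensities outside [0, 1]: min={arr.min():.4g} max={arr.max():.4g}"
        )
    return np.clip(arr, 0.0, 1.0)


def load_image(
    path: str | Path,
    as_grey: bool = True,
    rgb_weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Load a PNG/JPEG/TIFF image as a grey image in [0, 1].

    RGB inputs are collapsed with ``rgb_weights`` (default: equal weights,
    i.e. the channel mean). Raises ``IOError`` naming the path for unreadable
    files and ``ValidationError`` for zero-sized images.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
    except FileNotFoundError:
        raise IOError(f"image file not found: {path}") from None
    except UnidentifiedImageError:
        raise IOError(f"unreadable image file: {path}") from None
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        if not as_grey:
            raise ValidationError("colour output is not supported; pass as_grey=True")
        arr = arr[..., :3]  # drop alpha
        w = np.full(3, 1.0 / 3.0) if rgb_weights is None else np.asarray(rgb_weights, float)
        if w.shape != (3,):
            raise ValidationError("rgb_weights must have exactly 3 entries")
        arr = arr @ (w / w.sum())
    return validate_grey_image(arr / 255.0)


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a grey image to disk as 8-bit greyscale (format from suffix)."""
    arr = validate_grey_image(img)
    u8 = np.rint(arr * 255.0).astype(np.uint8)
    Image.fromarray(u8, mode="L").save(Path(path))


def resize_to(img: np.ndarray, side: int) -> np.ndarray:
    """Resize a grey image to side x side with bilinear interpolation."""
    if side < 3:
        raise ValidationError(f"target side must be >= 3, got {side}")
    arr = validate_grey_image(img)
    if arr.shape == (side, side):
        return arr.copy()
    out = _sk_resize(
        arr, (side, side), order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


@dataclass
class LabeledDataset:
    """An ordered list of (path-or-image, label) pairs over the two classes."""

    items: list[tuple[object, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (_, label) in enumerate(self.items):
            if label not in CLASSES:
                raise ValidationError(
                    f"item {i}: unknown label {label!r}; expected one of {CLASSES}"
                )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.items]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for _, label in self.items:
            counts[label] += 1
        return counts

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.items[i] for i in indices])

    def images(self) -> np.ndarray:
        """Materialize all items as a stacked (n, H, W) array."""
        loaded = [
            it if isinstance(it, np.ndarray) else load_image(it)
            for it, _ in self.items
        ]
        return np.stack(loaded)


def load_dataset(root: str | Path) -> LabeledDataset:
    """Load a labeled dataset from class subdirectories or a CSV manifest.

    A directory root must contain ``fracture/`` and ``healthy/`` subdirectories
    of images; a CSV manifest must have a ``path,label`` header with paths
    relative to the manifest's directory (or absolute). Ordering is
    lexicographic by path.
    """
    root = Path(root)
    items: list[tuple[object, str]] = []
    if root.is_file():
        with open(root, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"path", "label"} <= set(reader.fieldnames):
                raise ValidationError(f"manifest {root} must have 'path,label' columns")
            for rownum, row in enumerate(reader, start=2):
                label = row["label"].strip()
                if label not in CLASSES:
                    raise ValidationError(
                        f"{root} row {rownum}: unknown label {label!r} "
                        f"(path {row['path']!r}); expected one of {CLASSES}"
                    )
                p = Path(row["path"])
                items.append((p if p.is_absolute() else root.parent / p, label))
    elif root.is_dir():
        for cls in CLASSES:
            sub = root / cls
            if sub.is_dir():
                items.extend(
                    (p, cls)
                    for p in sub.iterdir()
                    if p.suffix.lower() in SUPPORTED_SUFFIXES
                )
    else:
        raise IOError(f"dataset root not found: {root}")
    if not items:
        raise ValidationError(f"no labeled images found under {root}")
    items.sort(key=lambda pair: str(pair[0]))
    return LabeledDataset(items)


def write_manifest(ds: LabeledDataset, path: str | Path) -> None:
    """Write a ``path,label`` CSV manifest for a path-backed dataset."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        for item, label in ds.items:
            writer.writerow([str(item), label])
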