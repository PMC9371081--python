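"""Synthetic bone-phantom generator.

Real long-bone radiographs show a bright elongated shaft on a dark, noisy
background; a fracture appears as a narrow transverse dark discontinuity where
pixel intensity drops below the surrounding healthy bone. The phantoms emulate
exactly that geometry: a randomly oriented bright band (rotated rectangle)
with Gaussian-blurred borders (sigma = 1 px, so gradients are ramps rather
than ideal steps), additive Gaussian pixel noise, and — for the fracture
class — a dark gap of configurable width crossing the shaft at a configurable
angle. Everything is deterministic given the spec's seed; dataset items derive
their seeds as ``master_seed + index`` so a dataset can be extended without
regenerating earlier items.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .image_io import LabeledDataset, ValidationError, save_image, write_manifest


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of one phantom image.

    ``shaft_intensity`` must exceed ``background_intensity`` by more than
    3 * noise_sigma so the shaft edges are detectable by construction.
    ``gap_angle`` is measured from the shaft's own axis (90 = perpendicular
    transverse fracture).
    """

    side: int = 128
    shaft_width: int | None = None  # defaults to side // 4
    shaft_intensity: float = 0.85
    background_intensity: float = 0.15
    noise_sigma: float = 0.05
    fracture: bool = False
    gap_width: int = 6
    gap_angle: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 16:
            raise ValidationError(f"side must be >= 16, got {self.side}")
        if self.shaft_width is None:
            object.__setattr__(self, "shaft_width", self.side // 4)
        if not 0 < self.shaft_width < self.side:
            raise ValidationError(f"shaft_width must be in (0, side), got {self.shaft_width}")
        lo, hi = self.background_intensity, self.shaft_intensity
        if not (0 <= lo < hi <= 1):
            raise ValidationError(f"need 0 <= background < shaft <= 1, got {lo}, {hi}")
        if hi <= lo + 3 * self.noise_sigma:
            raise ValidationError(
                "shaft/background contrast must exceed 3*noise_sigma "
                f"(contrast {hi - lo:.3f}, noise_sigma {self.noise_sigma})"
            )
        if self.fracture and self.gap_width < 2:
            raise ValidationError(f"gap_width must be >= 2, got {self.gap_width}")


def shaft_axis_angle(spec: PhantomSpec) -> float:
    """The shaft orientation (radians) this spec's seed will produce."""
    rng = np.random.default_rng(spec.seed)
    return float(rng.uniform(0, np.pi))


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, str]:
    """Render one phantom; returns (grey image in [0, 1], label).

    The label is ``"fracture"`` when the spec's fracture flag is set, else
    ``"healthy"``.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.side
    angle = rng.uniform(0, np.pi)  # shaft axis direction
    # shaft center jitter keeps the band near, not exactly at, the middle
    cy = s / 2 + rng.uniform(-s / 16, s / 16)
    cx = s / 2 + rng.uniform(-s / 16, s / 16)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    # signed distance from the shaft axis (perpendicular direction)
    ux, uy = np.cos(angle), np.sin(angle)
    d_perp = -(yy - cy) * ux + (xx - cx) * uy
    shaft = np.abs(d_perp) <= spec.shaft_width / 2
    clean = np.where(shaft, spec.shaft_intensity, spec.background_intensity)

    if spec.fracture:
        # gap crosses the shaft at gap_angle relative to the axis, centered at
        # a point on the axis near the image middle
        t0 = rng.uniform(-s / 8, s / 8)
        gy, gx = cy + t0 * uy, cx + t0 * ux
        ga = angle + np.deg2rad(spec.gap_angle)
        gux, guy = np.cos(ga), np.sin(ga)
        d_gap = -(yy - gy) * gux + (xx - gx) * guy
        gap = (np.abs(d_gap) <= spec.gap_width / 2) & shaft
        clean = np.where(gap, spec.background_intensity, clean)

    clean = ndi.gaussian_filter(clean, sigma=1.0, mode="nearest")
    noisy = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    img = np.clip(noisy, 0.0, 1.0)
    return img, ("fracture" if spec.fracture else "healthy")


def shaft_mask(spec: PhantomSpec) -> np.ndarray:
    """The exact (pre-blur) shaft mask the spec's seed produces."""
    rng = np.random.default_rng(spec.seed)
    s = spec.side
    angle = rng.uniform(0, np.pi)
    cy = s / 2 + rng.uniform(-s / 16, s / 16)
    cx = s / 2 + rng.uniform(-s / 16, s / 16)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    d_perp = -(yy - cy) * np.cos(angle) + (xx - cx) * np.sin(angle)
    return np.abs(d_perp) <= spec.shaft_width / 2


def gap_mask(spec: PhantomSpec, widen: float = 2.0, interior_margin: float = 3.0) -> np.ndarray:
    """The exact (pre-blur) fracture-gap band this spec's seed produces,
    widened by ``widen`` pixels along the shaft to cover blurred gap borders
    and shrunk by ``interior_margin`` across it, so the band excludes the
    shaft's own side edges. Requires a fracture spec."""
    if not spec.fracture:
        raise ValidationError("gap_mask needs a fracture spec")
    rng = np.random.default_rng(spec.seed)
    s = spec.side
    angle = rng.uniform(0, np.pi)
    cy = s / 2 + rng.uniform(-s / 16, s / 16)
    cx = s / 2 + rng.uniform(-s / 16, s / 16)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    ux, uy = np.cos(angle), np.sin(angle)
    d_perp = -(yy - cy) * ux + (xx - cx) * uy
    shaft = np.abs(d_perp) <= spec.shaft_width / 2 - interior_margin
    t0 = rng.uniform(-s / 8, s / 8)
    gy, gx = cy + t0 * uy, cx + t0 * ux
    ga = angle + np.deg2rad(spec.gap_angle)
    gux, guy = np.cos(ga), np.sin(ga)
    d_gap = -(yy - gy) * gux + (xx - gx) * guy
    return (np.abs(d_gap) <= spec.gap_width / 2 + widen) & shaft


def add_salt_pepper(img: np.ndarray, fraction: float, seed: int = 0) -> np.ndarray:
    """Corrupt a grey image with impulse noise: ``fraction`` of the pixels
    (with replacement) are forced to 0 or 1 at random."""
    if not 0 <= fraction <= 1:
        raise ValidationError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    out = np.array(img, dtype=np.float64)
    n = int(fraction * out.size)
    ys = rng.integers(0, out.shape[0], n)
    xs = rng.integers(0, out.shape[1], n)
    out[ys, xs] = rng.integers(0, 2, n).astype(np.float64)
    return out


def generate_dataset(
    n_per_class: int,
    template: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> LabeledDataset:
    """A balanced in-memory phantom dataset (optionally written to disk).

    Item ``i`` uses seed ``seed + i``; fracture and healthy items alternate so
    truncation keeps the classes balanced. With ``out_dir`` set, images are
    written as PNGs plus a ``manifest.csv``, and the returned dataset is
    path-backed.
    """
    if n_per_class < 1:
        raise ValidationError(f"n_per_class must be >= 1, got {n_per_class}")
    items: list[tuple[object, str]] = []
    for i in range(2 * n_per_class):
        spec = replace(template, fracture=(i % 2 == 0), seed=seed + i)
        img, label = generate_phantom(spec)
        items.append((img, label))
    ds = LabeledDataset(items)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: list[tuple[object, str]] = []
        for i, (img, label) in enumerate(ds.items):
            p = out_dir / f"{label}_{i:05d}.png"
            save_image(img, p)
            paths.append((p, label))
        ds = LabeledDataset(paths)
        write_manifest(ds, out_dir / "manifest.csv")
    return ds
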