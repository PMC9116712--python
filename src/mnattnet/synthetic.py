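"""Procedural generator of labeled lymphocyte images with ground-truth
micronucleus masks.

Each frame emulates the structure of a Giemsa-type stained single-cell
photomicrograph: a pale background, a pink cytoplasm ellipse, a dark violet
nucleus, and — in positive images — one small round micronucleus lying in
the cytoplasm, separate from the nucleus. Three confounders seen in real
assay data are modeled: dark stain-contamination specks (decoys drawn from
the same size range as micronuclei, placed outside the cytoplasm),
understained low-contrast cells, and frames containing more than one cell.

The generator does not attempt photo-realism (no optics, no texture); its
geometry ranges are self-chosen and are not calibrated to any real scanner.
Every random choice flows through a per-call seeded generator, so an
identical scene specification renders a bit-identical image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PlacementError", "SceneSpec", "LabeledImage", "render_scene",
           "generate_dataset", "save_dataset", "DEFAULT_CONFOUNDER_RATES",
           "PALETTE"]

# All stain colors in one place (RGB, 0-255). stain_level linearly blends
# cell colors toward the background; specks are contaminant particles and
# stay dark regardless of staining.
PALETTE = {
    "background": np.array([246.0, 244.0, 247.0]),
    "cytoplasm": np.array([228.0, 192.0, 218.0]),
    "nucleus": np.array([96.0, 62.0, 134.0]),
    "micronucleus": np.array([104.0, 70.0, 140.0]),
    "speck": np.array([38.0, 36.0, 42.0]),
}

DEFAULT_CONFOUNDER_RATES = {"specked": 0.15, "understained": 0.15,
                            "multicell": 0.10}


class PlacementError(ValueError):
    """Raised when a micronucleus cannot be placed per the scene invariants."""


@dataclass
class SceneSpec:
    """Deterministic description of one rendered frame.

    ``seed`` drives noise and secondary geometry; two identical specs
    (including seed) render byte-identical images.
    """

    image_size: int = 224
    nucleus_center: tuple[float, float] = (112.0, 112.0)
    nucleus_axes: tuple[float, float] = (32.0, 28.0)
    has_micronucleus: bool = False
    mn_center: tuple[float, float] = (0.0, 0.0)
    mn_radius: float = 5.0
    n_specks: int = 0
    stain_level: float = 1.0
    n_cells: int = 1
    noise_sigma: float = 4.0
    psf_sigma: float = 0.8  # optical point-spread blur, px (0 disables)
    cyto_scale: float = 2.1  # cytoplasm axes = cyto_scale * nucleus_axes
    seed: int = 0

    @property
    def cyto_axes(self) -> tuple[float, float]:
        return (self.cyto_scale * self.nucleus_axes[0],
                self.cyto_scale * self.nucleus_axes[1])

    def validate(self) -> None:
        a, b = self.nucleus_axes
        if not 0 <= self.stain_level <= 1:
            raise ValueError(f"stain_level must be in [0,1], got {self.stain_level}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not self.has_micronucleus:
            return
        r = self.mn_radius
        if r < 2:
            raise PlacementError(f"micronucleus radius must be >= 2 px, got {r}")
        if r > min(a, b) / 3:
            raise PlacementError(
                f"micronucleus radius {r} exceeds min(nucleus_axes)/3 = {min(a, b) / 3:.1f}")
        cx, cy = self.nucleus_center
        x, y = self.mn_center
        ca, cb = self.cyto_axes
        # disc must fit inside the cytoplasm ellipse (conservative shrink by r)
        if ((x - cx) / (ca - r)) ** 2 + ((y - cy) / (cb - r)) ** 2 > 1:
            raise PlacementError("micronucleus disc extends beyond the cytoplasm")
        # and clear the nucleus ellipse (inflate by r plus a 1 px guard)
        if ((x - cx) / (a + r + 1)) ** 2 + ((y - cy) / (b + r + 1)) ** 2 < 1:
            raise PlacementError("micronucleus disc overlaps the nucleus")


@dataclass
class LabeledImage:
    """One RGB cell image with a binary label (1 = micronucleus present)."""

    pixels: np.ndarray  # (H, W, 3) uint8
    label: int
    mn_mask: np.ndarray | None = None  # (H, W) uint8, synthetic images only
    provenance: str = "original"
    id: str = ""
    parent_id: str = ""

    def __post_init__(self):
        if self.mn_mask is not None:
            has_px = bool(np.any(self.mn_mask))
            if has_px != (self.label == 1):
                raise ValueError("label/mask inconsistency: label="
                                 f"{self.label}, mask nonzero={has_px}")


def _ellipse_mask(size: int, center, axes) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    cx, cy = center
    a, b = axes
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _disc_mask(size: int, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2


def _stain(color: np.ndarray, level: float) -> np.ndarray:
    bg = PALETTE["background"]
    return bg + level * (color - bg)


def render_scene(spec: SceneSpec) -> LabeledImage:
    """Deterministically render one scene to an 8-bit RGB image + mask."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    canvas = np.tile(PALETTE["background"], (size, size, 1))

    def paint(mask, color):
        canvas[mask] = color

    # secondary cells first, partially framed near the border, never positive
    for _ in range(spec.n_cells - 1):
        angle = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.42, 0.55) * size
        cx = spec.nucleus_center[0] + dist * np.cos(angle)
        cy = spec.nucleus_center[1] + dist * np.sin(angle)
        na = rng.uniform(18, 26)
        nb = rng.uniform(16, 24)
        paint(_ellipse_mask(size, (cx, cy), (spec.cyto_scale * na, spec.cyto_scale * nb)),
              _stain(PALETTE["cytoplasm"], spec.stain_level))
        paint(_ellipse_mask(size, (cx, cy), (na, nb)),
              _stain(PALETTE["nucleus"], spec.stain_level))

    paint(_ellipse_mask(size, spec.nucleus_center, spec.cyto_axes),
          _stain(PALETTE["cytoplasm"], spec.stain_level))
    paint(_ellipse_mask(size, spec.nucleus_center, spec.nucleus_axes),
          _stain(PALETTE["nucleus"], spec.stain_level))

    mn_mask = np.zeros((size, size), dtype=np.uint8)
    if spec.has_micronucleus:
        disc = _disc_mask(size, spec.mn_center, spec.mn_radius)
        if not disc.any():
            raise PlacementError("micronucleus disc rasterized to zero pixels")
        paint(disc, _stain(PALETTE["micronucleus"], spec.stain_level))
        mn_mask[disc] = 1

    # contamination specks: dark dots outside the cytoplasm, same size range
    # as micronuclei (deliberate decoys); they can never touch the mn mask
    ca, cb = spec.cyto_axes
    cx0, cy0 = spec.nucleus_center
    placed = 0
    attempts = 0
    while placed < spec.n_specks and attempts < 200:
        attempts += 1
        x = rng.uniform(4, size - 4)
        y = rng.uniform(4, size - 4)
        r = rng.uniform(3, 7)
        if ((x - cx0) / (ca + r + 2)) ** 2 + ((y - cy0) / (cb + r + 2)) ** 2 <= 1:
            continue  # inside / too close to the main cell
        paint(_disc_mask(size, (x, y), r), PALETTE["speck"])
        placed += 1

    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
    if spec.psf_sigma > 0:
        # optical point-spread blur: real photomicrographs carry no iid
        # pixel noise; blurring after the noise correlates it like optics do
        from scipy import ndimage
        canvas = ndimage.gaussian_filter(
            canvas, sigma=(spec.psf_sigma, spec.psf_sigma, 0.0))
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return LabeledImage(pixels=pixels, label=int(spec.has_micronucleus),
                        mn_mask=mn_mask)


def _random_scene(rng: np.random.Generator, positive: bool, specked: bool,
                  understained: bool, multicell: bool,
                  image_size: int) -> SceneSpec:
    """Draw one scene spec; retries micronucleus placement until valid."""
    c = image_size / 2
    for _ in range(100):
        nucleus_center = (c + rng.uniform(-15, 15), c + rng.uniform(-15, 15))
        nucleus_axes = (rng.uniform(26, 38), rng.uniform(24, 34))
        stain = rng.uniform(0.25, 0.45) if understained else rng.uniform(0.8, 1.0)
        spec = SceneSpec(
            image_size=image_size,
            nucleus_center=nucleus_center,
            nucleus_axes=nucleus_axes,
            has_micronucleus=positive,
            n_specks=int(rng.integers(1, 4)) if specked else 0,
            stain_level=float(stain),
            n_cells=2 if multicell else 1,
            seed=int(rng.integers(2 ** 31)),
        )
        if positive:
            r = float(rng.integers(3, 8))
            angle = rng.uniform(0, 2 * np.pi)
            # radial band between the nucleus and cytoplasm boundaries
            na = np.hypot(nucleus_axes[0] * np.cos(angle), nucleus_axes[1] * np.sin(angle))
            lo = na + r + 3
            hi = spec.cyto_scale * na - r - 3
            if hi <= lo:
                continue
            d = rng.uniform(lo, hi)
            spec.mn_center = (nucleus_center[0] + d * np.cos(angle),
                              nucleus_center[1] + d * np.sin(angle))
            spec.mn_radius = r
        try:
            spec.validate()
        except PlacementError:
            continue
        return spec
    raise PlacementError("could not draw a valid scene in 100 attempts")


def generate_dataset(n_pos: int, n_neg: int,
                     confounder_rates: dict | None = None,
                     seed: int = 0, image_size: int = 224) -> list[LabeledImage]:
    """Render exactly ``n_pos`` positive and ``n_neg`` negative frames.

    ``confounder_rates`` gives the per-image probability of each confounder
    (keys ``specked``, ``understained``, ``multicell``), applied identically
    in both classes. Fully reproducible from ``seed``.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    rates = dict(DEFAULT_CONFOUNDER_RATES)
    if confounder_rates:
        unknown = set(confounder_rates) - set(rates)
        if unknown:
            raise ValueError(f"unknown confounder keys: {sorted(unknown)}")
        rates.update(confounder_rates)
    for k, v in rates.items():
        if not 0 <= v <= 1:
            raise ValueError(f"rate {k}={v} outside [0,1]")
    rng = np.random.default_rng(seed)
    images = []
    for positive, count, tag in [(True, n_pos, "pos"), (False, n_neg, "neg")]:
        for i in range(count):
            spec = _random_scene(
                rng, positive,
                specked=rng.random() < rates["specked"],
                understained=rng.random() < rates["understained"],
                multicell=rng.random() < rates["multicell"],
                image_size=image_size)
            img = render_scene(spec)
            img.id = f"{tag}{i:05d}"
            img.parent_id = img.id
            img.provenance = f"original; seed={spec.seed}"
            images.append(img)
    return images


def save_dataset(images: list[LabeledImage], out_dir) -> "pandas.DataFrame":
    """Write PNGs plus a manifest CSV (path, label, mask_path, provenance, seed)."""
    import pandas as pd
    from PIL import Image
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        path = out / f"{img.id}.png"
        Image.fromarray(img.pixels).save(path)
        mask_path = ""
        if img.mn_mask is not None and img.label == 1:
            mask_path = str(out / f"{img.id}_mask.png")
            Image.fromarray(img.mn_mask * 255).save(mask_path)
        seed = img.provenance.split("seed=")[-1] if "seed=" in img.provenance else ""
        rows.append({"path": str(path), "label": img.label,
                     "mask_path": mask_path, "provenance": img.provenance,
                     "seed": seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
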