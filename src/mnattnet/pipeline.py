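"""Dataset split, five-fold augmentation, and imbalance handling.

The sample pool is divided per class into train/validation/test at 6:2:2
with the rounding convention n_train = ceil(0.6 n), n_test = floor(0.2 n),
n_val = remainder — the unique simple convention that reproduces the
study-scale per-class counts (726 -> 436/145/145, 10419 -> 6252/2084/2083).

Augmentation is a five-fold cascade per image: the original, a random
rotation, that rotation flipped horizontally, flipped vertically, and
rescaled by a random factor. Class imbalance is handled by augmenting
positives and downsampling the negative TRAIN pool (default target: the
size of the augmented positive train pool); the test split is never
augmented. Two dataset variants are assembled:

* TAD  — augmentation on the training split only;
* TVAD — training and validation splits augmented (validation negatives
  are augmented without downsampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import LabeledImage

__all__ = ["SplitCounts", "DatasetManifest", "split_counts", "AUG_TAGS",
           "apply_augmentation", "augment_five_fold", "assemble_variant",
           "materialize"]

AUG_TAGS = ["original", "rotated", "rot+hflip", "rot+vflip", "rot+scaled"]


@dataclass
class SplitCounts:
    n_train: int
    n_val: int
    n_test: int

    @property
    def total(self) -> int:
        return self.n_train + self.n_val + self.n_test


def split_counts(n: int, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)) -> SplitCounts:
    """Per-class split sizes: train = ceil, test = floor, val = remainder."""
    if n < 0:
        raise ValueError(f"class total must be non-negative, got {n}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n_train = math.ceil(ratios[0] * n)
    n_test = math.floor(ratios[2] * n)
    n_val = n - n_train - n_test
    if n_val < 0:
        raise ValueError(f"ratios {ratios} leave a negative validation count for n={n}")
    return SplitCounts(n_train=n_train, n_val=n_val, n_test=n_test)


# ---------------------------------------------------------------------------
# pixel-level augmentation


def _to_square(arr: np.ndarray, size: int, order: int) -> np.ndarray:
    """Center-crop or reflect-pad a (possibly rescaled) array back to size."""
    h, w = arr.shape[:2]
    if h > size:
        top = (h - size) // 2
        arr = arr[top:top + size]
    if w > size:
        left = (w - size) // 2
        arr = arr[:, left:left + size]
    h, w = arr.shape[:2]
    if h < size or w < size:
        pt, pl = (size - h) // 2, (size - w) // 2
        pad = [(pt, size - h - pt), (pl, size - w - pl)] + \
              [(0, 0)] * (arr.ndim - 2)
        mode = "reflect" if order > 0 else "constant"
        arr = np.pad(arr, pad, mode=mode)
    return arr


def _transform(pixels: np.ndarray, tag: str, angle: float, scale: float,
               order: int) -> np.ndarray:
    from skimage import transform as sktf

    if tag == "original":
        return pixels.copy()
    is_mask = pixels.ndim == 2
    arr = pixels.astype(np.float64)
    rot = sktf.rotate(arr, angle, mode="constant" if is_mask else "reflect",
                      order=order, preserve_range=True)
    if tag == "rot+hflip":
        rot = rot[:, ::-1]
    elif tag == "rot+vflip":
        rot = rot[::-1]
    elif tag == "rot+scaled":
        kwargs = {} if is_mask else {"channel_axis": -1}
        rot = sktf.rescale(rot, scale, order=order, preserve_range=True,
                           mode="reflect", anti_aliasing=order > 0, **kwargs)
        rot = _to_square(rot, pixels.shape[0], order)
    return np.clip(np.rint(rot), 0, 255).astype(pixels.dtype)


def apply_augmentation(image: LabeledImage, tag: str, angle: float,
                       scale: float) -> LabeledImage:
    """Produce one augmented copy; the mask is transformed identically
    (nearest-neighbour, so it stays binary)."""
    if tag not in AUG_TAGS:
        raise ValueError(f"unknown augmentation tag {tag!r}")
    pixels = _transform(image.pixels, tag, angle, scale, order=3)
    mask = None
    if image.mn_mask is not None:
        mask = _transform(image.mn_mask, tag, angle, scale, order=0)
        if image.label == 1 and not mask.any():
            raise ValueError(
                f"augmentation {tag} (angle={angle:.1f}, scale={scale:.2f}) "
                f"pushed the micronucleus of {image.id!r} out of frame")
    return LabeledImage(pixels=pixels, label=image.label, mn_mask=mask,
                        provenance=tag, id=f"{image.id}:{tag}",
                        parent_id=image.id)


def _draw_params(rng: np.random.Generator, angle_range, scale_range):
    return (float(rng.uniform(*angle_range)), float(rng.uniform(*scale_range)))


def augment_five_fold(images: list[LabeledImage], seed: int = 0,
                      angle_range: tuple[float, float] = (-180.0, 180.0),
                      scale_range: tuple[float, float] = (0.85, 1.15)
                      ) -> list[LabeledImage]:
    """Five-fold cascade: original + rotated + rot+hflip + rot+vflip +
    rot+scaled, one rotation angle and one scale drawn per input image."""
    for img in images:
        if not img.provenance.startswith("original"):
            raise ValueError(
                f"refusing to re-augment {img.id!r} (provenance "
                f"{img.provenance!r}); augmentation must not compound")
    rng = np.random.default_rng(seed)
    out = []
    for img in images:
        angle, scale = _draw_params(rng, angle_range, scale_range)
        for tag in AUG_TAGS:
            if tag == "original":
                copy = LabeledImage(pixels=img.pixels, label=img.label,
                                    mn_mask=img.mn_mask, provenance="original",
                                    id=img.id, parent_id=img.id)
                out.append(copy)
            else:
                out.append(apply_augmentation(img, tag, angle, scale))
    return out


# ---------------------------------------------------------------------------
# manifest assembly


@dataclass
class DatasetManifest:
    """Split-assigned, augmentation-tagged records forming a TAD or TVAD set.

    ``records`` columns: id, parent_id, label, split, provenance, angle,
    scale. Augmented records carry the transform parameters so pixels can be
    materialized lazily and deterministically.
    """

    records: pd.DataFrame
    variant: str

    def validate(self) -> None:
        df = self.records
        if df["id"].duplicated().any():
            raise ValueError("duplicate record ids")
        split_of_parent = df[df["provenance"] == "original"].set_index("id")["split"]
        aug = df[df["provenance"] != "original"]
        # no leakage: every augmented record's parent is in the same split
        parent_split = split_of_parent.reindex(aug["parent_id"]).to_numpy()
        if (parent_split != aug["split"].to_numpy()).any():
            raise ValueError("augmented record in a different split than its parent")
        if (df[df["split"] == "test"]["provenance"] != "original").any():
            raise ValueError("test split must not contain augmented records")
        if self.variant == "TAD" and \
                (aug["split"] != "train").any():
            raise ValueError("TAD allows augmented records in train only")

    def counts_table(self) -> pd.DataFrame:
        """Per-split per-class counts in the layout of the study tables."""
        rows = []
        for split, name in [("train", "Training data"),
                            ("val", "Validation data"),
                            ("test", "Test data")]:
            sub = self.records[self.records["split"] == split]
            neg = int((sub["label"] == 0).sum())
            pos = int((sub["label"] == 1).sum())
            rows.append({"Dataset": name, "Images without micronuclei": neg,
                         "Images with micronuclei": pos, "Total": neg + pos})
        return pd.DataFrame(rows)

    def split_ids(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split].reset_index(drop=True)

    def to_csv(self, path) -> None:
        df = self.records.copy()
        df.insert(0, "variant", self.variant)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        variant = df["variant"].iloc[0]
        return cls(records=df.drop(columns=["variant"]), variant=variant)


def _augmented_rows(rows: list[dict], rng, angle_range, scale_range) -> list[dict]:
    out = []
    for row in rows:
        angle, scale = _draw_params(rng, angle_range, scale_range)
        for tag in AUG_TAGS:
            if tag == "original":
                out.append(row)
            else:
                out.append({**row, "id": f"{row['id']}:{tag}",
                            "provenance": tag, "angle": angle, "scale": scale})
    return out


def assemble_variant(pos_ids: list[str], neg_ids: list[str], variant: str,
                     ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     neg_train_target: int | None = None, seed: int = 0,
                     angle_range: tuple[float, float] = (-180.0, 180.0),
                     scale_range: tuple[float, float] = (0.85, 1.15)
                     ) -> DatasetManifest:
    """Assemble a TAD or TVAD manifest from per-class image id pools.

    Positives in train (both variants) and in val (TVAD) are five-fold
    augmented; the negative train pool is downsampled to
    ``neg_train_target`` (default: the augmented positive train pool size);
    TVAD validation negatives are augmented without downsampling; the test
    split is untouched in both variants.
    """
    if variant not in ("TAD", "TVAD"):
        raise ValueError(f"variant must be TAD or TVAD, got {variant!r}")
    rng = np.random.default_rng(seed)

    def split_pool(ids, label):
        ids = list(ids)
        perm = rng.permutation(len(ids))
        ids = [ids[i] for i in perm]
        sc = split_counts(len(ids), ratios)
        pools = {"train": ids[:sc.n_train],
                 "val": ids[sc.n_train:sc.n_train + sc.n_val],
                 "test": ids[sc.n_train + sc.n_val:]}
        return {split: [_row(i, label, split) for i in members]
                for split, members in pools.items()}

    def _row(id_, label, split):
        return {"id": id_, "parent_id": id_, "label": label, "split": split,
                "provenance": "original", "angle": 0.0, "scale": 1.0}

    pos = split_pool(pos_ids, 1)
    neg = split_pool(neg_ids, 0)

    pos_train = _augmented_rows(pos["train"], rng, angle_range, scale_range)
    if neg_train_target is None:
        # balance against the augmented positive pool, bounded by availability
        neg_train_target = min(len(pos_train), len(neg["train"]))
    if neg_train_target > len(neg["train"]):
        raise ValueError(
            f"neg_train_target={neg_train_target} exceeds the available "
            f"{len(neg['train'])} training negatives")
    keep = rng.choice(len(neg["train"]), size=neg_train_target, replace=False)
    neg_train = [neg["train"][i] for i in sorted(keep)]

    if variant == "TVAD":
        pos_val = _augmented_rows(pos["val"], rng, angle_range, scale_range)
        neg_val = _augmented_rows(neg["val"], rng, angle_range, scale_range)
    else:
        pos_val, neg_val = pos["val"], neg["val"]

    rows = (pos_train + neg_train + pos_val + neg_val
            + pos["test"] + neg["test"])
    df = pd.DataFrame(rows)
    tag_order = {t: i for i, t in enumerate(AUG_TAGS)}
    df = df.sort_values(
        by=["parent_id", "provenance"],
        key=lambda col: col.map(tag_order) if col.name == "provenance" else col
    ).reset_index(drop=True)
    manifest = DatasetManifest(records=df, variant=variant)
    manifest.validate()
    return manifest


def materialize(manifest: DatasetManifest, images: dict[str, LabeledImage],
                split: str) -> list[LabeledImage]:
    """Render the actual pixels for one split of a manifest."""
    out = []
    for row in manifest.split_ids(split).itertuples():
        parent = images[row.parent_id]
        if row.provenance == "original":
            out.append(parent)
        else:
            out.append(apply_augmentation(parent, row.provenance,
                                          row.angle, row.scale))
    return out
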