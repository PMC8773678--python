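"""Patch extraction, labeling, shift augmentation, balancing and splitting.

The CNN's classification unit is a 16x16 matrix of t-scores cut from an
axial slice.  Slices are tiled by a non-overlapping grid anchored at (0, 0);
a tile is adopted only if every pixel lies inside the t-map's validity mask
(inside the parenchyma and outside the ventricles).  Tiles are labeled
infarcted when their footprint overlaps the lesion ground-truth mask, and
the scarce infarcted class is augmented by re-cutting each adopted patch
shifted along the eight compass directions, keeping only shifts that neither
flip the label nor leave the parenchyma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .normative import TScoreMap
from .preprocess import ContractError
from .volume import BinaryMask

PATCH_SIZE = 16

Label = Literal["infarcted", "non_infarcted", "unlabeled"]

#: Compass direction -> (row step, col step); north decreases the row index.
DIRECTIONS: dict[str, tuple[int, int]] = {
    "N": (-1, 0), "NE": (-1, 1), "E": (0, 1), "SE": (1, 1),
    "S": (1, 0), "SW": (1, -1), "W": (0, -1), "NW": (-1, -1),
}


@dataclass(frozen=True)
class Patch:
    """A square tile of t-scores at (slice_index, row0, col0), 0-based."""

    values: np.ndarray
    slice_index: int
    row0: int
    col0: int
    label: Label = "unlabeled"
    provenance: str = "original"  # "original" or "augmented:<direction>"

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def key(self) -> tuple:
        """Deterministic sort key independent of construction order."""
        return (self.slice_index, self.row0, self.col0, self.provenance)


@dataclass
class PatchDataset:
    """A labeled patch collection with optional train/validation assignment."""

    patches: list[Patch]
    seed: int | None = None
    split_assignment: dict[int, str] | None = None  # index -> "train"/"validation"

    @property
    def class_counts(self) -> tuple[int, int]:
        """(infarcted, non_infarcted) counts."""
        inf = sum(1 for p in self.patches if p.label == "infarcted")
        non = sum(1 for p in self.patches if p.label == "non_infarcted")
        return inf, non

    def subset(self, split: str) -> list[Patch]:
        if self.split_assignment is None:
            raise ContractError("dataset has no split assignment")
        return [self.patches[i] for i, s in sorted(self.split_assignment.items())
                if s == split]

    def arrays(self, split: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (n, size, size) float32 values and 0/1 labels (1 = infarcted)."""
        patches = self.patches if split is None else self.subset(split)
        x = np.stack([p.values for p in patches]).astype(np.float32)
        y = np.array([1 if p.label == "infarcted" else 0 for p in patches],
                     dtype=np.int64)
        return x, y


def area_patch_estimate(slice_shape: tuple[int, int], patch_size: int = PATCH_SIZE) -> int:
    """Area-based per-slice patch count, floor(rows*cols / patch_size^2).

    This is the coarse estimate quoted for a 181x217 slice ("about 153");
    the exact number of complete disjoint tiles is smaller
    (floor(rows/16) * floor(cols/16) = 143).
    """
    rows, cols = slice_shape
    return (rows * cols) // (patch_size * patch_size)


def _patch_in_mask(mask2d: np.ndarray, row0: int, col0: int, size: int) -> bool:
    rows, cols = mask2d.shape
    if row0 < 0 or col0 < 0 or row0 + size > rows or col0 + size > cols:
        return False
    return bool(mask2d[row0:row0 + size, col0:col0 + size].all())


def tile_patches(tmap: TScoreMap, patch_size: int = PATCH_SIZE) -> list[Patch]:
    """Non-overlapping grid tiling of every axial slice, anchored at (0, 0).

    Only complete ``patch_size`` x ``patch_size`` tiles are produced, and a
    tile is adopted only if all of its pixels lie in the t-map mask.  A patch
    size larger than the slice yields an empty result.
    """
    if patch_size < 1:
        raise ContractError("patch_size must be >= 1")
    rows, cols, n_slices = tmap.t.shape
    patches: list[Patch] = []
    for k in range(n_slices):
        plane = tmap.t[:, :, k]
        mask = tmap.mask.data[:, :, k]
        if not mask.any():
            continue
        for r0 in range(0, rows - patch_size + 1, patch_size):
            for c0 in range(0, cols - patch_size + 1, patch_size):
                if mask[r0:r0 + patch_size, c0:c0 + patch_size].all():
                    patches.append(Patch(
                        values=plane[r0:r0 + patch_size, c0:c0 + patch_size].copy(),
                        slice_index=k, row0=r0, col0=c0))
    return patches


def lesion_overlap(patch: Patch, lesion_mask: BinaryMask) -> int:
    """Number of lesion pixels under the patch footprint on its slice."""
    s = patch.size
    plane = lesion_mask.data[:, :, patch.slice_index]
    return int(plane[patch.row0:patch.row0 + s, patch.col0:patch.col0 + s].sum())


def label_patch(patch: Patch, lesion_mask: BinaryMask,
                min_lesion_pixels: int = 1) -> Patch:
    """Label infarcted iff the footprint overlaps >= ``min_lesion_pixels`` lesion pixels."""
    overlap = lesion_overlap(patch, lesion_mask)
    label: Label = "infarcted" if overlap >= min_lesion_pixels else "non_infarcted"
    return replace(patch, label=label)


def augment_patch(patch: Patch, tmap: TScoreMap, lesion_mask: BinaryMask,
                  shift_pixels: int = 4, min_lesion_pixels: int = 1) -> list[Patch]:
    """Shift-based augmentation: up to 8 extra patches, one per compass direction.

    Each candidate is the patch displaced by ``shift_pixels`` along a compass
    direction (diagonals shift both axes).  A candidate is rejected if any of
    its pixels leaves the t-map mask (out of the parenchyma or into the
    ventricle, or off the slice), or if relabeling against the lesion mask
    would flip its class.  Rejections silently shrink the output.
    """
    if patch.label == "unlabeled":
        raise ContractError("augment_patch requires a labeled patch")
    s = patch.size
    k = patch.slice_index
    plane = tmap.t[:, :, k]
    mask = tmap.mask.data[:, :, k]
    out: list[Patch] = []
    for name, (dr, dc) in DIRECTIONS.items():
        r0 = patch.row0 + dr * shift_pixels
        c0 = patch.col0 + dc * shift_pixels
        if not _patch_in_mask(mask, r0, c0, s):
            continue
        candidate = Patch(values=plane[r0:r0 + s, c0:c0 + s].copy(),
                          slice_index=k, row0=r0, col0=c0,
                          provenance=f"augmented:{name}")
        candidate = label_patch(candidate, lesion_mask, min_lesion_pixels)
        if candidate.label != patch.label:
            continue
        out.append(candidate)
    return out


def balance_classes(patches: Iterable[Patch], seed: int,
                    majority_ratio: float = 1.1) -> PatchDataset:
    """Keep all minority-class patches; subsample the majority class (seeded).

    The majority class is cut down to ``round(majority_ratio * n_minority)``
    (round half up), or kept whole if already smaller.  The selection is
    reproducible under a fixed seed and invariant to the input order.
    """
    patches = sorted(patches, key=Patch.key)
    inf = [p for p in patches if p.label == "infarcted"]
    non = [p for p in patches if p.label == "non_infarcted"]
    if not inf or not non:
        raise ContractError("balance_classes requires both classes present")
    minority, majority = (inf, non) if len(inf) <= len(non) else (non, inf)
    n_keep = min(len(majority), int(math.floor(majority_ratio * len(minority) + 0.5)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(majority), size=n_keep, replace=False)
    kept = minority + [majority[i] for i in sorted(idx)]
    return PatchDataset(patches=sorted(kept, key=Patch.key), seed=seed)


def split_dataset(ds: PatchDataset, train_fraction: float = 0.8,
                  seed: int = 0) -> PatchDataset:
    """Seeded uniform random train/validation partition.

    Train size is ``train_fraction * total`` rounded half up; the remainder
    is validation.  Reproducible under a fixed seed and invariant to input
    order.
    """
    if not 0 < train_fraction < 1:
        raise ContractError("train_fraction must be in (0, 1)")
    if not ds.patches:
        raise ContractError("cannot split an empty dataset")
    patches = sorted(ds.patches, key=Patch.key)
    total = len(patches)
    n_train = int(math.floor(train_fraction * total + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(total)
    assignment = {int(i): ("train" if rank < n_train else "validation")
                  for rank, i in enumerate(perm)}
    return PatchDataset(patches=patches, seed=seed, split_assignment=assignment)


def resample_splits(ds: PatchDataset, k: int, train_fraction: float = 0.8,
                    seed: int = 0) -> list[PatchDataset]:
    """Repeat the random split ``k`` times with derived seeds (cross-validation)."""
    return [split_dataset(ds, train_fraction, seed=(seed * 1000 + rep) % (2 ** 31))
            for rep in range(k)]


def save_dataset(ds: PatchDataset, directory: str | Path) -> None:
    """Serialize as a CSV manifest plus an .npy stack of patch matrices."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(ds.patches):
        split = (ds.split_assignment or {}).get(i, "")
        rows.append({"patch_id": i, "slice": p.slice_index, "row0": p.row0,
                     "col0": p.col0, "label": p.label, "provenance": p.provenance,
                     "split": split})
    pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False)
    np.save(d / "values.npy", np.stack([p.values for p in ds.patches]).astype(np.float32))


def load_dataset(directory: str | Path) -> PatchDataset:
    d = Path(directory)
    manifest = pd.read_csv(d / "manifest.csv", keep_default_na=False)
    values = np.load(d / "values.npy")
    patches = [Patch(values=values[i], slice_index=int(r["slice"]),
                     row0=int(r["row0"]), col0=int(r["col0"]),
                     label=str(r["label"]), provenance=str(r["provenance"]))
               for i, r in manifest.iterrows()]
    split = {int(r["patch_id"]): str(r["split"])
             for _, r in manifest.iterrows() if str(r["split"])}
    return PatchDataset(patches=patches, split_assignment=split or None)
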