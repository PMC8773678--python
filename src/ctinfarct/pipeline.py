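"""End-to-end orchestration: preprocessing chains, patch dataset assembly,
per-patient detection, atlas lookup and report rendering.

The per-subject preprocessing chain is fixed: intensity transformation,
statistical skull/CSF elimination, mask-aware Gaussian smoothing (default
5-mm FWHM).  Controls then feed the normative model; a patient volume is
turned into a t-score map against that model, tiled into 16x16 patches, and
each adopted patch is classified independently by the trained CNN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import patches as pk
from .metrics import ConfusionMatrix, compute_metrics
from .nn import PatchCNN, predict_patches
from .normative import NormativeModel, TScoreMap, build_normative_maps, compute_tscore_map
from .preprocess import ContractError, eliminate_skull_csf, smooth_gaussian, transform_intensity
from .volume import BinaryMask, CTVolume


def preprocess_volume(vol: CTVolume, fwhm_mm: float = 5.0):
    """Transform -> skull/CSF elimination -> mask-aware smoothing.

    Returns the smoothed parenchyma-only volume (transformed units) and the
    :class:`~ctinfarct.preprocess.ParenchymaSegmentation`.
    """
    transformed = transform_intensity(vol)
    stripped, seg = eliminate_skull_csf(transformed)
    smoothed = smooth_gaussian(stripped, fwhm_mm=fwhm_mm, mask=seg.parenchyma_mask)
    return smoothed, seg


def build_model_from_controls(controls: list[CTVolume],
                              fwhm_mm: float = 5.0) -> NormativeModel:
    """Run the control preprocessing chain and fit the normative maps."""
    processed = [preprocess_volume(c, fwhm_mm)[0] for c in controls]
    return build_normative_maps(processed)


def patient_tscore_map(patient: CTVolume, model: NormativeModel,
                       fwhm_mm: float = 5.0) -> TScoreMap:
    """Patient chain: transform, eliminate, smooth, then the t-score map."""
    smoothed, seg = preprocess_volume(patient, fwhm_mm)
    return compute_tscore_map(smoothed, model, seg.parenchyma_mask)


def build_patch_dataset(tmaps: list[TScoreMap], lesion_masks: list[BinaryMask],
                        seed: int, shift_pixels: int = 4,
                        min_lesion_pixels: int = 1, augment: bool = True,
                        majority_ratio: float = 1.1,
                        train_fraction: float = 0.8) -> pk.PatchDataset:
    """Tile, label, augment, balance and split patches from patient t-maps."""
    collected: list[pk.Patch] = []
    for tmap, lesion in zip(tmaps, lesion_masks):
        tiles = [pk.label_patch(p, lesion, min_lesion_pixels)
                 for p in pk.tile_patches(tmap)]
        collected.extend(tiles)
        if augment:
            for p in tiles:
                collected.extend(pk.augment_patch(p, tmap, lesion, shift_pixels,
                                                  min_lesion_pixels))
    balanced = pk.balance_classes(collected, seed=seed, majority_ratio=majority_ratio)
    return pk.split_dataset(balanced, train_fraction=train_fraction, seed=seed)


@dataclass
class DetectionResult:
    """Detected infarcted patches for one patient."""

    patient_id: str
    detections: pd.DataFrame  # columns: slice, row0, col0, probability [, atlas]
    n_adopted: int

    @property
    def n_detected(self) -> int:
        return len(self.detections)

    def summary(self) -> dict:
        return {"patient_id": self.patient_id, "n_adopted_patches": self.n_adopted,
                "n_detected_patches": self.n_detected}


def detect_infarcts(patient: CTVolume, model: PatchCNN, normative: NormativeModel,
                    fwhm_mm: float = 5.0, patient_id: str = "patient",
                    atlas: "AtlasVolume | None" = None) -> DetectionResult:
    """Full patient pipeline: preprocess, t-map, tile, classify every tile.

    Returns the adopted tiles classified infarcted, with their infarct
    probabilities; deterministic for a fixed trained model and input.
    """
    if not model.trained:
        raise ContractError("detect_infarcts requires a trained model")
    tmap = patient_tscore_map(patient, normative, fwhm_mm)
    tiles = pk.tile_patches(tmap)
    rows = []
    if tiles:
        for patch, (label, prob) in zip(tiles, predict_patches(model, tiles)):
            if label == "infarcted":
                row = {"slice": patch.slice_index, "row0": patch.row0,
                       "col0": patch.col0, "probability": prob}
                if atlas is not None:
                    regions = map_patch_to_atlas(
                        (patch.slice_index, patch.row0, patch.col0), atlas,
                        patch_size=patch.size)
                    row["atlas"] = ";".join(name for name, _ in regions)
                rows.append(row)
    det = pd.DataFrame(rows, columns=["slice", "row0", "col0", "probability"]
                       + (["atlas"] if atlas is not None else []))
    return DetectionResult(patient_id=patient_id, detections=det, n_adopted=len(tiles))


@dataclass
class AtlasVolume:
    """An integer label volume plus a label->name table (0 = unlabeled)."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def name(self, label: int) -> str:
        return self.names.get(label, str(label))


def map_patch_to_atlas(coords: tuple[int, int, int], atlas: AtlasVolume,
                       patch_size: int = pk.PATCH_SIZE) -> list[tuple[str, int]]:
    """Region names under a patch footprint, by descending pixel count.

    ``coords`` is (slice_index, row0, col0) on the template grid — atlas
    lookup is pure coordinate indexing, no image processing.  Label 0 is
    background and never reported.
    """
    k, r0, c0 = coords
    if atlas.labels.ndim != 3:
        raise ContractError("atlas must be a 3-D label volume")
    plane = atlas.labels[:, :, k]
    foot = plane[r0:r0 + patch_size, c0:c0 + patch_size]
    if foot.shape != (patch_size, patch_size):
        raise ContractError("patch footprint leaves the atlas grid")
    labels, counts = np.unique(foot[foot != 0], return_counts=True)
    order = np.argsort(-counts, kind="stable")
    return [(atlas.name(int(labels[i])), int(counts[i])) for i in order]


def render_report(result: DetectionResult, background: CTVolume,
                  out_dir: str | Path, patch_size: int = pk.PATCH_SIZE) -> dict:
    """Write per-slice overlay PNGs plus CSV/JSON summaries.

    Each axial slice with at least one detection gets an image with red
    rectangles at the detected patches; a slice with none is skipped.
    Returns the summary dictionary (also written as JSON).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if background.shape[2] <= (result.detections["slice"].max() if result.n_detected else 0):
        raise ContractError("background volume does not cover the detected slices")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.detections.to_csv(out / "detections.csv", index=False)
    summary = result.summary()
    summary["slices_with_detections"] = (
        sorted(int(s) for s in result.detections["slice"].unique())
        if result.n_detected else [])
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    for k in summary["slices_with_detections"]:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(background.axial_slice(k), cmap="gray", origin="lower")
        for _, row in result.detections[result.detections["slice"] == k].iterrows():
            # imshow puts array columns on x and rows on y
            ax.add_patch(Rectangle((row["col0"] - 0.5, row["row0"] - 0.5),
                                   patch_size, patch_size,
                                   fill=False, edgecolor="red", linewidth=1.2))
        ax.set_title(f"{result.patient_id} slice {k}")
        ax.axis("off")
        fig.savefig(out / f"slice_{int(k):03d}.png", dpi=100, bbox_inches="tight")
        plt.close(fig)
    return summary


def evaluate_detection(result: DetectionResult, tmap: TScoreMap,
                       lesion_mask: BinaryMask,
                       min_lesion_pixels: int = 1) -> dict:
    """Patch-level confusion of a detection run against the ground truth.

    Adopted tiles overlapping the lesion mask are positives; the returned
    dict carries the confusion counts and percent metrics.
    """
    tiles = pk.tile_patches(tmap)
    detected = {(int(r["slice"]), int(r["row0"]), int(r["col0"]))
                for _, r in result.detections.iterrows()}
    y_true, y_pred = [], []
    for patch in tiles:
        labeled = pk.label_patch(patch, lesion_mask, min_lesion_pixels)
        y_true.append(1 if labeled.label == "infarcted" else 0)
        y_pred.append(1 if (patch.slice_index, patch.row0, patch.col0) in detected else 0)
    cm = ConfusionMatrix.from_predictions(y_true, y_pred)
    out = {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn}
    out.update(compute_metrics(cm, ndigits=None))
    return out
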