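"""Control-cohort template and single-case normative t-score maps.

A lesion-free control cohort, preprocessed onto a common grid, is summarised
voxel-wise by a mean map and a sample-SD map.  A patient volume on the same
grid is then compared voxel-by-voxel with the modified single-case t
statistic of Crawford and Howell::

    t = (p - mean_C) / (sqrt((n + 1) / n) * sd_C)

where ``p`` is the patient value, ``mean_C`` and ``sd_C`` the control mean
and sample SD at that voxel and ``n`` the control count; the
``sqrt((n+1)/n)`` factor accounts for the uncertainty of the control mean
and SD estimated from a finite cohort.  Hypodense infarcts produce strongly
negative t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import ContractError
from .volume import BinaryMask, CTVolume, read_volume, write_volume

#: SD guard: voxels whose control SD is below this are excluded from t-maps.
SD_EPSILON = 1e-6


@dataclass
class NormativeModel:
    """Voxel-wise control statistics: mean map, sample-SD map, cohort size.

    ``valid_mask`` marks voxels with at least two nonzero (parenchymal)
    control contributions; t-scores are only meaningful there.
    """

    mean_map: np.ndarray
    sd_map: np.ndarray
    n: int
    valid_mask: BinaryMask
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ContractError("a normative model needs at least 2 controls")
        if self.mean_map.shape != self.sd_map.shape:
            raise ContractError("mean and SD maps must share the template shape")
        if np.any(self.sd_map < 0):
            raise ContractError("SD map must be nonnegative")


@dataclass
class TScoreMap:
    """A voxel-wise t grid plus the mask on which it is valid.

    ``t`` is finite on the mask and exactly 0 off it; ``n_used`` is the
    control count behind the statistic.
    """

    t: np.ndarray
    mask: BinaryMask
    n_used: int
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def as_volume(self) -> CTVolume:
        return CTVolume(data=self.t, voxel_size_mm=self.voxel_size_mm,
                        space="template", unit="tscore")


def _stack(controls: list[CTVolume]) -> np.ndarray:
    if not controls:
        raise ContractError("need at least one control volume")
    shape = controls[0].shape
    for c in controls:
        if c.shape != shape:
            raise ContractError(f"control shape {c.shape} does not match {shape}")
    return np.stack([np.asarray(c.data, dtype=np.float64) for c in controls], axis=0)


def build_template(controls: list[CTVolume]) -> CTVolume:
    """Voxel-wise arithmetic mean of the control volumes (the cohort CT template)."""
    stack = _stack(controls)
    return controls[0].with_data(stack.mean(axis=0))


def build_normative_maps(controls: list[CTVolume]) -> NormativeModel:
    """Voxel-wise mean and sample SD (n-1 denominator) across >=2 controls."""
    if len(controls) < 2:
        raise ContractError("need at least 2 controls for a normative model")
    stack = _stack(controls)
    mean_map = stack.mean(axis=0)
    sd_map = stack.std(axis=0, ddof=1)
    contributing = (stack != 0).sum(axis=0)
    valid = BinaryMask(contributing >= 2, role="parenchyma")
    return NormativeModel(mean_map=mean_map, sd_map=sd_map, n=len(controls),
                          valid_mask=valid, voxel_size_mm=controls[0].voxel_size_mm)


def compute_tscore_map(patient: CTVolume, model: NormativeModel,
                       parenchyma: BinaryMask,
                       sd_epsilon: float = SD_EPSILON) -> TScoreMap:
    """Crawford-Howell single-case t at every parenchymal voxel.

    The output mask is ``parenchyma & model.valid_mask & (sd >= sd_epsilon)``;
    t is set to 0 off the mask.  Zero-variance voxels are excluded rather
    than mapped to infinity.
    """
    data = np.asarray(patient.data, dtype=np.float64)
    if data.shape != model.mean_map.shape:
        raise ContractError(
            f"patient shape {data.shape} does not match model {model.mean_map.shape}")
    if parenchyma.shape != data.shape:
        raise ContractError("parenchyma mask shape does not match patient")
    correction = np.sqrt((model.n + 1.0) / model.n)
    mask = parenchyma.data & model.valid_mask.data & (model.sd_map >= sd_epsilon)
    t = np.zeros_like(data)
    t[mask] = (data[mask] - model.mean_map[mask]) / (correction * model.sd_map[mask])
    return TScoreMap(t=t, mask=BinaryMask(mask, role="parenchyma"), n_used=model.n,
                     voxel_size_mm=patient.voxel_size_mm)


def save_model(model: NormativeModel, directory: str | Path) -> None:
    """Serialize as mean/SD/valid NIfTI volumes plus a JSON sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    vs = model.voxel_size_mm
    write_volume(CTVolume(model.mean_map, vs, "template", "transformed"),
                 d / "mean.nii.gz")
    write_volume(CTVolume(model.sd_map, vs, "template", "transformed"),
                 d / "sd.nii.gz")
    write_volume(CTVolume(model.valid_mask.data.astype(np.uint8), vs,
                          "template", "transformed"), d / "valid.nii.gz")
    (d / "model.json").write_text(json.dumps(
        {"n": model.n, "sd_epsilon": SD_EPSILON, "voxel_size_mm": list(vs)}))


def load_model(directory: str | Path) -> NormativeModel:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    mean = read_volume(d / "mean.nii.gz", unit="transformed")
    sd = read_volume(d / "sd.nii.gz", unit="transformed")
    valid = read_volume(d / "valid.nii.gz", unit="transformed")
    return NormativeModel(mean_map=np.asarray(mean.data, np.float64),
                          sd_map=np.asarray(sd.data, np.float64),
                          n=int(meta["n"]),
                          valid_mask=BinaryMask(np.asarray(valid.data) > 0.5),
                          voxel_size_mm=tuple(meta["voxel_size_mm"]))
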