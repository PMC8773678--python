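"""Seeded digital head phantoms: control cohorts and lesioned patients.

Since no imaging data accompany the detection method, phantoms stand in for
the clinical cohorts.  Each phantom is built directly on the template grid
(no registration step is needed) from nested ellipsoids: an outer skull
shell around a brain ellipsoid, a gray-matter shell over an inner
white-matter ellipsoid, and two lateral-ventricle ellipsoids.  Tissue means
use the standard CT attenuation values — CSF 0 HU, white matter 25 HU, gray
matter 35 HU — with bone at 1000 HU and air background at -1000 HU.
Per-subject tissue-mean jitter models biological variation between
subjects; additive Gaussian voxel noise models scanner noise.

Patients additionally carry hypodense lesions (unions of overlapping
spheres fully inside the parenchyma) with a sampled HU decrement, plus the
matching ground-truth mask that stands in for an expert's MRI-derived
delineation.

The default grid is 91 x 109 x 91 at 2-mm spacing (half the linear
resolution of the full 181 x 217 x 181 1-mm template) so that full-cohort
runs stay cheap; the full grid is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import ContractError
from .volume import BinaryMask, CTVolume, write_mask, write_volume


class GenerationError(RuntimeError):
    """Raised when a phantom cannot satisfy its geometric constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue statistics and seeding of a phantom cohort."""

    shape: tuple[int, int, int] = (91, 109, 91)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # tissue mean HU (ordering background < CSF < WM < GM < skull required)
    hu_background: float = -1000.0
    hu_skull: float = 1000.0
    hu_csf: float = 0.0
    hu_white_matter: float = 25.0
    hu_gray_matter: float = 35.0
    noise_sd_hu: float = 3.0
    subject_jitter_sd_hu: float = 1.0
    # geometry as fractions of the half-extent of each axis
    brain_axes_frac: tuple[float, float, float] = (0.80, 0.85, 0.80)
    skull_thickness_frac: float = 0.04
    wm_axes_frac: tuple[float, float, float] = (0.60, 0.68, 0.60)
    ventricle_axes_frac: tuple[float, float, float] = (0.10, 0.28, 0.12)
    ventricle_offset_frac: float = 0.16  # lateral offset of each ventricle
    seed: int = 0

    def __post_init__(self) -> None:
        order = (self.hu_background, self.hu_csf, self.hu_white_matter,
                 self.hu_gray_matter, self.hu_skull)
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ContractError("tissue means must satisfy background < CSF < WM < GM < skull")
        if self.noise_sd_hu < 0:
            raise ContractError("noise sd must be nonnegative")


@dataclass(frozen=True)
class LesionSpec:
    """Planted hypodense lesions: unions of overlapping spheres."""

    count: int = 3
    radius_range_mm: tuple[float, float] = (6.0, 12.0)
    decrement_range_hu: tuple[float, float] = (8.0, 20.0)
    spheres_per_lesion: int = 3
    sphere_scatter_mm: float = 4.0  # spread of secondary sphere centres
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decrement_range_hu[0] <= 0:
            raise ContractError("infarcts are hypodense: decrement must be > 0")
        if self.radius_range_mm[0] <= 0:
            raise ContractError("lesion radii must be positive")


@dataclass
class _Geometry:
    brain: np.ndarray
    skull: np.ndarray
    wm: np.ndarray
    gm: np.ndarray
    ventricles: np.ndarray
    parenchyma: np.ndarray  # wm | gm


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def build_geometry(spec: PhantomSpec) -> _Geometry:
    """Deterministic tissue-region masks for a phantom specification."""
    shape = spec.shape
    center = tuple((s - 1) / 2.0 for s in shape)
    half = tuple(s / 2.0 for s in shape)
    brain_axes = tuple(h * f for h, f in zip(half, spec.brain_axes_frac))
    outer_axes = tuple(a * (1.0 + spec.skull_thickness_frac) for a in brain_axes)
    wm_axes = tuple(h * f for h, f in zip(half, spec.wm_axes_frac))
    vent_axes = tuple(h * f for h, f in zip(half, spec.ventricle_axes_frac))

    brain = _ellipsoid(shape, center, brain_axes)
    outer = _ellipsoid(shape, center, outer_axes)
    skull = outer & ~brain
    wm = _ellipsoid(shape, center, wm_axes)
    off = spec.ventricle_offset_frac * half[0]
    v_left = _ellipsoid(shape, (center[0] - off, center[1], center[2]), vent_axes)
    v_right = _ellipsoid(shape, (center[0] + off, center[1], center[2]), vent_axes)
    ventricles = v_left | v_right
    if ventricles.any() and not (ventricles <= brain).all():
        raise ContractError("degenerate geometry: ventricles extend outside the brain")
    wm = wm & ~ventricles
    gm = brain & ~wm & ~ventricles
    return _Geometry(brain=brain, skull=skull, wm=wm, gm=gm,
                     ventricles=ventricles, parenchyma=wm | gm)


def _subject_rng(spec_seed: int, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, subject_seed]))


def _render(spec: PhantomSpec, geom: _Geometry, rng: np.random.Generator) -> np.ndarray:
    jitter = {name: rng.normal(0.0, spec.subject_jitter_sd_hu)
              for name in ("csf", "wm", "gm", "skull")}
    hu = np.full(spec.shape, spec.hu_background)
    hu[geom.skull] = spec.hu_skull + jitter["skull"]
    hu[geom.gm] = spec.hu_gray_matter + jitter["gm"]
    hu[geom.wm] = spec.hu_white_matter + jitter["wm"]
    hu[geom.ventricles] = spec.hu_csf + jitter["csf"]
    # noise is confined to the head: the exterior emulates the zero-filled
    # out-of-field background of a template-space volume, which maps to
    # exactly 0 under the intensity transformation and is excluded from the
    # whole-brain statistics of the skull/CSF elimination step
    if spec.noise_sd_hu > 0:
        head = geom.skull | geom.brain
        hu[head] += rng.normal(0.0, spec.noise_sd_hu, size=int(head.sum()))
    return hu


def generate_control(spec: PhantomSpec, subject_seed: int) -> CTVolume:
    """A lesion-free head phantom, deterministic in (spec.seed, subject_seed)."""
    geom = build_geometry(spec)
    rng = _subject_rng(spec.seed, subject_seed)
    hu = _render(spec, geom, rng)
    return CTVolume(data=hu, voxel_size_mm=spec.voxel_size_mm,
                    space="template", unit="HU")


def _plant_lesions(spec: PhantomSpec, geom: _Geometry, lesions: LesionSpec,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Lesion mask and per-voxel HU decrement field."""
    shape = spec.shape
    vox = spec.voxel_size_mm
    # distance (mm) from each parenchyma voxel to the nearest non-parenchyma
    # voxel: a sphere of radius r fits iff distance > r
    dist = ndimage.distance_transform_edt(geom.parenchyma, sampling=vox)
    mask = np.zeros(shape, bool)
    decrement_field = np.zeros(shape)
    grids = np.indices(shape).astype(float)
    for _ in range(lesions.count):
        radius = rng.uniform(*lesions.radius_range_mm)
        decrement = rng.uniform(*lesions.decrement_range_hu)
        candidates = np.argwhere(dist > radius + max(vox))
        if len(candidates) == 0:
            raise GenerationError(
                f"no parenchyma room for a lesion of radius {radius:.1f} mm")
        center = candidates[rng.integers(len(candidates))]
        lesion = np.zeros(shape, bool)
        centers = [center.astype(float)]
        for _ in range(lesions.spheres_per_lesion - 1):
            offset = rng.normal(0.0, lesions.sphere_scatter_mm, size=3) / np.asarray(vox)
            centers.append(center + offset)
        for c in centers:
            d2 = sum(((grids[a] - c[a]) * vox[a]) ** 2 for a in range(3))
            lesion |= d2 <= radius ** 2
        lesion &= geom.parenchyma  # satellite spheres may graze the boundary
        mask |= lesion
        decrement_field[lesion] = decrement
    if not mask.any():
        raise GenerationError("planted lesion mask is empty")
    return mask, decrement_field


def generate_patient(spec: PhantomSpec, lesions: LesionSpec,
                     subject_seed: int) -> tuple[CTVolume, BinaryMask]:
    """A phantom with planted hypodense lesions plus its ground-truth mask.

    With ``lesions.count == 0`` the output equals :func:`generate_control`
    for the same seeds and the mask is empty.
    """
    geom = build_geometry(spec)
    rng = _subject_rng(spec.seed, subject_seed)
    hu = _render(spec, geom, rng)
    if lesions.count == 0:
        vol = CTVolume(data=hu, voxel_size_mm=spec.voxel_size_mm,
                       space="template", unit="HU")
        return vol, BinaryMask(np.zeros(spec.shape, bool), role="lesion")
    lesion_rng = _subject_rng(lesions.seed, subject_seed)
    mask, decrement = _plant_lesions(spec, geom, lesions, lesion_rng)
    hu = hu - decrement
    vol = CTVolume(data=hu, voxel_size_mm=spec.voxel_size_mm,
                   space="template", unit="HU")
    return vol, BinaryMask(mask, role="lesion")


@dataclass(frozen=True)
class SulcusSpec:
    """A fluid-filled groove at the brain surface (aging artifact).

    Reproduces the known false-positive mechanism: a CSF-density sulcus in
    an elderly patient, absent from the controls, gets large-|t| scores.
    An empty spec (``size_mm`` all zero) is the identity.
    """

    center_voxel: tuple[int, int, int] = (0, 0, 0)
    size_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hu: float = 0.0  # CSF density
    noise_sd_hu: float = 3.0
    seed: int = 12345


def sulcus_mask(vol_shape, spec: SulcusSpec,
                voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    half = [max(int(round(s / (2 * v))), 0) for s, v in zip(spec.size_mm, voxel_size_mm)]
    if all(h == 0 for h in half) and all(s == 0 for s in spec.size_mm):
        return np.zeros(vol_shape, bool)
    mask = np.zeros(vol_shape, bool)
    sl = tuple(slice(max(c - h, 0), min(c + h + 1, n))
               for c, h, n in zip(spec.center_voxel, half, vol_shape))
    mask[sl] = True
    return mask


def add_sulcus_artifact(vol: CTVolume, spec: SulcusSpec,
                        phantom: PhantomSpec | None = None) -> CTVolume:
    """Carve a CSF-filled groove into a phantom's brain surface region.

    Groove voxels are set to CSF-like HU plus noise.  The groove must
    intersect the brain (soft-tissue) region; an empty spec is the identity.
    """
    groove = sulcus_mask(vol.shape, spec, vol.voxel_size_mm)
    if not groove.any():
        return vol.with_data(np.array(vol.data, copy=True))
    pspec = phantom or PhantomSpec(shape=vol.shape, voxel_size_mm=vol.voxel_size_mm)
    geom = build_geometry(pspec)
    groove &= geom.brain
    if not groove.any():
        raise ContractError("sulcus groove does not intersect the brain")
    rng = np.random.default_rng(spec.seed)
    data = np.array(vol.data, dtype=np.float64, copy=True)
    data[groove] = spec.hu + rng.normal(0.0, spec.noise_sd_hu, size=int(groove.sum()))
    return vol.with_data(data)


def generate_cohort(out_dir: str | Path, n_controls: int = 38, n_patients: int = 21,
                    spec: PhantomSpec | None = None,
                    lesions: LesionSpec | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Write a full phantom cohort (NIfTI volumes, lesion masks, manifest CSV).

    Default cohort sizes mirror the study design: 38 lesion-free controls
    and 21 lesioned patients.  Fully reproducible from ``seed``.
    """
    if n_controls < 2:
        raise ContractError("a cohort needs at least 2 controls")
    spec = replace(spec or PhantomSpec(), seed=seed)
    lesions = replace(lesions or LesionSpec(), seed=seed + 1)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_controls):
        subject_seed = 1000 + i
        vol = generate_control(spec, subject_seed)
        path = out / f"control_{i:03d}.nii.gz"
        write_volume(vol, path)
        rows.append({"subject_id": f"control_{i:03d}", "role": "control",
                     "seed": subject_seed, "volume": path.name, "lesion_mask": "",
                     "lesion_voxels": 0})
    for i in range(n_patients):
        subject_seed = 2000 + i
        vol, mask = generate_patient(spec, lesions, subject_seed)
        vpath = out / f"patient_{i:03d}.nii.gz"
        mpath = out / f"patient_{i:03d}_lesion.nii.gz"
        write_volume(vol, vpath)
        write_mask(mask, mpath, voxel_size_mm=spec.voxel_size_mm)
        rows.append({"subject_id": f"patient_{i:03d}", "role": "patient",
                     "seed": subject_seed, "volume": vpath.name,
                     "lesion_mask": mpath.name, "lesion_voxels": mask.count()})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
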