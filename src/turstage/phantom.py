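"""Synthetic multi-sequence pelvic phantom.

Generates 2-D grayscale slices that mimic the geometry relevant to
area-ratio staging of early endometrial cancer: one uterus region per
slice, one irregular tumor blob strictly inside it, sequence-dependent
tissue contrast, additive Gaussian noise, and (optionally) a bright
distractor blob outside the uterus emulating pelvic effusion — the
classic false-positive for tumor segmentation.

The stage-conditional tumor-to-uterus area ratio (TUR) of each slice is
drawn from a truncated normal whose mean and SD default to the per-stage,
per-sequence moments reported for clinical test cohorts (e.g. sagittal
T2WI: stage IA 0.103 +/- 0.077, stage IB 0.334 +/- 0.125).  The phantom
therefore reproduces the *separability* of the two stages without any
clinical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, EmptySegmentationError, GenerationError

SEQUENCES = ("axial_t2w", "axial_dwi", "sagittal_t2w")
STAGES = ("IA", "IB")

#: Stage-conditional TUR moments (ia_mean, ia_sd, ib_mean, ib_sd) per sequence,
#: matching the clinical test-set distributions the phantom emulates.
DEFAULT_TUR_MOMENTS: dict[str, tuple[float, float, float, float]] = {
    "axial_t2w": (0.165, 0.083, 0.307, 0.112),
    "axial_dwi": (0.190, 0.077, 0.335, 0.117),
    "sagittal_t2w": (0.103, 0.077, 0.334, 0.125),
}

#: Mean intensity (background, uterus, tumor) per sequence, 8-bit scale.
#: Free modelling choice: tumor is brightest on DWI (b=800 diffusion
#: restriction), moderately bright on T2WI; uterus sits between background
#: and tumor on every sequence.
SEQUENCE_CONTRAST: dict[str, tuple[float, float, float]] = {
    "axial_t2w": (60.0, 115.0, 175.0),
    "axial_dwi": (40.0, 95.0, 220.0),
    "sagittal_t2w": (70.0, 120.0, 180.0),
}

#: TUR draws are rejection-truncated to this open interval so every draw
#: is renderable as a pixel mask.
TUR_BOUNDS = (0.02, 0.95)

BACKGROUND, UTERUS, TUMOR = 0, 1, 2


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for one MRI sequence kind.

    TUR means/SDs are unitless ratios; ``noise_sd`` is in 8-bit intensity
    units; ``distractor_prob`` is the per-slice probability of a bright
    pelvic-effusion-like blob outside the uterus.
    """

    tur_ia_mean: float
    tur_ia_sd: float
    tur_ib_mean: float
    tur_ib_sd: float
    image_size: int = 128
    noise_sd: float = 6.0
    distractor_prob: float = 0.0

    def __post_init__(self):
        for name in ("tur_ia_mean", "tur_ib_mean"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("tur_ia_sd", "tur_ib_sd"):
            if getattr(self, name) < 0.0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.image_size < 32:
            raise ConfigurationError(f"image_size must be >= 32, got {self.image_size}")
        if not 0.0 <= self.distractor_prob <= 1.0:
            raise ConfigurationError(
                f"distractor_prob must lie in [0, 1], got {self.distractor_prob}"
            )
        if self.noise_sd < 0.0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def moments(self, stage: str) -> tuple[float, float]:
        if stage == "IA":
            return self.tur_ia_mean, self.tur_ia_sd
        if stage == "IB":
            return self.tur_ib_mean, self.tur_ib_sd
        raise ConfigurationError(f"stage must be IA or IB, got {stage!r}")


def default_params(
    image_size: int = 128, noise_sd: float = 6.0, distractor_prob: float = 0.0
) -> dict[str, PhantomParams]:
    """Per-sequence parameter set with the default stage-conditional TUR moments."""
    return {
        seq: PhantomParams(*DEFAULT_TUR_MOMENTS[seq], image_size, noise_sd, distractor_prob)
        for seq in SEQUENCES
    }


def distractor_preset(image_size: int = 128) -> dict[str, PhantomParams]:
    """Preset with pelvic-effusion-like distractor blobs enabled on every slice."""
    return default_params(image_size=image_size, distractor_prob=1.0)


@dataclass(frozen=True)
class GrayscaleImage:
    """One 2-D slice of non-negative intensities plus minimal metadata."""

    pixels: np.ndarray
    sequence: str
    pixel_spacing_mm: float = 1.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.pixels)):
            raise ConfigurationError("pixels must be finite")


@dataclass(frozen=True)
class SliceSample:
    image: GrayscaleImage
    mask: np.ndarray
    intended_tur: float


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic patient: a stage label and one slice per sequence kind."""

    patient_id: str
    stage: str
    slices: Mapping[str, SliceSample] = field(repr=False)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, max_tries: int = 10_000) -> float:
    """Rejection-sample Normal(mean, sd) until the draw falls inside (lo, hi)."""
    if sd == 0.0:
        if not lo < mean < hi:
            raise GenerationError(f"degenerate TUR mean {mean} outside ({lo}, {hi})")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise GenerationError(
        f"could not draw a TUR inside ({lo}, {hi}) from Normal({mean}, {sd})"
    )


def _random_uterus(rng: np.random.Generator, size: int) -> np.ndarray:
    """Random filled ellipse covering 5-50% of the image, fully inside it."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    for _ in range(50):
        frac = rng.uniform(0.08, 0.30)
        area = frac * size * size
        q = rng.uniform(0.55, 0.95)          # axis ratio b/a
        a = math.sqrt(area / (math.pi * q))
        b = q * a
        theta = rng.uniform(0.0, math.pi)
        margin = max(a, b) + 2.0
        if 2 * margin >= size:
            continue
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        npix = int(mask.sum())
        if 0.05 * size * size <= npix <= 0.50 * size * size:
            return mask
    raise GenerationError("could not place a uterus ellipse of valid area")


_CROSS = ndimage.generate_binary_structure(2, 1)


def _grow_tumor(rng: np.random.Generator, uterus: np.ndarray, target: int) -> np.ndarray:
    """Grow an irregular connected blob inside ``uterus`` to exactly ``target`` pixels.

    Seeded at a deep interior point and expanded by randomized dilation; the
    irregular outlines emulate the variable tumor shapes that make tumors
    harder to segment than the organ itself.
    """
    dist = ndimage.distance_transform_edt(uterus)
    deep = np.argwhere(dist >= 0.6 * dist.max())
    sy, sx = deep[rng.integers(len(deep))]
    tumor = np.zeros_like(uterus)
    tumor[sy, sx] = True
    count = 1
    while count < target:
        frontier = ndimage.binary_dilation(tumor, _CROSS) & uterus & ~tumor
        cand = np.argwhere(frontier)
        if len(cand) == 0:
            raise GenerationError("tumor growth exhausted the uterus before reaching target")
        keep = rng.random(len(cand)) < 0.7
        if not keep.any():
            keep[rng.integers(len(cand))] = True
        chosen = cand[keep]
        room = target - count
        if len(chosen) > room:
            chosen = chosen[rng.permutation(len(chosen))[:room]]
        tumor[chosen[:, 0], chosen[:, 1]] = True
        count += len(chosen)
    return tumor


def _place_distractor(rng: np.random.Generator, uterus: np.ndarray) -> np.ndarray | None:
    """A disk outside the uterus (never touching it); None if no room."""
    size = uterus.shape[0]
    dist_out = ndimage.distance_transform_edt(~uterus)
    for _ in range(20):
        r = rng.uniform(2.0, size / 16.0)
        ok = dist_out > r + 2.0
        ok[: int(r) + 1, :] = ok[-(int(r) + 1):, :] = False
        ok[:, : int(r) + 1] = ok[:, -(int(r) + 1):] = False
        cand = np.argwhere(ok)
        if len(cand):
            cy, cx = cand[rng.integers(len(cand))]
            yy, xx = np.ogrid[0:size, 0:size]
            return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return None


def render_slice(
    stage: str,
    sequence: str,
    intended_tur: float,
    params: PhantomParams,
    rng: np.random.Generator,
) -> tuple[GrayscaleImage, np.ndarray]:
    """Render one slice: returns (image, label mask with 0=bg, 1=uterus, 2=tumor).

    The realized mask TUR — tumor / (tumor + uterus) pixels — is within
    1/(organ area) of ``intended_tur``, far inside the +/-0.01 contract.
    """
    if not 0.0 < intended_tur < 1.0:
        raise ConfigurationError(f"intended_tur must lie in (0, 1), got {intended_tur}")
    if sequence not in SEQUENCE_CONTRAST:
        raise ConfigurationError(f"unknown sequence {sequence!r}")
    size = params.image_size
    last_err: GenerationError | None = None
    for _ in range(10):
        try:
            uterus = _random_uterus(rng, size)
            organ_area = int(uterus.sum())
            target = max(1, round(intended_tur * organ_area))
            if target >= organ_area:
                raise GenerationError("tumor target not smaller than the organ")
            tumor = _grow_tumor(rng, uterus, target)
            break
        except GenerationError as err:  # retry with fresh geometry
            last_err = err
    else:
        raise GenerationError(f"slice generation failed after retries: {last_err}")

    mask = np.zeros((size, size), dtype=np.uint8)
    mask[uterus] = UTERUS
    mask[tumor] = TUMOR

    bg, ut, tm = SEQUENCE_CONTRAST[sequence]
    image = np.full((size, size), bg, dtype=np.float64)
    image[uterus] = ut
    image[tumor] = tm
    if params.distractor_prob > 0.0 and rng.random() < params.distractor_prob:
        blob = _place_distractor(rng, uterus)
        if blob is not None:
            image[blob] = tm  # tumor-like brightness, but labelled background
    if params.noise_sd > 0.0:
        image = image + rng.normal(0.0, params.noise_sd, image.shape)
    image = np.clip(image, 0.0, 255.0)
    return GrayscaleImage(image, sequence), mask


def realized_tur(mask: np.ndarray) -> float:
    """Mask TUR: tumor pixels / (tumor + uterus) pixels."""
    t = int((mask == TUMOR).sum())
    u = int((mask == UTERUS).sum())
    if t + u == 0:
        raise EmptySegmentationError("mask contains no uterus or tumor pixels")
    return t / (t + u)


def sample_cohort(
    n_ia: int,
    n_ib: int,
    params: Mapping[str, PhantomParams] | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Draw a synthetic cohort of ``n_ia`` stage-IA and ``n_ib`` stage-IB patients.

    Each patient receives one slice per sequence; the slice's intended TUR is
    drawn from that sequence's stage-conditional truncated normal.  Fully
    deterministic given ``seed``.
    """
    if n_ia < 0 or n_ib < 0:
        raise ConfigurationError(f"cohort sizes must be >= 0, got n_ia={n_ia}, n_ib={n_ib}")
    if params is None:
        params = default_params()
    missing = [s for s in SEQUENCES if s not in params]
    if missing:
        raise ConfigurationError(f"params missing sequences: {missing}")
    rng = np.random.default_rng(seed)
    lo, hi = TUR_BOUNDS
    cases: list[PhantomCase] = []
    stages = ["IA"] * n_ia + ["IB"] * n_ib
    for idx, stage in enumerate(stages):
        pid = f"P{idx:04d}"
        slices: dict[str, SliceSample] = {}
        for seq in SEQUENCES:
            p = params[seq]
            mean, sd = p.moments(stage)
            tur = _truncated_normal(rng, mean, sd, lo, hi)
            image, mask = render_slice(stage, seq, tur, p, rng)
            slices[seq] = SliceSample(image, mask, tur)
        cases.append(PhantomCase(pid, stage, slices))
    return cases


# ---------------------------------------------------------------------------
# File I/O


def write_image(path: Path, pixels: np.ndarray) -> None:
    iio.imwrite(path, np.clip(np.round(pixels), 0, 255).astype(np.uint8))


def write_mask(path: Path, mask: np.ndarray) -> None:
    iio.imwrite(path, mask.astype(np.uint8))


def read_image(path: Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.float64)


def read_mask(path: Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.uint8)


def write_cohort(cases: list[PhantomCase], directory: Path, nifti: bool = False) -> Path:
    """Write a cohort to ``directory``; returns the manifest CSV path.

    Images and masks are 8-bit PNGs (mask codes 0/1/2); one manifest row per
    slice.  With ``nifti=True`` each image is additionally written as a
    single-slice .nii.gz volume.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        for seq in SEQUENCES:
            s = case.slices[seq]
            img_name = f"{case.patient_id}_{seq}.png"
            mask_name = f"{case.patient_id}_{seq}_mask.png"
            write_image(directory / img_name, s.image.pixels)
            write_mask(directory / mask_name, s.mask)
            if nifti:
                import nibabel as nib

                vol = s.image.pixels.astype(np.float32)[..., None]
                nib.save(nib.Nifti1Image(vol, np.eye(4)),
                         directory / f"{case.patient_id}_{seq}.nii.gz")
            rows.append({
                "patient_id": case.patient_id,
                "stage": case.stage,
                "sequence": seq,
                "image_path": img_name,
                "mask_path": mask_name,
                "intended_tur": s.intended_tur,
            })
    manifest = directory / "manifest.csv"
    pd.DataFrame(
        rows,
        columns=["patient_id", "stage", "sequence", "image_path", "mask_path", "intended_tur"],
    ).to_csv(manifest, index=False)
    return manifest
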