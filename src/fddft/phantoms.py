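"""Seeded synthetic MR-like phantoms with known ground-truth lesions.

The generator emulates the features of an axial T2-FLAIR stack that the
segmentation pipeline actually keys on:

* a bright skull-like rim (scalp/skull band) around the head, separated
  from the brain by a dark band playing skull bone and suppressed CSF;
* heterogeneous brain-tissue texture (a smooth Gaussian random field
  added to a dark-to-mid parenchyma level) with a glaring lesion, the
  contrast regime of FLAIR edema;
* one or more higher-intensity ellipsoidal lesion blobs strictly inside
  the brain;
* per-slice multiplicative gain jitter, mimicking the slice-to-slice
  intensity inconsistency of different imaging protocols;
* additive Gaussian noise inside the head support, clipped to [0, 1].
  The background outside the head is exactly zero, as in preprocessed
  challenge-style volumes.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .io_preprocess import ImageGrid, VolumeStack

__all__ = ["PhantomSpec", "generate_phantom", "generate_hard_cases", "HARD_CASE_KINDS"]

HARD_CASE_KINDS = ("low_contrast", "low_energy", "multi_block")


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of a synthetic head volume.

    Intensities are on the normalized [0, 1] scale and mimic an axial
    T2-FLAIR contrast: mid-dark parenchyma, a glaring lesion, a bright
    scalp/skull rim, and a dark band (skull bone plus suppressed CSF)
    between the rim and the brain.  Lesions are ellipsoids given by
    (row, col, slice) centers and per-axis radii in voxels; every lesion
    must lie inside the brain ellipsoid.
    """

    shape: tuple[int, int, int] = (240, 240, 32)
    brain_semiaxes: tuple[float, float, float] = (88.0, 72.0, 20.0)
    lesion_centers: tuple[tuple[float, float, float], ...] = ((150.0, 100.0, 16.0),)
    lesion_radii: tuple[tuple[float, float, float], ...] = ((22.0, 20.0, 11.0),)
    lesion_contrast: float = 0.55
    tissue_level: float = 0.16
    texture_sigma: float = 0.03
    texture_scale: float = 6.0
    csf_level: float = 0.05
    csf_thickness: float = 5.0
    skull_level: float = 0.85
    skull_thickness: float = 12.0
    noise_sigma: float = 0.02
    slice_gain_jitter: float = 0.10
    seed: int = 0


def _ellipsoid_mask(shape: tuple[int, int, int], center, semiaxes) -> np.ndarray:
    h, w, d = shape
    rr = np.arange(h, dtype=float)[:, None, None]
    cc = np.arange(w, dtype=float)[None, :, None]
    zz = np.arange(d, dtype=float)[None, None, :]
    q = (
        ((rr - center[0]) / semiaxes[0]) ** 2
        + ((cc - center[1]) / semiaxes[1]) ** 2
        + ((zz - center[2]) / semiaxes[2]) ** 2
    )
    return q <= 1.0


def generate_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[VolumeStack, np.ndarray]:
    """Build the intensity volume and its binary lesion ground truth.

    Returns ``(volume, truth)`` where ``truth`` has shape ``(H, W, D)``.
    Raises :class:`PhantomSpecError` if any lesion voxel falls outside the
    brain ellipsoid.
    """
    h, w, d = spec.shape
    center = ((h - 1) / 2.0, (w - 1) / 2.0, (d - 1) / 2.0)
    brain = _ellipsoid_mask(spec.shape, center, spec.brain_semiaxes)
    csf_outer = _ellipsoid_mask(
        spec.shape, center, tuple(a + spec.csf_thickness for a in spec.brain_semiaxes)
    )
    skull_outer = _ellipsoid_mask(
        spec.shape,
        center,
        tuple(a + spec.csf_thickness + spec.skull_thickness for a in spec.brain_semiaxes),
    )
    csf = csf_outer & ~brain  # dark skull-bone/CSF band
    skull = skull_outer & ~csf_outer  # bright scalp/skull rim
    head = skull_outer

    truth = np.zeros(spec.shape, dtype=bool)
    if len(spec.lesion_centers) != len(spec.lesion_radii):
        raise PhantomSpecError("lesion_centers and lesion_radii must have equal length")
    for c, r in zip(spec.lesion_centers, spec.lesion_radii):
        radii = (r, r, r) if np.isscalar(r) else tuple(r)
        lesion = _ellipsoid_mask(spec.shape, c, radii)
        if np.any(lesion & ~brain):
            raise PhantomSpecError(f"lesion at {c} with radii {radii} extends outside the brain")
        truth |= lesion

    rng = np.random.default_rng(spec.seed)
    vol = np.zeros(spec.shape, dtype=float)
    vol[brain] = spec.tissue_level
    if spec.texture_sigma > 0:
        field = ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.texture_scale)
        sd = field.std()
        if sd > 0:
            vol[brain] += (field * (spec.texture_sigma / sd))[brain]
    vol[truth] += spec.lesion_contrast
    vol[csf] = spec.csf_level
    vol[skull] = spec.skull_level

    if spec.slice_gain_jitter > 0:
        gains = rng.uniform(1.0 - spec.slice_gain_jitter, 1.0 + spec.slice_gain_jitter, size=d)
        vol *= gains[None, None, :]
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        vol[head] += noise[head]
    np.clip(vol, 0.0, 1.0, out=vol)
    # keep exact-zero background even after jitter/noise bookkeeping
    vol[~head] = 0.0
    return VolumeStack.from_array(vol, mask=truth.astype(np.uint8)), truth.astype(np.uint8)


def _disk(shape: tuple[int, int], center, radius) -> np.ndarray:
    rr = np.arange(shape[0], dtype=float)[:, None]
    cc = np.arange(shape[1], dtype=float)[None, :]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_hard_cases(kind: str, seed: int = 0) -> tuple[ImageGrid, np.ndarray]:
    """2-D fixtures for the documented failure regimes.

    ``low_contrast``   — lesion/tissue gap no larger than the noise level
                         (low heterogeneity; boundaries nearly invisible).
    ``low_energy``     — lesion darker than the surrounding tissue mean
                         (low intensity and weak pair connection).
    ``multi_block``    — three disjoint blocks of unequal size on an empty
                         background; the biggest block dominates the PEDF
                         and starves the others of attention.

    Returns ``(image, truth_mask)``; the pipeline is *expected* to degrade
    on these, so callers snapshot its behaviour rather than assert success.
    """
    if kind not in HARD_CASE_KINDS:
        raise ValueError(f"kind must be one of {HARD_CASE_KINDS}, got {kind!r}")
    rng = np.random.default_rng(seed)
    shape = (128, 128)
    img = np.zeros(shape, dtype=float)
    truth = np.zeros(shape, dtype=bool)
    if kind in ("low_contrast", "low_energy"):
        brain = _disk(shape, (63.5, 63.5), 50)
        rim = _disk(shape, (63.5, 63.5), 53) & ~brain
        noise_sigma = 0.02
        img[brain] = 0.4
        lesion = _disk(shape, (80, 50), 14)
        if kind == "low_contrast":
            img[lesion] = 0.4 + noise_sigma  # gap == noise level
        else:
            img[lesion] = 0.25  # below the tissue mean
        img[rim] = 0.9
        img[brain | rim] += rng.normal(0.0, noise_sigma, size=shape)[brain | rim]
        truth = lesion
    else:  # multi_block
        # unequal sizes: the largest block soaks up the PEDF attention
        blocks = [((20, 20), (84, 84)), ((92, 30), (118, 70)), ((30, 95), (58, 120))]
        levels = [0.5, 0.6, 0.9]
        for ((r0, c0), (r1, c1)), level in zip(blocks, levels):
            img[r0:r1, c0:c1] = level
        # the small bright block plays the lesion
        (r0, c0), (r1, c1) = blocks[2]
        truth[r0:r1, c0:c1] = True
        img += rng.normal(0.0, 0.01, size=shape) * (img > 0)
    np.clip(img, 0.0, 1.0, out=img)
    return ImageGrid(img), truth.astype(np.uint8)
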