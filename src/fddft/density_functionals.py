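"""Kinetic/potential energy-density landscapes of a gray-level image.

A normalized image ``rho`` in ``[0, 1]^(H x W)`` is treated as the density
of a 2-D many-particle system on the pixel lattice.  The pseudo-Fermi
relation ``rho[k_F] = k_F^D / (D (2 pi)^D)`` at ``D = 2`` gives the kinetic
energy density functional (KEDF)

    t[rho](r) = 2 pi^2 rho(r),

a pointwise intensity enhancement, while the potential energy density
functional (PEDF) measures long-range pixel-pair similarity through a
Coulombic potential,

    u[rho](r) = 1/2 * integral rho(r') / |r - r'| d^2 r',

discretized with unit pixel cells and the self-term ``r = r'`` excluded.
The PEDF is a global convolution of the image with the reciprocal distance
kernel (RDK) ``k(r'; r) = 1 / (2 |r - r'|)``, which is what makes an
FFT-accelerated O(N log N) evaluation possible; the O(N^3) pixel-by-pixel
sum is kept as the test oracle (:func:`pedf_direct`).

Scale balance between the two landscapes is carried by the adaptive
scaling factor ``gamma = <u>/(2 <t>)`` (global means), entering the
Lagrangian and Hamiltonian density functionals

    L = gamma^2 t - gamma u,      H = gamma^2 t + gamma u.

The zero-level set of L marks boundaries where inside/outside pixel
interactions cancel; its superlevel sets are the raw material of the
aware feature map downstream.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.fft
from skimage.transform import resize

from .errors import FactorRangeError, KernelDimensionError, ZeroKineticError
from .io_preprocess import ImageGrid

__all__ = [
    "TWO_PI_SQ",
    "ReciprocalDistanceKernel",
    "EnergyLandscapes",
    "kedf",
    "build_rdk",
    "pedf_direct",
    "pedf_fft",
    "gamma_init",
    "ldf",
    "hdf",
    "compute_landscapes",
]

#: KEDF prefactor: the D = 2 pseudo-Fermi relation collapses to t = 2 pi^2 rho.
TWO_PI_SQ = 2.0 * np.pi**2

#: integral of 1/|x| over the unit square centered at the origin,
#: 4 ln(1 + sqrt(2)); the analytic Coulomb self-cell contribution.
SELF_CELL_INTEGRAL = 4.0 * np.log(1.0 + np.sqrt(2.0))


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, ImageGrid) else np.asarray(img, dtype=float)


@dataclasses.dataclass(frozen=True, eq=False)
class ReciprocalDistanceKernel:
    """The discrete kernel 1/(2 |delta|) on the offset grid.

    ``values`` covers offsets ``di in [-(H_r-1), H_r-1]`` and
    ``dj in [-(W_r-1), W_r-1]``; the zero-offset cell (the kernel origin)
    is 0 because the discrete Coulomb sum excludes the self-interaction.
    """

    values: np.ndarray
    origin_row: int
    origin_col: int
    reduced_dims: tuple[int, int]


@dataclasses.dataclass(frozen=True, eq=False)
class EnergyLandscapes:
    """The (t, u, L, H, gamma) bundle for one image."""

    t: np.ndarray
    u: np.ndarray
    L: np.ndarray
    Hd: np.ndarray
    gamma: float


def kedf(img: ImageGrid | np.ndarray) -> np.ndarray:
    """Kinetic energy density functional: elementwise ``2 pi^2 rho``."""
    return TWO_PI_SQ * _values(img)


def build_rdk(h_r: int, w_r: int) -> ReciprocalDistanceKernel:
    """Build the reciprocal distance kernel for an ``h_r x w_r`` grid.

    The kernel spans every offset reachable between two cells of the grid,
    i.e. a ``(2 h_r - 1) x (2 w_r - 1)`` matrix, so that convolving the
    image against it realizes the full all-pairs Coulomb sum.
    """
    if h_r < 2 or w_r < 2:
        raise KernelDimensionError(f"kernel dims must be >= 2, got ({h_r}, {w_r})")
    di = np.arange(-(h_r - 1), h_r, dtype=float)[:, None]
    dj = np.arange(-(w_r - 1), w_r, dtype=float)[None, :]
    dist = np.hypot(di, dj)
    values = np.zeros_like(dist)
    nz = dist > 0
    values[nz] = 1.0 / (2.0 * dist[nz])
    return ReciprocalDistanceKernel(
        values=values, origin_row=h_r - 1, origin_col=w_r - 1, reduced_dims=(h_r, w_r)
    )


def pedf_direct(img: ImageGrid | np.ndarray) -> np.ndarray:
    """O(N^2)-pairs evaluation of the PEDF sum; the oracle for small grids.

    Computes ``u(r) = 1/2 sum_{r' != r} rho(r') / ||r - r'||`` with unit
    cell area, by materializing the full pairwise distance matrix.  Memory
    grows as (H W)^2 — intended for grids up to roughly 64 x 64.
    """
    rho = _values(img)
    h, w = rho.shape
    coords = np.stack(np.meshgrid(np.arange(h), np.arange(w), indexing="ij"), axis=-1)
    pts = coords.reshape(-1, 2).astype(float)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, 0.5 / np.where(dist > 0, dist, 1.0), 0.0)
    return (inv @ rho.ravel()).reshape(h, w)


def _linear_convolve_fft(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded FFT linear convolution, cropped to the field's window.

    Both operands are padded to the full linear-convolution support (next
    fast FFT length), multiplied elementwise in the frequency domain
    (Hadamard product), inverse-transformed, and the ``field``-shaped
    window aligned with the kernel origin is cut out.
    """
    fh, fw = field.shape
    kh, kw = kernel.shape
    full = (fh + kh - 1, fw + kw - 1)
    fast = [scipy.fft.next_fast_len(s, real=True) for s in full]
    F = scipy.fft.rfft2(field, fast)
    K = scipy.fft.rfft2(kernel, fast)
    conv = scipy.fft.irfft2(F * K, fast)[: full[0], : full[1]]
    # the RDK is always odd-sized with its origin at (kh//2, kw//2), so the
    # window aligned with the field starts exactly there.
    return conv[kh // 2 : kh // 2 + fh, kw // 2 : kw // 2 + fw]


def pedf_fft(img: ImageGrid | np.ndarray, factor: float = 0.125) -> np.ndarray:
    """FFT-accelerated PEDF through the dimension-reduced encode/decode path.

    The image is (1) bilinearly downsampled to ``round(factor * (H, W))``,
    (2) linearly convolved with the matching RDK via zero-padded 2-D FFTs,
    and (3) bicubically upsampled back to ``(H, W)``.  Two normalizations
    make the reduced path agree with the full-resolution discrete sum:

    * the Coulomb sum over a value-preserving resampling scales linearly
      with the grid extent (cell area contributes ``f^2``, distances
      ``f``), so the reduced result is multiplied by the geometric-mean
      reduction ``s = sqrt((H/H_r) (W/W_r))`` on the way back up — this
      also keeps ``gamma`` stable across reduction factors;
    * the coarse grid's zero origin cell excludes the whole near field
      within half a reduced cell of each point, which the full-resolution
      sum includes; its analytic value for a locally flat density,
      ``1/2 * C0 * (s - 1) * rho(r)`` with ``C0 = 4 ln(1 + sqrt(2))``
      (the unit-cell Coulomb integral), is added back at full resolution.

    The correction vanishes smoothly as ``s -> 1``; at ``factor = 1`` the
    path is the exact discrete sum up to FFT round-off.
    """
    if not 0.0 < factor <= 1.0:
        raise FactorRangeError(f"dimension-reduction factor must be in (0, 1], got {factor}")
    rho = _values(img)
    h, w = rho.shape
    h_r = max(2, round(factor * h))
    w_r = max(2, round(factor * w))
    reduced = (h_r, w_r) != (h, w)
    small = (
        resize(rho, (h_r, w_r), order=1, anti_aliasing=False, preserve_range=True)
        if reduced
        else rho
    )
    kernel = build_rdk(h_r, w_r)
    u_small = _linear_convolve_fft(small, kernel.values)
    if not reduced:
        return u_small
    scale = np.sqrt((h / h_r) * (w / w_r))
    u = resize(u_small, (h, w), order=3, preserve_range=True) * scale
    return u + 0.5 * SELF_CELL_INTEGRAL * (scale - 1.0) * rho


def gamma_init(t: np.ndarray, u: np.ndarray) -> float:
    """Adaptive scaling factor ``gamma = <u> / (2 <t>)`` from global means."""
    mean_t = float(np.mean(t))
    if mean_t <= 0.0:
        raise ZeroKineticError("gamma undefined: global mean KEDF is not positive")
    return 0.5 * float(np.mean(u)) / mean_t


def ldf(t: np.ndarray, u: np.ndarray, gamma: float) -> np.ndarray:
    """Lagrangian density functional ``gamma^2 t - gamma u``."""
    return gamma * gamma * t - gamma * u


def hdf(t: np.ndarray, u: np.ndarray, gamma: float) -> np.ndarray:
    """Hamiltonian density functional ``gamma^2 t + gamma u``."""
    return gamma * gamma * t + gamma * u


def compute_landscapes(img: ImageGrid | np.ndarray, factor: float = 0.125) -> EnergyLandscapes:
    """One-shot t/u/L/H/gamma computation with the initial gamma."""
    t = kedf(img)
    u = pedf_fft(img, factor)
    gamma = gamma_init(t, u)
    return EnergyLandscapes(t=t, u=u, L=ldf(t, u, gamma), Hd=hdf(t, u, gamma), gamma=gamma)
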