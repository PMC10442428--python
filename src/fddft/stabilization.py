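"""Fermi normalization, similarity convergence, and geometric stability.

Two iterative procedures act on the energy landscapes before any mask is
extracted:

*Similarity convergence* repeatedly applies the Fermi normalization

    FN(rho; rho_F, rho_S) = 1 / (exp(-(rho - rho_F)/rho_S) + 1)

— a sigmoid of the z-score, with ``rho_F``/``rho_S`` the mean and standard
deviation of the currently retained elements — and keeps only elements
with ``FN > 0.5`` (equivalently, above the running mean).  Iteration stops
once fewer than a configurable fraction (default one half) of the initial
support survives.  The surviving set is a high-similarity subgraph mask
used to vet lesion candidates.

*Geometric stability* cures the border deformation of the Lagrangian
landscape by gradient-ascending the adaptive scaling factor:

    gamma_new <- gamma_prev + eta * <L>_new / <L>_prev

with learning rate ``eta`` (default 0.5), until the global LDF mean
satisfies ``<L> >= 0``.  The first update has no completed pair of
iterations yet, so its ratio is seeded at 1 (both means are typically
negative before convergence, putting the ratio near 1 anyway).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit

from . import density_functionals as df
from .errors import ConstantInputError, StabilizationError

__all__ = [
    "FermiParams",
    "SimilarityMask",
    "StabilizedLDF",
    "fermi_normalize",
    "similarity_convergence",
    "geometric_stability",
]


@dataclasses.dataclass(frozen=True)
class FermiParams:
    """Fermi-like level (global mean) and spread (global std) of a matrix."""

    rho_F: float
    rho_S: float

    @classmethod
    def of(cls, values: np.ndarray) -> "FermiParams":
        values = np.asarray(values, dtype=float)
        return cls(rho_F=float(values.mean()), rho_S=float(values.std()))


@dataclasses.dataclass(frozen=True, eq=False)
class SimilarityMask:
    """Surviving high-similarity subgraph after iterated Fermi truncation."""

    mask: np.ndarray
    iterations: int
    source: str


@dataclasses.dataclass(frozen=True, eq=False)
class StabilizedLDF:
    """Result of the gamma gradient ascent."""

    L_star: np.ndarray
    gamma_star: float
    eta: float
    trace: tuple[float, ...]

    @property
    def steps(self) -> int:
        """Number of gamma updates performed (trace also logs the initial mean)."""
        return len(self.trace) - 1


def fermi_normalize(M: np.ndarray, params: FermiParams | None = None) -> np.ndarray:
    """Sigmoid of the z-score, elementwise; strictly increasing in M.

    Raises :class:`ConstantInputError` when the matrix is constant
    (``rho_S = 0`` makes the z-score undefined).
    """
    M = np.asarray(M, dtype=float)
    if params is None:
        params = FermiParams.of(M)
    if params.rho_S <= 0.0:
        raise ConstantInputError("Fermi normalization undefined for a constant matrix")
    return expit((M - params.rho_F) / params.rho_S)


def similarity_convergence(
    landscape: np.ndarray,
    support: np.ndarray | None = None,
    stop_fraction: float = 0.5,
    source: str = "pedf",
    max_iter: int = 100,
) -> SimilarityMask:
    """Iterate FN > 0.5 retention until the surviving set is small enough.

    Statistics are recomputed over the currently retained elements only, so
    the threshold tracks the shrinking set (a level-set-style sweep toward
    the densest, most similar subgraph).  "Total data length" for the stop
    rule is the nonzero-support count of the initial landscape, not H x W —
    background zeros would otherwise satisfy the stop trivially.

    A support with fewer than 4 pixels is returned unchanged with
    ``iterations = 0``; a landscape that is constant on its support raises
    :class:`ConstantInputError`.
    """
    landscape = np.asarray(landscape, dtype=float)
    if support is None:
        support = landscape != 0
    retained = np.asarray(support, dtype=bool).copy()
    total = int(retained.sum())
    if total < 4:
        return SimilarityMask(mask=retained, iterations=0, source=source)
    iterations = 0
    while retained.sum() >= stop_fraction * total and iterations < max_iter:
        vals = landscape[retained]
        params = FermiParams.of(vals)
        if params.rho_S <= 0.0:
            raise ConstantInputError("similarity convergence stalled on a constant landscape")
        # FN > 0.5  <=>  value strictly above the running mean
        retained = retained & (landscape > params.rho_F)
        iterations += 1
    return SimilarityMask(mask=retained, iterations=iterations, source=source)


def geometric_stability(
    t: np.ndarray,
    u: np.ndarray,
    eta: float = 0.5,
    gamma0: float | None = None,
    max_iter: int = 1000,
) -> StabilizedLDF:
    """Gradient-ascend gamma until the global LDF mean is non-negative.

    Starting from ``gamma0`` (default: the balance value ``<u>/(2 <t>)``,
    which is exactly the minimizer of ``<L>(gamma)`` — so ascent always
    makes progress), each step adds ``eta * <L>_new / <L>_prev`` where the
    ratio is taken over the two most recently completed iterations and
    seeded at 1 for the first update.  Returns the final landscape, the
    final gamma, and the full ``<L>`` trace (including the initial mean).

    Raises :class:`StabilizationError` (carrying the trace) if the
    criterion is not met within ``max_iter`` updates.
    """
    if eta <= 0.0:
        raise ValueError(f"learning rate must be positive, got {eta}")
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    gamma = df.gamma_init(t, u) if gamma0 is None else float(gamma0)
    L = df.ldf(t, u, gamma)
    trace = [float(L.mean())]
    steps = 0
    while trace[-1] < 0.0:
        if steps >= max_iter:
            raise StabilizationError(
                f"<L> still {trace[-1]:.3g} after {max_iter} gamma updates", trace
            )
        ratio = 1.0 if len(trace) < 2 else trace[-1] / trace[-2]
        gamma = gamma + eta * ratio
        L = df.ldf(t, u, gamma)
        trace.append(float(L.mean()))
        steps += 1
    return StabilizedLDF(L_star=L, gamma_star=gamma, eta=eta, trace=tuple(trace))
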