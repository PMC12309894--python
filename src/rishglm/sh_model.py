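"""Real even-order spherical-harmonic representation of shell signals.

Diffusion signals on a shell are antipodally symmetric, so only even orders
l are modeled. The basis is the real symmetric convention: for a complex
orthonormal harmonic Y_l^m,

* m < 0:  sqrt(2) * Im(Y_l^|m|)
* m = 0:  Y_l^0 (real)
* m > 0:  sqrt(2) * Re(Y_l^m)

ordered by (l ascending, m ascending within l). Fitting is L2-regularized
least squares per voxel, with a Laplace-Beltrami smoothness penalty
(diagonal l^2 (l+1)^2, leaving l=0 untouched) by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .io_core import ShellData

__all__ = [
    "SHBasisSpec",
    "SHIndexMap",
    "SHCoefficientImage",
    "num_coefficients",
    "build_basis",
    "fit_sh",
    "reconstruct",
]

log = logging.getLogger(__name__)

#: Normal-matrix condition number above which fitting warns.
COND_WARN = 1e8


def num_coefficients(max_order: int) -> int:
    """Number of real even-order SH coefficients up to ``max_order``."""
    if max_order < 0 or max_order % 2:
        raise ValueError(f"max_order must be even and non-negative, got {max_order}")
    return (max_order + 1) * (max_order + 2) // 2


@dataclass(frozen=True)
class SHBasisSpec:
    """Order, regularization weight and penalty type of an SH fit."""

    max_order: int = 6
    lambda_reg: float = 5e-3
    regularizer: str = "laplace_beltrami"

    def __post_init__(self):
        num_coefficients(self.max_order)  # validates parity/sign
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")
        if self.regularizer not in ("laplace_beltrami", "identity"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")


@dataclass(frozen=True)
class SHIndexMap:
    """Bijection between coefficient positions and (l, m) pairs."""

    pairs: tuple  # of (l, m)

    @classmethod
    def for_order(cls, max_order: int) -> "SHIndexMap":
        num_coefficients(max_order)
        pairs = tuple((l, m) for l in range(0, max_order + 1, 2)
                      for m in range(-l, l + 1))
        return cls(pairs)

    @property
    def max_order(self) -> int:
        return self.pairs[-1][0]

    @property
    def orders(self) -> tuple:
        return tuple(range(0, self.max_order + 1, 2))

    def order_slice(self, l: int) -> slice:
        idx = [i for i, (ll, _) in enumerate(self.pairs) if ll == l]
        return slice(idx[0], idx[-1] + 1)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SHCoefficientImage:
    """Voxel grid of real even-order SH coefficients for one shell."""

    coeffs: np.ndarray  # X x Y x Z x M
    index_map: SHIndexMap
    bvalue: float
    mask: np.ndarray  # X x Y x Z bool

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.coeffs.shape[:3] != self.mask.shape:
            raise ValueError("coefficient grid does not match mask grid")
        if self.coeffs.shape[3] != len(self.index_map):
            raise ValueError("coefficient count does not match index map")

    @property
    def grid_shape(self):
        return self.coeffs.shape[:3]


def _check_unit(directions: np.ndarray) -> np.ndarray:
    directions = np.asarray(directions, dtype=float)
    if directions.ndim != 2 or directions.shape[1] != 3:
        raise ValueError(f"directions must be (N, 3), got {directions.shape}")
    norms = np.linalg.norm(directions, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("directions must be unit vectors")
    return directions


def build_basis(directions, spec: SHBasisSpec):
    """Evaluate the real even-order SH basis at unit directions.

    Returns
    -------
    B : (n_dirs, n_coeffs) ndarray
        Design matrix, columns in :class:`SHIndexMap` order.
    R : (n_coeffs,) ndarray
        Diagonal of the regularizer matrix: l^2 (l+1)^2 for
        ``laplace_beltrami``, ones for ``identity``.
    """
    directions = _check_unit(directions)
    index_map = SHIndexMap.for_order(spec.max_order)
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(directions[:, 1], directions[:, 0])  # azimuth
    cols = np.empty((directions.shape[0], len(index_map)))
    reg = np.empty(len(index_map))
    for j, (l, m) in enumerate(index_map.pairs):
        Y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols[:, j] = np.sqrt(2.0) * Y.imag
        elif m == 0:
            cols[:, j] = Y.real
        else:
            cols[:, j] = np.sqrt(2.0) * Y.real
        reg[j] = float(l * l * (l + 1) * (l + 1)) \
            if spec.regularizer == "laplace_beltrami" else 1.0
    return cols, reg


def _fit_operator(directions, spec: SHBasisSpec):
    """Precompute the linear map signals -> coefficients for one shell."""
    B, reg = build_basis(directions, spec)
    n_dirs, n_coeffs = B.shape
    if spec.lambda_reg == 0 and n_dirs < n_coeffs:
        raise ValueError(
            f"{n_dirs} directions cannot determine {n_coeffs} coefficients "
            "without regularization"
        )
    normal = B.T @ B + spec.lambda_reg * np.diag(reg)
    cond = np.linalg.cond(normal)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"singular SH normal matrix (condition number {cond:.3g}); "
            "the direction set is degenerate"
        )
    if cond > COND_WARN:
        warnings.warn(
            f"ill-conditioned SH fit (condition number {cond:.3g})",
            RuntimeWarning, stacklevel=3,
        )
    return np.linalg.solve(normal, B.T), B


def fit_sh(shell: ShellData, spec: SHBasisSpec,
           mask: np.ndarray | None = None) -> SHCoefficientImage:
    """Fit SH coefficients to every masked voxel of a shell.

    Per voxel, solves ``(B'B + lambda R) c = B' s``. Outside the mask
    coefficients are zero.
    """
    if mask is None:
        mask = np.ones(shell.grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shell.grid_shape:
        raise ValueError("mask grid does not match shell grid")
    op, _ = _fit_operator(shell.directions, spec)
    index_map = SHIndexMap.for_order(spec.max_order)
    signals = shell.dwi_signals[mask]  # n_vox x n_dirs
    coeffs = np.zeros(shell.grid_shape + (len(index_map),))
    coeffs[mask] = signals @ op.T
    return SHCoefficientImage(coeffs, index_map, shell.bvalue, mask)


def reconstruct(coeffs: SHCoefficientImage, directions,
                clip_negative: bool = True, return_clip_count: bool = False):
    """Evaluate the SH expansion at arbitrary unit directions.

    Negative reconstructed values (unphysical for magnitude MR data) are
    clipped to zero by default; the clip count is logged and optionally
    returned.
    """
    spec = SHBasisSpec(max_order=coeffs.index_map.max_order, lambda_reg=0.0)
    B, _ = build_basis(directions, spec)
    flat = coeffs.coeffs.reshape(-1, len(coeffs.index_map))
    signal = (flat @ B.T).reshape(coeffs.grid_shape + (B.shape[0],))
    n_clipped = 0
    if clip_negative:
        neg = signal < 0
        n_clipped = int(neg.sum())
        if n_clipped:
            log.info("clipped %d negative reconstructed samples", n_clipped)
            signal = np.where(neg, 0.0, signal)
    if return_clip_count:
        return signal, n_clipped
    return signal
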