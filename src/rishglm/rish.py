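"""Rotational-invariant spherical-harmonic (RISH) features and scaling.

The per-order feature is the energy L_l = sum_m c_{l,m}^2, which is
invariant to head orientation (rotations mix coefficients only within an
order, orthogonally). Site harmonization multiplies each order's
coefficients by sqrt(theta_l), so the feature itself is multiplied by
theta_l exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .sh_model import SHCoefficientImage

__all__ = ["RISHFeatureImage", "ScalingMaps", "compute_rish", "apply_scaling"]

log = logging.getLogger(__name__)


@dataclass
class RISHFeatureImage:
    """Per-order rotational invariants on a voxel grid.

    ``features[..., k]`` holds order ``orders[k]``; non-negative everywhere,
    zero outside the mask.
    """

    features: np.ndarray  # X x Y x Z x K
    orders: tuple
    mask: np.ndarray
    bvalue: float

    def __post_init__(self):
        self.orders = tuple(int(l) for l in self.orders)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.features.shape != self.mask.shape + (len(self.orders),):
            raise ValueError("feature grid does not match mask/orders")

    @property
    def grid_shape(self):
        return self.features.shape[:3]


@dataclass
class ScalingMaps:
    """Voxel-wise per-order scaling factors theta_l for one target site.

    ``theta[..., k]`` scales RISH order ``orders[k]``. ``valid`` marks
    voxels where the ratio was computable; elsewhere theta is 1 and the
    subject signal passes through unscaled.
    """

    theta: np.ndarray  # X x Y x Z x K
    orders: tuple
    valid: np.ndarray  # X x Y x Z bool
    clip_bounds: tuple = (0.1, 10.0)
    n_clipped: dict = field(default_factory=dict)

    def __post_init__(self):
        self.orders = tuple(int(l) for l in self.orders)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.theta.shape != self.valid.shape + (len(self.orders),):
            raise ValueError("theta grid does not match validity mask/orders")

    @property
    def grid_shape(self):
        return self.theta.shape[:3]

    def smoothed(self, fwhm_vox: float) -> "ScalingMaps":
        """Gaussian-smooth the maps (FWHM in voxels); optional, off by default."""
        sigma = fwhm_vox / 2.3548
        sm = np.stack([gaussian_filter(self.theta[..., k], sigma)
                       for k in range(self.theta.shape[-1])], axis=-1)
        return ScalingMaps(sm, self.orders, self.valid, self.clip_bounds,
                           dict(self.n_clipped))


def compute_rish(coeffs: SHCoefficientImage) -> RISHFeatureImage:
    """Per-order energy L_l = sum_m c_{l,m}^2 at every voxel."""
    imap = coeffs.index_map
    orders = imap.orders
    feats = np.empty(coeffs.grid_shape + (len(orders),))
    for k, l in enumerate(orders):
        sl = imap.order_slice(l)
        feats[..., k] = np.sum(coeffs.coeffs[..., sl] ** 2, axis=-1)
    feats[~coeffs.mask] = 0.0
    return RISHFeatureImage(feats, orders, coeffs.mask, coeffs.bvalue)


def apply_scaling(coeffs: SHCoefficientImage,
                  scaling: ScalingMaps) -> SHCoefficientImage:
    """Multiply order-l coefficients by sqrt(theta_l) voxel-wise.

    The output's RISH features equal ``theta * L(input)`` exactly. Voxels
    flagged invalid in the scaling maps pass through unscaled (their count
    is logged).
    """
    if scaling.grid_shape != coeffs.grid_shape:
        raise ValueError(
            f"scaling grid {scaling.grid_shape} does not match "
            f"coefficient grid {coeffs.grid_shape}"
        )
    if tuple(scaling.orders) != tuple(coeffs.index_map.orders):
        raise ValueError(
            f"scaling orders {scaling.orders} do not match coefficient "
            f"orders {coeffs.index_map.orders}"
        )
    out = coeffs.coeffs.copy()
    imap = coeffs.index_map
    for k, l in enumerate(imap.orders):
        factor = np.sqrt(scaling.theta[..., k])
        factor = np.where(scaling.valid, factor, 1.0)
        out[..., imap.order_slice(l)] *= factor[..., None]
    n_invalid = int((~scaling.valid & coeffs.mask).sum())
    if n_invalid:
        log.info("passed %d voxels through unscaled (invalid theta)", n_invalid)
    return SHCoefficientImage(out, imap, coeffs.bvalue, coeffs.mask)
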