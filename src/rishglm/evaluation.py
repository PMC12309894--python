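"""Harmonization quality metrics: DTI maps, group tests, recovery error.

The diffusion tensor is estimated per voxel by log-linear least squares
(signals floored before the log), from which FA and MD follow in closed
form. Site differences are assessed with voxel-wise covariate-adjusted
t-tests on metric maps, reported as the fraction of mask voxels significant
at a given alpha; scaling-map recovery against phantom ground truth is
summarized by relative-error percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_core import CovariateTable, DwiVolume, ShellData, select_shell
from .rish import ScalingMaps

__all__ = [
    "TensorImage",
    "GroupTestResult",
    "fit_dti",
    "fa_md",
    "subject_fa_md",
    "adjusted_group_test",
    "scaling_recovery_error",
    "age_metric_correlation",
]

log = logging.getLogger(__name__)

SIGNAL_FLOOR_REL = 1e-6  # of S0, applied before the log


@dataclass
class TensorImage:
    """Voxel-wise diffusion tensor: unique elements, S0 and eigenvalues."""

    elements: np.ndarray  # X x Y x Z x 6: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    s0: np.ndarray
    evals: np.ndarray  # X x Y x Z x 3, descending
    mask: np.ndarray
    n_negative_evals: int = 0


@dataclass
class GroupTestResult:
    """Voxel-wise covariate-adjusted two-site comparison."""

    t_map: np.ndarray
    p_map: np.ndarray
    significant_fraction: float
    alpha: float
    sites: tuple
    dof: int
    n_excluded: int  # zero-variance voxels without a defined t


def _dti_design(directions, bvalue):
    g = np.asarray(directions, dtype=float)
    return bvalue * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def fit_dti(shell: ShellData, mask: np.ndarray | None = None) -> TensorImage:
    """Log-linear least-squares tensor fit of one shell.

    Solves ``log(S/S0) = -b g'Dg`` per voxel; needs >= 6 well-spread
    directions. Negative eigenvalues (noise) are permitted and counted.
    """
    if mask is None:
        mask = np.ones(shell.grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    A = _dti_design(shell.directions, shell.bvalue)
    if A.shape[0] < 6 or np.linalg.matrix_rank(A) < 6:
        raise ValueError(
            f"{A.shape[0]} directions do not determine a tensor "
            "(rank-deficient direction set)"
        )
    s0 = shell.b0_mean
    floor = SIGNAL_FLOOR_REL * np.maximum(s0[mask, None], SIGNAL_FLOOR_REL)
    sig = np.maximum(shell.dwi_signals[mask], floor)
    y = -np.log(sig / np.maximum(s0[mask, None], SIGNAL_FLOOR_REL))
    D, *_ = np.linalg.lstsq(A, y.T, rcond=None)  # 6 x n_vox
    elements = np.zeros(shell.grid_shape + (6,))
    elements[mask] = D.T

    T = np.zeros(shell.grid_shape + (3, 3))
    xx, yy, zz, xy, xz, yz = (elements[..., i] for i in range(6))
    T[..., 0, 0], T[..., 1, 1], T[..., 2, 2] = xx, yy, zz
    T[..., 0, 1] = T[..., 1, 0] = xy
    T[..., 0, 2] = T[..., 2, 0] = xz
    T[..., 1, 2] = T[..., 2, 1] = yz
    evals = np.linalg.eigvalsh(T)[..., ::-1]  # descending
    n_neg = int((evals[mask] < 0).sum())
    if n_neg:
        log.info("tensor fit produced %d negative eigenvalues", n_neg)
    return TensorImage(elements, s0, evals, mask, n_neg)


def fa_md(tensor: TensorImage):
    """Fractional anisotropy and mean diffusivity from eigenvalues.

    MD = mean eigenvalue; FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||,
    defined as 0 for an all-zero tensor.
    """
    ev = tensor.evals
    md = ev.mean(axis=-1)
    dev = ev - md[..., None]
    norm = np.linalg.norm(ev, axis=-1)
    fa = np.zeros_like(md)
    nz = norm > 0
    fa[nz] = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1)[nz] / norm[nz]
    return fa, md


def subject_fa_md(dwi: DwiVolume, bvalue: float,
                  mask: np.ndarray | None = None, shell_tol: float = 100.0):
    """Convenience: shell selection + tensor fit + FA/MD for one subject."""
    shell = select_shell(dwi, bvalue, shell_tol)
    return fa_md(fit_dti(shell, mask))


def adjusted_group_test(metric_maps, table: CovariateTable, sites,
                        covariates=(), alpha: float = 0.05,
                        mask: np.ndarray | None = None) -> GroupTestResult:
    """Voxel-wise two-site t-test with linear covariate adjustment.

    Fits ``metric ~ intercept + site + centered covariates`` per voxel by
    least squares and tests the site contrast; with no covariates this is
    the classical equal-variance two-sample t-test. Zero-variance voxels
    have no defined statistic and are excluded from the fraction (counted).
    """
    site_a, site_b = sites
    sel, labels = [], []
    for i, sid in enumerate(table.subjects):
        s = table.site_of(sid)
        if s in (site_a, site_b):
            sel.append(i)
            labels.append(s)
    labels = np.asarray(labels)
    if (labels == site_a).sum() < 3 or (labels == site_b).sum() < 3:
        raise ValueError(f"need >= 3 subjects per site in {sites}")
    maps = np.stack([np.asarray(metric_maps[i]) for i in sel])
    n = maps.shape[0]
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    cols = [np.ones(n), (labels == site_b).astype(float)]
    sub = table.frame.iloc[sel]
    for c in covariates:
        v = sub[c].to_numpy(dtype=float)
        cols.append(v - v.mean())
    X = np.column_stack(cols)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient test design (site/covariate collinear)")
    dof = n - p
    Y = maps.reshape(n, -1)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    s2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(s2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    t = t.reshape(maps.shape[1:])
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = pvals.reshape(maps.shape[1:])

    defined = np.isfinite(t) & mask
    n_excluded = int(mask.sum() - defined.sum())
    frac = float((pvals[defined] <= alpha).sum() / max(defined.sum(), 1))
    return GroupTestResult(t, pvals, frac, alpha, (site_a, site_b), dof,
                           n_excluded)


def scaling_recovery_error(estimated: ScalingMaps, truth: np.ndarray,
                           mask: np.ndarray | None = None) -> dict:
    """Relative-error percentiles of estimated vs true scaling maps.

    ``truth`` is an (X, Y, Z, K) array aligned with ``estimated.orders``.
    Returns ``{order: {"median": ..., "p90": ...}}`` over valid mask voxels.
    """
    truth = np.asarray(truth)
    if truth.shape != estimated.theta.shape:
        raise ValueError(
            f"truth shape {truth.shape} != estimate {estimated.theta.shape}"
        )
    if mask is None:
        mask = np.ones(estimated.grid_shape, dtype=bool)
    sel = np.asarray(mask, dtype=bool) & estimated.valid
    out = {}
    for k, l in enumerate(estimated.orders):
        rel = np.abs(estimated.theta[sel, k] - truth[sel, k]) / truth[sel, k]
        out[int(l)] = {"median": float(np.median(rel)),
                       "p90": float(np.percentile(rel, 90))}
    return out


def age_metric_correlation(metric_maps, table: CovariateTable,
                           mask: np.ndarray | None = None,
                           age_column: str = "age"):
    """Pearson r between subject age and subject-mean metric in the mask.

    Returns ``(r, p_value)``; ``(nan, nan)`` when the metric has no
    variance across subjects.
    """
    if len(metric_maps) != len(table):
        raise ValueError("one metric map per table row required")
    if len(metric_maps) < 4:
        raise ValueError("need at least 4 subjects for a correlation")
    if mask is None:
        mask = np.ones(np.asarray(metric_maps[0]).shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    means = np.array([np.asarray(m)[mask].mean() for m in metric_maps])
    ages = table.frame[age_column].to_numpy(dtype=float)
    if np.ptp(means) == 0 or np.ptp(ages) == 0:
        log.warning("degenerate correlation input (zero variance)")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(ages, means)
    return float(r), float(p)
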