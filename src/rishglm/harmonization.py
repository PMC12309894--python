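"""Learning and applying RISH-based cross-site harmonization.

Two estimators of the per-order voxel-wise scaling maps theta_l mapping a
target site onto a reference site are provided:

* ``means``: the conventional estimator, theta_l = sigma_{l,R} / sigma_{l,T},
  the ratio of voxel-wise mean RISH features of two matched training groups.
* ``glm``: a voxel-wise general linear model of the RISH features on site
  indicator variables plus covariates (age, sex, ...). The site coefficients
  are covariate-adjusted site means, so theta_l = beta_{l,R} / beta_{l,T}
  removes the scanner effect without absorbing biological differences
  between unmatched training groups. Any number of sites is handled in a
  single fit by adding one indicator column per site.

With site indicators only (no covariates) the two estimators coincide
exactly, because ordinary least squares on orthogonal group indicators
returns the group means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .io_core import CovariateTable, DwiVolume, ShellData, select_shell
from .rish import RISHFeatureImage, ScalingMaps, apply_scaling, compute_rish
from .sh_model import SHBasisSpec, SHCoefficientImage, fit_sh, reconstruct

__all__ = [
    "DesignMatrix",
    "SiteMeanFeatures",
    "GLMCoefficientMaps",
    "HarmonizationModel",
    "TrainConfig",
    "build_design",
    "fit_site_means",
    "scaling_from_means",
    "fit_rish_glm",
    "scaling_from_glm",
    "covariate_effect_percent",
    "train",
    "harmonize_subject",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class GridMismatchError(ValueError):
    """Voxel grids of two inputs do not match."""


@dataclass
class DesignMatrix:
    """Site indicators plus mean-centered covariates for the voxel-wise GLM.

    One 0/1 indicator column per site (reference first, no global
    intercept), then covariate columns centered over the pooled training
    sample; ``centering`` records the subtracted means so apply-time
    behavior is reproducible.
    """

    matrix: np.ndarray  # n_subjects x (n_sites + n_covariates)
    columns: tuple
    site_labels: tuple
    reference_site: str
    centering: dict
    subjects: tuple

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise KeyError(f"no design column named {name!r}; "
                           f"have {list(self.columns)}") from None


@dataclass
class SiteMeanFeatures:
    """Voxel-wise mean RISH features per site (the sigma maps)."""

    means: dict  # site -> X x Y x Z x K
    orders: tuple
    mask: np.ndarray
    n_subjects: dict


@dataclass
class GLMCoefficientMaps:
    """Voxel-wise OLS coefficients of RISH features per order.

    ``betas[..., k, j]`` is the coefficient of design column ``columns[j]``
    for order ``orders[k]``. Site coefficients may go negative in noise;
    they are flagged downstream when forming ratios, not here.
    """

    betas: np.ndarray  # X x Y x Z x K x p
    columns: tuple
    site_labels: tuple
    reference_site: str
    orders: tuple
    resid_var: np.ndarray  # X x Y x Z x K
    mask: np.ndarray
    centering: dict
    dof: int


@dataclass
class TrainConfig:
    """Settings of a harmonization training run."""

    reference_site: str
    method: str = "glm"  # {"glm", "means"}
    covariates: tuple = ()
    max_order: int = 6
    lambda_reg: float = 5e-3
    regularizer: str = "laplace_beltrami"
    bvalue: float = 1000.0
    shell_tol: float = 100.0
    clip_bounds: tuple = (0.1, 10.0)
    eps_rel: float = 1e-6

    def __post_init__(self):
        if self.method not in ("glm", "means"):
            raise ValueError(f"unknown method {self.method!r}")
        self.covariates = tuple(self.covariates)

    @property
    def basis_spec(self) -> SHBasisSpec:
        return SHBasisSpec(self.max_order, self.lambda_reg, self.regularizer)


@dataclass
class HarmonizationModel:
    """A trained harmonization: per-target-site scaling maps plus metadata."""

    reference_site: str
    target_sites: tuple
    orders: tuple
    bvalue: float
    method: str
    scaling: dict  # site -> ScalingMaps
    grid_shape: tuple
    affine: np.ndarray
    mask: np.ndarray
    config: TrainConfig
    betas: GLMCoefficientMaps | None = None
    centering: dict = field(default_factory=dict)


def build_design(table: CovariateTable, covariate_names=None,
                 reference_site: str | None = None) -> DesignMatrix:
    """Assemble the site-indicator + centered-covariate design matrix.

    Raises on rank deficiency (e.g. a covariate perfectly collinear with
    site membership), naming candidate columns.
    """
    covariate_names = tuple(table.covariate_columns if covariate_names is None
                            else covariate_names)
    sites = table.sites
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to harmonize")
    if reference_site is None:
        reference_site = sites[0]
    if reference_site not in sites:
        raise ValueError(f"reference site {reference_site!r} not in {sites}")
    site_labels = (reference_site,
                   *[s for s in sites if s != reference_site])

    df = table.frame
    n = len(df)
    cols, names, centering = [], [], {}
    site_vec = df[table.site_column].to_numpy()
    for s in site_labels:
        cols.append((site_vec == s).astype(float))
        names.append(str(s))
    for c in covariate_names:
        v = df[c].to_numpy()
        if not np.issubdtype(np.asarray(v).dtype, np.number):
            raise ValueError(
                f"covariate {c!r} is not numeric; expand categoricals to "
                "indicator columns first (read_covariates does this)"
            )
        mean = float(np.mean(v))
        cols.append(np.asarray(v, dtype=float) - mean)
        names.append(c)
        centering[c] = mean
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offending = []
        for j in range(len(site_labels), X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                offending.append(names[j])
        raise ValueError(
            "design matrix is rank deficient; candidate collinear columns: "
            f"{offending or names}"
        )
    return DesignMatrix(X, tuple(names), site_labels, reference_site,
                        centering, tuple(df.index))


def _check_feature_grids(features):
    first = features[0]
    for f in features[1:]:
        if f.grid_shape != first.grid_shape:
            raise GridMismatchError(
                f"feature grids differ: {f.grid_shape} vs {first.grid_shape}"
            )
        if tuple(f.orders) != tuple(first.orders):
            raise ValueError("feature orders differ between subjects")
    return first


def fit_site_means(features, sites) -> SiteMeanFeatures:
    """Voxel-wise arithmetic mean of RISH features per site."""
    if len(features) != len(sites):
        raise ValueError("one site label per feature image required")
    first = _check_feature_grids(features)
    stacks = {}
    for f, s in zip(features, sites):
        stacks.setdefault(s, []).append(f.features)
    means, counts = {}, {}
    for s, arrs in stacks.items():
        if len(arrs) < 2:
            raise ValueError(f"site {s!r} has fewer than 2 training subjects")
        means[s] = np.mean(arrs, axis=0)
        counts[s] = len(arrs)
    return SiteMeanFeatures(means, tuple(first.orders), first.mask, counts)


def _ratio_maps(numer, denom, orders, mask, clip_bounds, eps_rel) -> ScalingMaps:
    """theta = numer/denom with an eps guard and clipping, per order.

    A voxel is valid only if every order's denominator exceeds
    ``eps_rel * mean(denominator)`` for that order within the mask;
    elsewhere theta = 1.
    """
    K = numer.shape[-1]
    theta = np.ones_like(numer)
    valid = np.asarray(mask, dtype=bool).copy()
    for k in range(K):
        d = denom[..., k]
        eps = eps_rel * float(np.mean(np.abs(d[mask]))) if mask.any() else eps_rel
        valid &= d > eps
    n_clipped = {}
    lo, hi = clip_bounds
    for k, l in enumerate(orders):
        raw = np.divide(numer[..., k], denom[..., k],
                        out=np.ones_like(numer[..., k]),
                        where=valid)
        clipped = np.clip(raw, lo, hi)
        n_clipped[int(l)] = int(((raw != clipped) & valid).sum())
        theta[..., k] = np.where(valid, clipped, 1.0)
    total = sum(n_clipped.values())
    if total:
        log.info("clipped theta at %d voxel-orders to [%g, %g]", total, lo, hi)
    return ScalingMaps(theta, tuple(orders), valid, tuple(clip_bounds), n_clipped)


def scaling_from_means(means: SiteMeanFeatures, reference: str, target: str,
                       clip_bounds=(0.1, 10.0), eps_rel: float = 1e-6) -> ScalingMaps:
    """Conventional scaling maps: theta_l = sigma_{l,R} / sigma_{l,T}."""
    for s in (reference, target):
        if s not in means.means:
            raise KeyError(f"site {s!r} not in site means {list(means.means)}")
    return _ratio_maps(means.means[reference], means.means[target],
                       means.orders, means.mask, clip_bounds, eps_rel)


def fit_rish_glm(features, design: DesignMatrix,
                 mask: np.ndarray | None = None) -> GLMCoefficientMaps:
    """Voxel-wise OLS of RISH features on the design matrix, every order.

    With a site-indicators-only design the site coefficients equal the
    voxel-wise site means exactly.
    """
    if len(features) != design.matrix.shape[0]:
        raise ValueError(
            f"{len(features)} feature images but design has "
            f"{design.matrix.shape[0]} rows"
        )
    first = _check_feature_grids(features)
    if mask is None:
        mask = first.mask
    X = design.matrix
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} subjects cannot identify {p} design columns")
    Y = np.stack([f.features for f in features])  # n x X x Y x Z x K
    grid = first.grid_shape
    K = len(first.orders)
    Yf = Y.reshape(n, -1)
    beta = np.linalg.solve(X.T @ X, X.T @ Yf)  # p x (vox*K)
    resid = Yf - X @ beta
    dof = n - p
    var = (resid ** 2).sum(axis=0) / dof
    betas = np.moveaxis(beta, 0, -1).reshape(grid + (K, p))
    resid_var = var.reshape(grid + (K,))
    return GLMCoefficientMaps(betas, design.columns, design.site_labels,
                              design.reference_site, tuple(first.orders),
                              resid_var, np.asarray(mask, dtype=bool),
                              dict(design.centering), dof)


def scaling_from_glm(betas: GLMCoefficientMaps, reference: str, target: str,
                     clip_bounds=(0.1, 10.0), eps_rel: float = 1e-6) -> ScalingMaps:
    """GLM scaling maps: theta_l = beta_{l,R} / beta_{l,T}.

    Because covariates are mean-centered, the site coefficients are
    covariate-adjusted site means evaluated at the pooled-cohort average
    covariate values.
    """
    i_ref = betas.columns.index(str(reference)) \
        if str(reference) in betas.columns else None
    i_tgt = betas.columns.index(str(target)) \
        if str(target) in betas.columns else None
    if i_ref is None or i_tgt is None:
        raise KeyError(
            f"sites {reference!r}/{target!r} not both in design columns "
            f"{list(betas.columns)}"
        )
    return _ratio_maps(betas.betas[..., i_ref], betas.betas[..., i_tgt],
                       betas.orders, betas.mask, clip_bounds, eps_rel)


def covariate_effect_percent(betas: GLMCoefficientMaps, covariate: str,
                             reference: str | None = None,
                             eps_rel: float = 1e-6) -> np.ndarray:
    """Percent change of L_l per unit covariate, relative to the adjusted
    reference-site mean: 100 * beta_cov / beta_ref per voxel and order.

    Returns an (X, Y, Z, K) array with NaN where the reference coefficient
    is too close to zero.
    """
    if covariate not in betas.columns:
        raise KeyError(f"no covariate column {covariate!r} in "
                       f"{list(betas.columns)}")
    reference = betas.reference_site if reference is None else reference
    j_cov = betas.columns.index(covariate)
    j_ref = betas.columns.index(str(reference))
    ref = betas.betas[..., j_ref]
    cov = betas.betas[..., j_cov]
    out = np.full_like(cov, np.nan)
    for k in range(ref.shape[-1]):
        r = ref[..., k]
        eps = eps_rel * float(np.mean(np.abs(r[betas.mask])))
        ok = np.abs(r) > eps
        out[..., k] = np.where(ok, 100.0 * cov[..., k] / np.where(ok, r, 1.0),
                               np.nan)
    out[~betas.mask] = np.nan
    return out


def _subject_features(subject, config: TrainConfig, mask):
    if isinstance(subject, SHCoefficientImage):
        coeffs = subject
    elif isinstance(subject, ShellData):
        coeffs = fit_sh(subject, config.basis_spec, mask)
    else:
        raise TypeError(
            f"subjects must be ShellData or SHCoefficientImage, got "
            f"{type(subject).__name__}"
        )
    return compute_rish(coeffs)


def train(subjects, table: CovariateTable, config: TrainConfig,
          mask: np.ndarray | None = None,
          affine: np.ndarray | None = None) -> HarmonizationModel:
    """Learn scaling maps for every non-reference site in one pass.

    ``subjects`` is a list of :class:`ShellData` (or precomputed
    :class:`SHCoefficientImage`) aligned row-by-row with ``table``; all
    inputs must already live on one common voxel grid (this function does
    no registration).

    With ``method="glm"`` all sites are fitted simultaneously with
    covariate adjustment; with ``method="means"`` each target site is
    compared to the reference independently via group means.
    """
    if len(subjects) != len(table):
        raise ValueError(f"{len(subjects)} subjects but {len(table)} table rows")
    features = [_subject_features(s, config, mask) for s in subjects]
    first = _check_feature_grids(features)
    mask = first.mask if mask is None else np.asarray(mask, dtype=bool)
    sites_per_subject = [table.site_of(sid) for sid in table.subjects]
    site_labels = table.sites
    if config.reference_site not in site_labels:
        raise ValueError(
            f"reference site {config.reference_site!r} not among {site_labels}"
        )
    targets = tuple(s for s in site_labels if s != config.reference_site)

    betas = None
    centering: dict = {}
    scaling = {}
    if config.method == "glm":
        design = build_design(table, config.covariates,
                              config.reference_site)
        betas = fit_rish_glm(features, design, mask)
        centering = dict(design.centering)
        for t in targets:
            scaling[t] = scaling_from_glm(betas, config.reference_site, t,
                                          config.clip_bounds, config.eps_rel)
    else:
        if config.covariates:
            log.warning("method='means' ignores covariates %s",
                        list(config.covariates))
        means = fit_site_means(features, sites_per_subject)
        for t in targets:
            scaling[t] = scaling_from_means(means, config.reference_site, t,
                                            config.clip_bounds, config.eps_rel)
    if affine is None:
        affine = np.eye(4)
    return HarmonizationModel(
        reference_site=config.reference_site, target_sites=targets,
        orders=tuple(first.orders), bvalue=config.bvalue,
        method=config.method, scaling=scaling, grid_shape=first.grid_shape,
        affine=np.asarray(affine, dtype=float), mask=mask, config=config,
        betas=betas, centering=centering,
    )


def harmonize_subject(dwi: DwiVolume, model: HarmonizationModel, site: str,
                      mask: np.ndarray | None = None) -> DwiVolume:
    """Map one subject's DWI volume onto the reference site.

    Reference-site subjects pass through unchanged. For a target site, the
    modeled shell is fitted with spherical harmonics, each order's
    coefficients are multiplied by sqrt(theta_l), and the signal is
    reconstructed at the subject's own directions. b=0 volumes (and any
    volumes outside the modeled shell) pass through unchanged.
    """
    if site == model.reference_site:
        return dwi
    if site not in model.scaling:
        raise KeyError(
            f"site {site!r} is not a target of this model; targets: "
            f"{list(model.scaling)}"
        )
    if dwi.data.shape[:3] != tuple(model.grid_shape):
        raise GridMismatchError(
            f"subject grid {dwi.data.shape[:3]} does not match model grid "
            f"{tuple(model.grid_shape)}"
        )
    cfg = model.config
    shell = select_shell(dwi, model.bvalue, cfg.shell_tol)
    use_mask = model.mask if mask is None else np.asarray(mask, dtype=bool)
    coeffs = fit_sh(shell, cfg.basis_spec, use_mask)
    scaled = apply_scaling(coeffs, model.scaling[site])
    recon, n_clip = reconstruct(scaled, shell.directions,
                                return_clip_count=True)
    if n_clip:
        log.info("subject harmonization clipped %d negative samples", n_clip)
    out = dwi.data.copy()
    in_shell = dwi.gradients.shell_mask(model.bvalue, cfg.shell_tol)
    out[..., in_shell] = recon
    out[~use_mask] = dwi.data[~use_mask]
    return DwiVolume(out, dwi.affine, dwi.gradients)


# ---------------------------------------------------------------------------
# serialization

def _save_map(path, arr, affine):
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
             str(path))


def save_model(model: HarmonizationModel, directory) -> None:
    """Write a model directory: metadata.json plus one NIfTI per map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "reference_site": model.reference_site,
        "target_sites": list(model.target_sites),
        "orders": list(model.orders),
        "bvalue": model.bvalue,
        "method": model.method,
        "grid_shape": list(model.grid_shape),
        "centering": model.centering,
        "config": {
            "reference_site": cfg.reference_site,
            "method": cfg.method,
            "covariates": list(cfg.covariates),
            "max_order": cfg.max_order,
            "lambda_reg": cfg.lambda_reg,
            "regularizer": cfg.regularizer,
            "bvalue": cfg.bvalue,
            "shell_tol": cfg.shell_tol,
            "clip_bounds": list(cfg.clip_bounds),
            "eps_rel": cfg.eps_rel,
        },
        "beta_columns": list(model.betas.columns) if model.betas else None,
        "beta_dof": model.betas.dof if model.betas else None,
        "beta_site_labels": list(model.betas.site_labels) if model.betas else None,
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=2))
    aff = model.affine
    _save_map(d / "mask.nii.gz", model.mask.astype(np.float32), aff)
    for site, sc in model.scaling.items():
        for k, l in enumerate(sc.orders):
            _save_map(d / f"scaling_{site}_L{l}.nii.gz", sc.theta[..., k], aff)
        _save_map(d / f"valid_{site}.nii.gz", sc.valid.astype(np.float32), aff)
    if model.betas is not None:
        b = model.betas
        for j, col in enumerate(b.columns):
            for k, l in enumerate(b.orders):
                _save_map(d / f"beta_{col}_L{l}.nii.gz", b.betas[..., k, j], aff)
        for k, l in enumerate(b.orders):
            _save_map(d / f"residvar_L{l}.nii.gz", b.resid_var[..., k], aff)


def _load_map(path):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"model file missing: {p}")
    img = nib.load(str(p))
    return np.asarray(img.get_fdata()), img.affine


def load_model(directory) -> HarmonizationModel:
    """Load a model directory written by :func:`save_model`."""
    d = Path(directory)
    meta_path = d / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.json in {d}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {meta.get('format_version')}"
        )
    c = meta["config"]
    cfg = TrainConfig(
        reference_site=c["reference_site"], method=c["method"],
        covariates=tuple(c["covariates"]), max_order=c["max_order"],
        lambda_reg=c["lambda_reg"], regularizer=c["regularizer"],
        bvalue=c["bvalue"], shell_tol=c["shell_tol"],
        clip_bounds=tuple(c["clip_bounds"]), eps_rel=c["eps_rel"],
    )
    orders = tuple(meta["orders"])
    mask, affine = _load_map(d / "mask.nii.gz")
    mask = mask > 0.5
    scaling = {}
    for site in meta["target_sites"]:
        theta = np.stack([_load_map(d / f"scaling_{site}_L{l}.nii.gz")[0]
                          for l in orders], axis=-1)
        valid = _load_map(d / f"valid_{site}.nii.gz")[0] > 0.5
        scaling[site] = ScalingMaps(theta, orders, valid,
                                    tuple(cfg.clip_bounds))
    betas = None
    if meta.get("beta_columns"):
        cols = tuple(meta["beta_columns"])
        b = np.stack(
            [np.stack([_load_map(d / f"beta_{col}_L{l}.nii.gz")[0]
                       for col in cols], axis=-1) for l in orders], axis=-2)
        rv = np.stack([_load_map(d / f"residvar_L{l}.nii.gz")[0]
                       for l in orders], axis=-1)
        betas = GLMCoefficientMaps(
            b, cols, tuple(meta["beta_site_labels"]), meta["reference_site"],
            orders, rv, mask, dict(meta["centering"]), int(meta["beta_dof"]))
    return HarmonizationModel(
        reference_site=meta["reference_site"],
        target_sites=tuple(meta["target_sites"]), orders=orders,
        bvalue=meta["bvalue"], method=meta["method"], scaling=scaling,
        grid_shape=tuple(meta["grid_shape"]), affine=affine, mask=mask,
        config=cfg, betas=betas, centering=dict(meta["centering"]),
    )
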