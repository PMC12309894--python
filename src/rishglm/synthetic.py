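"""Multi-site diffusion MRI phantom cohorts with known ground truth.

The generator emulates a retrospective multi-scanner study: per-site groups
of subjects with site-specific age/sex distributions, a single-shell
acquisition (60 directions at b = 1000 s/mm^2 plus one b=0), and two
separable signal effects:

* a *biological* effect — tensor diffusivities depend linearly on age and
  sex (radial diffusivity rises with age in white matter, lowering FA);
* a *scanner* effect — each non-reference site multiplies the SH energy of
  order l by a smooth positive field g_l(x), injected exactly in the
  spherical-harmonic domain, so the scaling maps a harmonization method
  should recover are known in closed form (theta_l = 1/g_l).

Because the site effect is injected on the noiseless signal before noise,
ground truth is exact and noiseless runs recover it to fit precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_core import CovariateTable, DwiVolume, GradientTable
from .sh_model import SHBasisSpec, SHIndexMap, build_basis, _fit_operator

__all__ = [
    "SitePopulation",
    "PhantomConfig",
    "PhantomGroundTruth",
    "packaged_directions",
    "simulate_cohort",
    "truth_rish_slopes",
]

WM, GM, CSF = 0, 1, 2


def packaged_directions() -> np.ndarray:
    """The fixed 60-direction set shipped with the package (unit vectors)."""
    with resources.files("rishglm.data").joinpath("directions60.txt").open() as f:
        dirs = np.loadtxt(f)
    return dirs


@dataclass(frozen=True)
class SitePopulation:
    """Demographics of one site's training group."""

    n_subjects: int = 18
    age_mean: float = 50.0
    age_sd: float = 10.0
    female_fraction: float = 0.4

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("each site needs at least 2 subjects")
        if not (0 <= self.female_fraction <= 1):
            raise ValueError("female_fraction must lie in [0, 1]")


def _default_sites():
    # Two groups of 18 with a ~21-year mean age gap, the hardest training
    # scenario for mean-based harmonization.
    return {
        "Site1": SitePopulation(18, 35.4, 6.1, 0.44),
        "Site2": SitePopulation(18, 56.4, 8.5, 0.39),
    }


@dataclass
class PhantomConfig:
    """Full description of a simulated multi-site cohort.

    ``sites`` maps site label to :class:`SitePopulation`; the first label is
    the reference site and receives no scanner effect. ``site_effects``
    optionally pins the per-order energy multiplier of a site to a constant
    (``{site: {l: value}}``) instead of a random smooth field in
    ``effect_range``.
    """

    grid_shape: tuple = (16, 16, 16)
    bvalue: float = 1000.0
    n_b0: int = 1
    sites: dict = field(default_factory=_default_sites)
    reference_site: str | None = None  # default: first key of ``sites``
    # tissue slabs along z: white matter, gray matter, CSF
    tissue_fractions: tuple = (0.7, 0.2, 0.1)
    wm_diffusivities: tuple = (1.7e-3, 0.2e-3, 0.2e-3)  # axial, radial, radial
    gm_diffusivity: float = 0.8e-3
    csf_diffusivity: float = 3.0e-3
    s0: float = 1.0
    # linear biological effects on WM radial diffusivity (relative per unit)
    age_slope: float = 0.003  # per year; raises RD, lowers FA with age
    sex_offset: float = 0.02  # relative RD offset for female subjects
    age_ref: float = 46.0  # covariate origin of the generative model
    max_order: int = 6
    effect_range: tuple = (0.7, 1.3)
    effect_smoothness: float = 2.0  # gaussian sigma (voxels) of g fields
    site_effects: dict | None = None
    noise_model: str = "rician"  # {"rician", "gaussian", "none"}
    snr: float = 30.0  # b0-referenced
    seed: int = 0  # demographics + noise
    effect_seed: int = 42  # scanner-effect fields (kept separate on purpose)

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.tissue_fractions = tuple(self.tissue_fractions)
        self.wm_diffusivities = tuple(self.wm_diffusivities)
        self.effect_range = tuple(self.effect_range)
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model != "none" and not self.snr > 0:
            raise ValueError("snr must be positive")
        lo, hi = self.effect_range
        if not (0 < lo <= hi):
            raise ValueError("effect_range must be positive with lo <= hi")
        for name, pop in self.sites.items():
            if not isinstance(pop, SitePopulation):
                raise TypeError(f"site {name!r} must map to a SitePopulation")
        if self.reference_site is None:
            self.reference_site = next(iter(self.sites))
        if self.reference_site not in self.sites:
            raise ValueError(f"reference site {self.reference_site!r} unknown")

    @property
    def orders(self) -> tuple:
        return tuple(range(0, self.max_order + 1, 2))


@dataclass
class PhantomGroundTruth:
    """Everything the simulator knows that an estimator should recover."""

    energy_scale: dict  # site -> X x Y x Z x K multiplier on L_l
    theta_true: dict  # site -> X x Y x Z x K = 1 / energy_scale
    orders: tuple
    tissue_labels: np.ndarray  # X x Y x Z int (0 WM, 1 GM, 2 CSF)
    mask: np.ndarray  # brain mask (whole grid)
    wm_mask: np.ndarray
    noiseless: dict  # subject_id -> float32 4D volume (site effect applied)
    directions: np.ndarray


def _tissue_labels(config: PhantomConfig) -> np.ndarray:
    nz = config.grid_shape[2]
    f_wm, f_gm, _ = config.tissue_fractions
    z_wm = int(round(f_wm * nz))
    z_gm = int(round((f_wm + f_gm) * nz))
    labels = np.full(config.grid_shape, CSF, dtype=int)
    labels[:, :, :z_wm] = WM
    labels[:, :, z_wm:z_gm] = GM
    return labels


def _smooth_field(rng, shape, sigma, lo, hi):
    f = gaussian_filter(rng.standard_normal(shape), sigma)
    f /= np.abs(f).max()
    center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    return center + half * f


def _site_energy_scales(config: PhantomConfig):
    """Per-site per-order multipliers g_l(x); reference site is all ones."""
    rng = np.random.default_rng(config.effect_seed)
    K = len(config.orders)
    lo, hi = config.effect_range
    scales = {}
    for site in config.sites:
        g = np.ones(config.grid_shape + (K,))
        if site != config.reference_site:
            pinned = (config.site_effects or {}).get(site, None)
            for k, l in enumerate(config.orders):
                if pinned is not None and l in pinned:
                    g[..., k] = pinned[l]
                else:
                    g[..., k] = _smooth_field(rng, config.grid_shape,
                                              config.effect_smoothness, lo, hi)
        scales[site] = g
    return scales


def _diffusivities(config: PhantomConfig, labels, age: float,
                   female: bool) -> np.ndarray:
    """Per-voxel diagonal tensor (axial, radial, radial) in mm^2/s."""
    ad, rd, _ = config.wm_diffusivities
    biol = 1.0 + config.age_slope * (age - config.age_ref) \
        + (config.sex_offset if female else 0.0)
    d = np.empty(config.grid_shape + (3,))
    d[labels == WM] = (ad, rd * biol, rd * biol)
    d[labels == GM] = config.gm_diffusivity
    d[labels == CSF] = config.csf_diffusivity
    return d


def _noiseless_signal(config: PhantomConfig, diffus, directions):
    """S = s0 * exp(-b g'Dg) for diagonal D aligned with the grid axes."""
    expo = np.einsum("...k,dk->...d", diffus, directions ** 2)
    return config.s0 * np.exp(-config.bvalue * expo)


def _apply_site_effect(signal, g, op, B, index_map):
    """Multiply order-l SH energy by g_l: coefficients scale by sqrt(g_l)."""
    grid = signal.shape[:3]
    c = signal.reshape(-1, signal.shape[-1]) @ op.T
    c = c.reshape(grid + (c.shape[-1],))
    for k, l in enumerate(index_map.orders):
        c[..., index_map.order_slice(l)] *= np.sqrt(g[..., k])[..., None]
    return c.reshape(-1, len(index_map)) @ B.T


def _add_noise(rng, data, sigma, model):
    if model == "none" or sigma == 0:
        return data
    if model == "gaussian":
        return data + rng.normal(0.0, sigma, data.shape)
    re = data + rng.normal(0.0, sigma, data.shape)
    im = rng.normal(0.0, sigma, data.shape)
    return np.sqrt(re ** 2 + im ** 2)


def simulate_cohort(config: PhantomConfig):
    """Generate one multi-site cohort.

    Returns
    -------
    volumes : list of DwiVolume
        One per subject, ordered as the covariate table rows.
    table : CovariateTable
        Columns ``site``, ``age``, ``sex`` (+ ``sex_M`` indicator).
    truth : PhantomGroundTruth
    """
    rng = np.random.default_rng(config.seed)
    directions = packaged_directions()
    labels = _tissue_labels(config)
    scales = _site_energy_scales(config)
    spec = SHBasisSpec(config.max_order, lambda_reg=0.0)
    op, B = _fit_operator(directions, spec)
    index_map = SHIndexMap.for_order(config.max_order)

    bvals = np.concatenate([np.zeros(config.n_b0),
                            np.full(len(directions), config.bvalue)])
    bvecs = np.vstack([np.zeros((config.n_b0, 3)), directions])
    grad = GradientTable(bvals, bvecs)
    sigma = 0.0 if config.noise_model == "none" else config.s0 / config.snr

    volumes, rows, noiseless = [], [], {}
    for site, pop in config.sites.items():
        ages = rng.normal(pop.age_mean, pop.age_sd, pop.n_subjects)
        female = rng.random(pop.n_subjects) < pop.female_fraction
        for i in range(pop.n_subjects):
            sid = f"{site}_s{i:02d}"
            diffus = _diffusivities(config, labels, ages[i], female[i])
            dwi = _noiseless_signal(config, diffus, directions)
            if not np.allclose(scales[site], 1.0):
                dwi = _apply_site_effect(dwi, scales[site], op, B, index_map)
                dwi = dwi.reshape(config.grid_shape + (len(directions),))
            b0 = np.full(config.grid_shape + (config.n_b0,), config.s0)
            clean = np.concatenate([b0, dwi], axis=-1)
            noiseless[sid] = clean.astype(np.float32)
            data = _add_noise(rng, clean, sigma, config.noise_model)
            volumes.append(DwiVolume(data, np.eye(4), grad))
            rows.append({"subject_id": sid, "site": site,
                         "age": ages[i], "sex": "F" if female[i] else "M"})

    df = pd.DataFrame(rows).set_index("subject_id")
    df["sex_M"] = (df["sex"] == "M").astype(float)
    table = CovariateTable(df, site_column="site",
                           covariate_columns=("age", "sex_M"))
    truth = PhantomGroundTruth(
        energy_scale=scales,
        theta_true={s: 1.0 / g for s, g in scales.items()},
        orders=config.orders, tissue_labels=labels,
        mask=np.ones(config.grid_shape, dtype=bool),
        wm_mask=labels == WM, noiseless=noiseless, directions=directions,
    )
    return volumes, table, truth


def truth_rish_slopes(config: PhantomConfig, covariate: str = "age",
                      delta: float = 1.0) -> np.ndarray:
    """Ground-truth per-order RISH slopes with respect to a covariate.

    Brute force: synthesize the noiseless reference-site signal at
    covariate +/- delta around the generative origin, fit exact SH, and
    central-difference the energies. Returns an (X, Y, Z, K) array of
    dL_l / d(covariate).
    """
    directions = packaged_directions()
    labels = _tissue_labels(config)
    spec = SHBasisSpec(config.max_order, lambda_reg=0.0)
    op, _ = _fit_operator(directions, spec)
    index_map = SHIndexMap.for_order(config.max_order)

    def energies(age, female):
        diffus = _diffusivities(config, labels, age, female)
        s = _noiseless_signal(config, diffus, directions)
        c = s.reshape(-1, s.shape[-1]) @ op.T
        K = len(index_map.orders)
        L = np.empty((c.shape[0], K))
        for k, l in enumerate(index_map.orders):
            sl = index_map.order_slice(l)
            L[:, k] = (c[:, sl] ** 2).sum(axis=1)
        return L.reshape(config.grid_shape + (K,))

    if covariate == "age":
        hi = energies(config.age_ref + delta, False)
        lo = energies(config.age_ref - delta, False)
        return (hi - lo) / (2.0 * delta)
    if covariate == "sex":
        return energies(config.age_ref, True) - energies(config.age_ref, False)
    raise ValueError(f"unknown covariate {covariate!r}")
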